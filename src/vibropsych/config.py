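"""Run configuration for the end-to-end reproduction driver.

Defaults equal the experiment's stated stimulus and schedule values:
500 ms trains, 90 Hz reference rate, 170 Hz reference waveform
frequency, 40 µm amplitude, 40 kHz sampling, 1,000 ms gap, 30 trials
per level in 3 blocks.  The config round-trips losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import stimgen
from .observer_sim import PopulationSpec


@dataclass
class RunConfig:
    # stimulus block
    waveform_frequency_hz: float = stimgen.REFERENCE_WAVEFORM_HZ
    pulse_rate_hz: float = stimgen.REFERENCE_RATE_HZ
    amplitude_um: float = stimgen.REFERENCE_AMPLITUDE_UM
    duration_ms: float = stimgen.REFERENCE_DURATION_MS
    sample_rate_hz: int = stimgen.DEFAULT_SAMPLE_RATE_HZ
    gap_ms: float = stimgen.DEFAULT_GAP_MS
    # schedule block
    seed: int = 0
    trials_per_level: int = stimgen.TRIALS_PER_LEVEL
    blocks: int = stimgen.BLOCKS_PER_SESSION
    include_practice: bool = False
    # observer population block
    n_participants: int = 25
    population: dict = field(default_factory=lambda: asdict(PopulationSpec()))
    # fit block
    sigmoid: str = "cumulative_gaussian"
    n_starts: int = 16
    catch_mode: str = "as_data"
    # analysis block
    pooling: str = "pooled"
    out_dir: str = "results"

    def population_spec(self) -> PopulationSpec:
        raw = dict(self.population)
        for key in ("shape_m", "shape_w", "rate_m", "rate_w", "gamma", "delta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return PopulationSpec(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
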