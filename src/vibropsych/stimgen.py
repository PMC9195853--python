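"""Pulsatile vibrotactile stimulus synthesis and session schedules.

Stimuli are trains of brief skin indentations ("pulses"), each a single
period of a raised cosine cut from a sinusoid of a given waveform
frequency, riding on a static base indentation.  A trial presents a
reference train followed (seamlessly or after a stimulus-free gap) by a
comparison train that may differ in pulse shape (waveform frequency,
hence pulse width) or in pulse rate.

All displacement values are expressed in micrometres relative to the
base indentation; absolute skin position is ``base + sample``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulseSpec",
    "TrainSpec",
    "Waveform",
    "Trial",
    "SessionSchedule",
    "make_pulse",
    "make_train",
    "make_trial_waveform",
    "build_schedule",
    "comparison_spec",
    "REFERENCE_WAVEFORM_HZ",
    "REFERENCE_RATE_HZ",
    "REFERENCE_AMPLITUDE_UM",
    "REFERENCE_DURATION_MS",
    "DEFAULT_SAMPLE_RATE_HZ",
    "DEFAULT_GAP_MS",
    "SHAPE_CHANGE_LEVELS_HZ",
    "RATE_CHANGE_LEVELS_HZ",
]

# Stimulus constants of the change-detection experiment.
REFERENCE_WAVEFORM_HZ = 170.0   # sinusoid the reference pulse is cut from
REFERENCE_RATE_HZ = 90.0        # reference pulse rate
REFERENCE_AMPLITUDE_UM = 40.0   # sinusoid amplitude (peak excursion 2A)
REFERENCE_DURATION_MS = 500.0   # train duration
DEFAULT_SAMPLE_RATE_HZ = 40_000
DEFAULT_GAP_MS = 1000.0
BASE_INDENTATION_MM = 1.0

# Comparison levels exclude the reference value: 14 shape levels, 9 rate
# levels, each presented 30 times next to an equal number of no-change
# trials, giving the 840- and 540-trial session totals.
SHAPE_CHANGE_LEVELS_HZ = tuple(float(f) for f in range(175, 245, 5))
RATE_CHANGE_LEVELS_HZ = tuple(float(r) for r in range(95, 140, 5))
TRIALS_PER_LEVEL = 30
BLOCKS_PER_SESSION = 3
PRACTICE_TRIALS = 20

Condition = Literal["shape", "rate"]


@dataclass(frozen=True)
class PulseSpec:
    """A single indentation pulse: one period of ``A(1 - cos 2pi f t)``.

    ``waveform_frequency_hz`` is the frequency of the underlying
    sinusoid; the pulse occupies exactly one period, so its width is
    ``1/f`` seconds.  ``amplitude_um`` is the sinusoid amplitude ``A``;
    the peak indentation above base is ``2A``.
    """

    waveform_frequency_hz: float = REFERENCE_WAVEFORM_HZ
    amplitude_um: float = REFERENCE_AMPLITUDE_UM

    def __post_init__(self) -> None:
        if self.waveform_frequency_hz <= 0:
            raise ValueError("waveform_frequency_hz must be positive")
        if self.amplitude_um <= 0:
            raise ValueError("amplitude_um must be positive")

    @property
    def width_s(self) -> float:
        return 1.0 / self.waveform_frequency_hz

    @property
    def width_ms(self) -> float:
        return 1000.0 / self.waveform_frequency_hz


@dataclass(frozen=True)
class TrainSpec:
    """A pulse train: pulses at ``pulse_rate_hz`` for ``duration_ms``."""

    pulse: PulseSpec = field(default_factory=PulseSpec)
    pulse_rate_hz: float = REFERENCE_RATE_HZ
    duration_ms: float = REFERENCE_DURATION_MS
    base_indentation_mm: float = BASE_INDENTATION_MM
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.pulse_rate_hz <= 0:
            raise ValueError("pulse_rate_hz must be positive")
        if self.pulse_rate_hz > self.pulse.waveform_frequency_hz:
            raise ValueError(
                "pulse width exceeds the inter-pulse period: "
                f"rate {self.pulse_rate_hz} Hz > waveform frequency "
                f"{self.pulse.waveform_frequency_hz} Hz"
            )

    @property
    def n_pulses(self) -> int:
        return int(math.floor(self.pulse_rate_hz * self.duration_ms / 1000.0 + 1e-9))


@dataclass(frozen=True)
class Waveform:
    """Sampled indentation trajectory (µm relative to base)."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate_hz

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.times_s, "displacement_um": self.samples}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Waveform":
        df = pd.read_csv(path)
        dt = np.diff(df["time_s"].to_numpy())
        fs = int(round(1.0 / float(np.median(dt))))
        return cls(df["displacement_um"].to_numpy(), fs)


@dataclass(frozen=True)
class Trial:
    """One change-detection trial of a session schedule."""

    condition: Condition
    is_change: bool
    level: float          # comparison waveform frequency (shape) or rate (rate), Hz
    gap_ms: float
    block_index: int      # -1 flags practice trials
    practice: bool = False

    def __post_init__(self) -> None:
        ref = REFERENCE_WAVEFORM_HZ if self.condition == "shape" else REFERENCE_RATE_HZ
        if self.is_change != (self.level != ref):
            raise ValueError("is_change inconsistent with level vs reference")


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered trial list realising one testing session."""

    condition: Condition
    gap_ms: float
    trials: tuple[Trial, ...]
    blocks: int
    seed: int

    @property
    def test_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.practice)

    @property
    def n_trials(self) -> int:
        """Number of non-practice trials."""
        return len(self.test_trials)

    def block_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for t in self.test_trials:
            counts[t.block_index] = counts.get(t.block_index, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(len(self.trials)),
                "block": [t.block_index for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "is_change": [t.is_change for t in self.trials],
                "level": [t.level for t in self.trials],
                "gap_ms": [t.gap_ms for t in self.trials],
                "practice_flag": [t.practice for t in self.trials],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "SessionSchedule":
        df = pd.read_csv(path)
        trials = tuple(
            Trial(
                condition=row.condition,
                is_change=bool(row.is_change),
                level=float(row.level),
                gap_ms=float(row.gap_ms),
                block_index=int(row.block),
                practice=bool(row.practice_flag),
            )
            for row in df.itertuples()
        )
        blocks = int(df.loc[~df["practice_flag"], "block"].nunique())
        return cls(
            condition=str(df["condition"].iloc[0]),
            gap_ms=float(df["gap_ms"].iloc[0]),
            trials=trials,
            blocks=blocks,
            seed=seed,
        )


def make_pulse(spec: PulseSpec, sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ) -> Waveform:
    """Synthesize one raised-cosine pulse, ``p(t) = A(1 - cos 2pi f t)``.

    The pulse occupies ``floor(fs/f)`` samples; the first rest sample
    (exactly zero) would fall at index ``floor(fs/f)``, which guarantees
    that consecutive pulses never overlap at the highest pulse rate.
    """
    f = spec.waveform_frequency_hz
    if sample_rate_hz < 2 * f:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz below Nyquist rate for {f} Hz waveform"
        )
    n = int(math.floor(sample_rate_hz / f))
    t = np.arange(n) / sample_rate_hz
    samples = spec.amplitude_um * (1.0 - np.cos(2.0 * np.pi * f * t))
    return Waveform(np.maximum(samples, 0.0), sample_rate_hz)


def make_train(spec: TrainSpec) -> Waveform:
    """Synthesize a pulse train: pulses at onsets ``k / rate``, rest between."""
    fs = spec.sample_rate_hz
    n_total = int(round(spec.duration_ms / 1000.0 * fs))
    pulse = make_pulse(spec.pulse, fs).samples
    out = np.zeros(n_total)
    for k in range(spec.n_pulses):
        onset = int(round(k * fs / spec.pulse_rate_hz))
        end = min(onset + pulse.size, n_total)
        out[onset:end] = pulse[: end - onset]
    return Waveform(out, fs)


def comparison_spec(trial: Trial, reference: TrainSpec) -> TrainSpec:
    """Train spec of the comparison stimulus: reference with one field changed."""
    if trial.condition == "shape":
        return replace(reference, pulse=replace(reference.pulse, waveform_frequency_hz=trial.level))
    return replace(reference, pulse_rate_hz=trial.level)


def make_trial_waveform(trial: Trial, reference: TrainSpec | None = None) -> Waveform:
    """Reference train, optional stimulus-free gap, then comparison train."""
    reference = reference if reference is not None else TrainSpec()
    fs = reference.sample_rate_hz
    ref = make_train(reference).samples
    comp = make_train(comparison_spec(trial, reference)).samples
    gap = np.zeros(int(round(trial.gap_ms / 1000.0 * fs)))
    return Waveform(np.concatenate([ref, gap, comp]), fs)


def _change_levels(condition: Condition) -> tuple[float, ...]:
    return SHAPE_CHANGE_LEVELS_HZ if condition == "shape" else RATE_CHANGE_LEVELS_HZ


def build_schedule(
    condition: Condition,
    gap_ms: float,
    seed: int,
    trials_per_level: int = TRIALS_PER_LEVEL,
    blocks: int = BLOCKS_PER_SESSION,
    include_practice: bool = False,
) -> SessionSchedule:
    """Build a pseudorandomized session schedule.

    Half the trials are no-change (reference repeated); each change level
    appears ``trials_per_level`` times, split evenly across blocks.  The
    shuffle is seeded and performed within blocks so every block holds
    equal level counts.  Practice trials (20, half change) are prepended
    with ``block_index=-1`` when requested and excluded from analysis.
    """
    if condition not in ("shape", "rate"):
        raise ValueError(f"unknown condition {condition!r}")
    if trials_per_level % blocks:
        raise ValueError("trials_per_level must divide evenly across blocks")
    levels = _change_levels(condition)
    reference = REFERENCE_WAVEFORM_HZ if condition == "shape" else REFERENCE_RATE_HZ
    per_block = trials_per_level // blocks
    n_change_block = per_block * len(levels)

    rng = np.random.default_rng(seed)
    trials: list[Trial] = []

    if include_practice:
        practice_levels = rng.choice(levels, size=PRACTICE_TRIALS // 2)
        practice = [
            Trial(condition, True, float(lv), gap_ms, -1, practice=True)
            for lv in practice_levels
        ] + [
            Trial(condition, False, reference, gap_ms, -1, practice=True)
            for _ in range(PRACTICE_TRIALS // 2)
        ]
        order = rng.permutation(len(practice))
        trials.extend(practice[i] for i in order)

    for b in range(blocks):
        block: list[Trial] = []
        for lv in levels:
            block.extend(
                Trial(condition, True, lv, gap_ms, b) for _ in range(per_block)
            )
        block.extend(
            Trial(condition, False, reference, gap_ms, b)
            for _ in range(n_change_block)
        )
        order = rng.permutation(len(block))
        trials.extend(block[i] for i in order)

    return SessionSchedule(condition, gap_ms, tuple(trials), blocks, seed)


def detect_pulses(w: Waveform, threshold_um: float = 1e-6) -> list[tuple[int, int]]:
    """Locate pulses in a sampled waveform as runs of strictly positive samples.

    Returns (start, stop) sample index pairs; ``stop`` is exclusive.
    Used for reconstruction checks (pulse count, per-pulse width).
    """
    above = w.samples > threshold_um
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(w.samples.size)
    return list(zip(starts, stops))
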