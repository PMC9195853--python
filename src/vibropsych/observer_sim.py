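"""Synthetic observers for the yes/no change-detection task.

An observer codes the stimulus on one axis — pulse width (ms), pulse
rate (Hz), or one of the global intensity formulations — and detects a
change with probability given by the psychometric mixture model applied
to the absolute difference between comparison and reference on that
axis.  On no-change trials the yes-probability is the false-alarm rate
gamma.  Working-memory degradation in gap sessions is modelled, when
requested, as a multiplicative inflation of the psychometric width.

An observer whose axis is constant across a stimulus family (e.g. mean
speed across pulse-shape changes) produces a flat yes-rate at gamma and
therefore no valid psychometric function — the degenerate case the
stimulus design exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import kinematics, stimgen
from .psychofit import PsychometricParams, predict
from .stimgen import (
    REFERENCE_RATE_HZ,
    REFERENCE_WAVEFORM_HZ,
    SessionSchedule,
    TrainSpec,
    Trial,
)

__all__ = [
    "ObserverSpec",
    "PopulationSpec",
    "decision_variable",
    "simulate_session",
    "simulate_cohort",
    "default_population",
]

RESPONSE_COLUMNS = [
    "participant_id",
    "session",
    "condition",
    "gap_ms",
    "trial_index",
    "level",
    "is_change",
    "response_yes",
]


@dataclass(frozen=True)
class ObserverSpec:
    """A parametric observer: coding axis + psychometric parameters.

    ``params`` live on the |comparison - reference| axis implied by
    ``coding_axis``; ``gap_width_inflation`` multiplies the width in gap
    sessions (1.0 reproduces the null finding of intact memory).
    """

    coding_axis: str                     # pulse_width_ms | pulse_rate_hz | intensity:<tag>
    params: PsychometricParams
    gap_width_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_width_inflation < 1.0:
            raise ValueError("gap_width_inflation must be >= 1")
        axis = self.coding_axis
        ok = axis in ("pulse_width_ms", "pulse_rate_hz") or (
            axis.startswith("intensity:") and axis.split(":", 1)[1] in kinematics.FORMULATIONS
        )
        if not ok:
            raise ValueError(f"unknown coding axis {axis!r}")


def decision_variable(
    trial: Trial,
    axis: str,
    reference: Optional[TrainSpec] = None,
    _cache: Optional[dict] = None,
) -> float:
    """Map a trial's comparison stimulus onto the observer's coding axis."""
    if axis == "pulse_width_ms":
        if trial.condition == "shape":
            return 1000.0 / trial.level
        return 1000.0 / REFERENCE_WAVEFORM_HZ  # rate changes keep the pulse shape
    if axis == "pulse_rate_hz":
        if trial.condition == "rate":
            return float(trial.level)
        return REFERENCE_RATE_HZ  # shape changes keep the rate
    if axis.startswith("intensity:"):
        tag = axis.split(":", 1)[1]
        reference = reference if reference is not None else TrainSpec()
        key = (trial.condition, trial.level, tag)
        if _cache is not None and key in _cache:
            return _cache[key]
        spec = stimgen.comparison_spec(trial, reference)
        value = kinematics.intensity_of_spec(spec, tag)
        if _cache is not None:
            _cache[key] = value
        return value
    raise ValueError(f"unknown coding axis {axis!r}")


def _reference_value(axis: str, condition: str, reference: TrainSpec, cache: dict) -> float:
    ref_level = REFERENCE_WAVEFORM_HZ if condition == "shape" else REFERENCE_RATE_HZ
    ref_trial = Trial(condition, False, ref_level, 0.0, 0)
    return decision_variable(ref_trial, axis, reference, cache)


def simulate_session(
    observer: ObserverSpec,
    schedule: SessionSchedule,
    participant_id: int = 0,
    session: int = 0,
    reference: Optional[TrainSpec] = None,
    full_lapse: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate Yes/No responses for every non-practice trial of a session.

    Change trials respond Yes with ``P(|axis(level) - axis(ref)|)`` under
    the observer's (possibly gap-inflated) psychometric parameters;
    no-change trials respond Yes with probability gamma.  With
    ``full_lapse`` the lapse rate instead flips the response on every
    trial type (delta is removed from the upper asymptote to
    compensate).  Draws are seeded through the observer unless an
    explicit generator is supplied.
    """
    rng = rng if rng is not None else np.random.default_rng(observer.seed)
    reference = reference if reference is not None else TrainSpec()
    params = observer.params
    if schedule.gap_ms > 0 and observer.gap_width_inflation != 1.0:
        params = replace(params, w=params.w * observer.gap_width_inflation)
    cache: dict = {}
    ref_value = _reference_value(observer.coding_axis, schedule.condition, reference, cache)

    rows = []
    for idx, trial in enumerate(schedule.test_trials):
        if trial.is_change:
            d = abs(decision_variable(trial, observer.coding_axis, reference, cache) - ref_value)
            if full_lapse:
                base = replace(params, delta=0.0)
                p = float(predict(base, d))
            else:
                p = float(predict(params, d))
        else:
            p = params.gamma
        yes = bool(rng.random() < p)
        if full_lapse and rng.random() < params.delta:
            yes = not yes
        rows.append(
            (
                participant_id,
                session,
                trial.condition,
                schedule.gap_ms,
                idx,
                trial.level,
                trial.is_change,
                yes,
            )
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions from which per-participant observers are drawn.

    Normal (mean, sd) for the thresholds and widths on each coding axis,
    uniform (lo, hi) for the asymptotes; a single width-inflation factor
    shared by the population.  Defaults emulate a cohort in which nearly
    every participant resolves pulse-shape (width) changes inside the
    tested range, while only a minority resolves rate changes — with
    intact storage across the gap (inflation 1).
    """

    shape_axis: str = "pulse_width_ms"
    rate_axis: str = "pulse_rate_hz"
    shape_m: tuple[float, float] = (0.9, 0.45)     # ms on the |delta width| axis
    shape_w: tuple[float, float] = (0.9, 0.25)
    rate_m: tuple[float, float] = (55.0, 15.0)     # Hz on the |delta rate| axis
    rate_w: tuple[float, float] = (25.0, 8.0)
    gamma: tuple[float, float] = (0.02, 0.08)
    delta: tuple[float, float] = (0.01, 0.04)
    gap_width_inflation: float = 1.0
    sigmoid: str = "cumulative_gaussian"
    # fraction of participants unable to perform the task on any axis
    # (their detection threshold sits far beyond every tested range)
    nonperformer_rate: float = 0.15

    def draw_observer(
        self,
        condition: str,
        rng: np.random.Generator,
        seed: int,
        nonperformer: bool = False,
    ) -> ObserverSpec:
        if condition == "shape":
            axis, (m_mu, m_sd), (w_mu, w_sd) = self.shape_axis, self.shape_m, self.shape_w
        else:
            axis, (m_mu, m_sd), (w_mu, w_sd) = self.rate_axis, self.rate_m, self.rate_w
        m = float(rng.normal(m_mu, m_sd))
        if nonperformer:
            m = 1e4 * m_mu  # flat performance across any tested range
        w = max(float(rng.normal(w_mu, w_sd)), 1e-3 * max(w_mu, 1.0))
        g = float(rng.uniform(*self.gamma))
        d = float(rng.uniform(*self.delta))
        return ObserverSpec(
            coding_axis=axis,
            params=PsychometricParams(m=m, w=w, gamma=g, delta=d, sigmoid=self.sigmoid),
            gap_width_inflation=self.gap_width_inflation,
            seed=seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {"_class": "PopulationSpec"}, fh)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("_class", None)
        for key in ("shape_m", "shape_w", "rate_m", "rate_w", "gamma", "delta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_population() -> PopulationSpec:
    return PopulationSpec()


# The four session types, counterbalanced over their 24 orderings.
SESSION_TYPES: tuple[tuple[str, float], ...] = (
    ("shape", 0.0),
    ("shape", stimgen.DEFAULT_GAP_MS),
    ("rate", 0.0),
    ("rate", stimgen.DEFAULT_GAP_MS),
)


def simulate_cohort(
    n_participants: int,
    population: Optional[PopulationSpec] = None,
    conditions: Sequence[tuple[str, float]] = SESSION_TYPES,
    seed: int = 0,
    trials_per_level: int = stimgen.TRIALS_PER_LEVEL,
    full_lapse: bool = False,
) -> pd.DataFrame:
    """Simulate a full cohort: every participant runs every session type.

    Session order is counterbalanced across the 24 permutations of the
    four session types, assigned to participants sequentially.  Each
    participant keeps one shape-axis observer and one rate-axis observer
    across their sessions (gap inflation applies within the observer).
    Fresh schedules are drawn per participant x session from the cohort
    seed, so the trial order differs across participants.
    """
    from itertools import permutations

    population = population if population is not None else default_population()
    orders = list(permutations(range(len(conditions))))
    ss = np.random.SeedSequence(seed)
    pop_rng = np.random.default_rng(ss.spawn(1)[0])
    tables = []
    for pid in range(n_participants):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(pid + 1,))
        rng = np.random.default_rng(child)
        nonperformer = bool(pop_rng.random() < population.nonperformer_rate)
        observers = {
            "shape": population.draw_observer("shape", pop_rng, seed=0, nonperformer=nonperformer),
            "rate": population.draw_observer("rate", pop_rng, seed=0, nonperformer=nonperformer),
        }
        order = orders[pid % len(orders)]
        for session_idx, cond_idx in enumerate(order):
            condition, gap_ms = conditions[cond_idx]
            sched_seed = int(rng.integers(2**31 - 1))
            schedule = stimgen.build_schedule(
                condition, gap_ms, seed=sched_seed, trials_per_level=trials_per_level
            )
            tables.append(
                simulate_session(
                    observers[condition],
                    schedule,
                    participant_id=pid,
                    session=session_idx,
                    full_lapse=full_lapse,
                    rng=rng,
                )
            )
    return pd.concat(tables, ignore_index=True)
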