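"""Analysis chain for change-detection response tables.

From a per-trial response table the pipeline aggregates binomial counts
per participant x condition x gap, fits the psychometric mixture model,
classifies validity, extracts false-alarm-corrected thresholds, converts
them to percent change of the reference stimulus, compares gap vs
no-gap sessions (paired t, probability-of-superiority effect size,
Pearson correlation), and refits the data on each global-intensity axis
to test whether intensity coding can explain performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import kinematics, stimgen
from .psychofit import (
    BinomialData,
    PsychometricResults,
    fit_ml,
)
from .stimgen import REFERENCE_RATE_HZ, REFERENCE_WAVEFORM_HZ, TrainSpec

__all__ = [
    "AggregatedSession",
    "ThresholdRecord",
    "ComparisonResult",
    "aggregate",
    "fit_sessions",
    "percent_change",
    "compare_gap_nogap",
    "rescale_to_intensity",
    "validity_census",
    "run_end_to_end",
]

# Relative axis span below which an intensity axis is degenerate (the
# iso-feature tolerance: discretization keeps it just above zero even on
# a true iso-feature line).
DEGENERATE_AXIS_TOL = 0.005


@dataclass(frozen=True)
class AggregatedSession:
    """Binomial counts for one participant x condition x gap cell."""

    participant_id: int
    condition: str
    gap_ms: float
    data: BinomialData            # change levels only (native axis, Hz)
    n_catch: int
    k_catch: int

    @property
    def false_alarm_rate(self) -> float:
        return self.k_catch / self.n_catch if self.n_catch else float("nan")


@dataclass(frozen=True)
class ThresholdRecord:
    participant_id: int
    condition: str
    gap_ms: float
    valid: bool
    invalid_reason: Optional[str]
    threshold_native: Optional[float]       # Hz on the session's native axis
    threshold_pct_change: Optional[float]   # % change vs the reference stimulus
    false_alarm_rate: float


@dataclass(frozen=True)
class ComparisonResult:
    """Paired gap vs no-gap comparison for one condition."""

    condition: str
    t_statistic: float
    dof: int
    p_value: float
    auc: float          # probability of superiority of gap over no-gap, ties 1/2
    pearson_r: float
    n_pairs: int


def aggregate(responses: pd.DataFrame) -> list[AggregatedSession]:
    """Collapse a per-trial response table into per-level binomial counts.

    Change trials yield k/n per level; no-change trials yield the
    empirical false-alarm rate.  Cells are emitted in (participant,
    condition, gap) order.
    """
    out: list[AggregatedSession] = []
    for (pid, cond, gap), grp in responses.groupby(
        ["participant_id", "condition", "gap_ms"], sort=True
    ):
        change = grp[grp["is_change"]]
        catch = grp[~grp["is_change"]]
        counts = (
            change.groupby("level")["response_yes"]
            .agg(n="size", k="sum")
            .reset_index()
            .sort_values("level")
        )
        data = BinomialData(
            counts["level"].to_numpy(),
            counts["n"].to_numpy(),
            counts["k"].to_numpy(),
        )
        out.append(
            AggregatedSession(
                participant_id=int(pid),
                condition=str(cond),
                gap_ms=float(gap),
                data=data,
                n_catch=int(len(catch)),
                k_catch=int(catch["response_yes"].sum()),
            )
        )
    return out


def percent_change(threshold_native: float, condition: str) -> float:
    """Threshold as percent change of the reference stimulus.

    Rate sessions: percent increase of the pulse rate over 90 Hz.
    Shape sessions: percent decrease of the pulse width relative to the
    reference width (width = 1/f, so 100 * (1 - 170 / f*)).
    """
    if condition == "rate":
        return 100.0 * (threshold_native - REFERENCE_RATE_HZ) / REFERENCE_RATE_HZ
    if condition == "shape":
        return 100.0 * (1.0 - REFERENCE_WAVEFORM_HZ / threshold_native)
    raise ValueError(f"unknown condition {condition!r}")


def fit_session(
    agg: AggregatedSession,
    catch_mode: str = "as_data",
    sigmoid: str = "cumulative_gaussian",
    n_starts: int = 16,
    seed: int = 0,
) -> PsychometricResults:
    """Fit one aggregated session on its native (Hz) axis.

    ``catch_mode`` controls how no-change trials inform the fit:
    ``"as_data"`` (default) inserts them as a binomial point at the
    reference level with gamma left free; ``"fix_gamma"`` freezes gamma
    at the empirical false-alarm rate; ``"ignore"`` uses change trials
    only.
    """
    data = agg.data
    fix_gamma = None
    if catch_mode == "as_data" and agg.n_catch > 0:
        ref = REFERENCE_WAVEFORM_HZ if agg.condition == "shape" else REFERENCE_RATE_HZ
        if ref < data.levels[0]:
            data = data.with_point(ref, agg.n_catch, agg.k_catch)
    elif catch_mode == "fix_gamma" and agg.n_catch > 0:
        fix_gamma = min(agg.false_alarm_rate, 0.45)
    elif catch_mode not in ("as_data", "fix_gamma", "ignore"):
        raise ValueError(f"unknown catch_mode {catch_mode!r}")
    return fit_ml(
        data, sigmoid=sigmoid, fix_gamma=fix_gamma, n_starts=n_starts, seed=seed
    )


def fit_sessions(
    sessions: Iterable[AggregatedSession],
    catch_mode: str = "as_data",
    sigmoid: str = "cumulative_gaussian",
    n_starts: int = 16,
    seed: int = 0,
) -> list[ThresholdRecord]:
    """Fit every session cell and extract threshold records.

    Thresholds are taken from the false-alarm-corrected 0.5 crossing on
    the change-level range (the tested stimulus range); percent-change
    conversion follows the condition's reference stimulus.
    """
    records: list[ThresholdRecord] = []
    for i, agg in enumerate(sessions):
        res = fit_session(
            agg, catch_mode=catch_mode, sigmoid=sigmoid, n_starts=n_starts, seed=seed + i
        )
        thr = res.threshold_corrected if res.valid else None
        records.append(
            ThresholdRecord(
                participant_id=agg.participant_id,
                condition=agg.condition,
                gap_ms=agg.gap_ms,
                valid=res.valid,
                invalid_reason=res.invalid_reason,
                threshold_native=thr,
                threshold_pct_change=(
                    percent_change(thr, agg.condition) if thr is not None else None
                ),
                false_alarm_rate=agg.false_alarm_rate,
            )
        )
    return records


def records_to_frame(records: Iterable[ThresholdRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def paired_auc(differences: np.ndarray) -> float:
    """Probability of superiority from paired differences (ties count 1/2)."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no pairs")
    return float(np.mean(d > 0) + 0.5 * np.mean(d == 0))


def compare_gap_nogap(records: Iterable[ThresholdRecord], condition: str) -> ComparisonResult:
    """Paired gap vs no-gap threshold comparison for one condition.

    Only participants valid in BOTH sessions enter.  Reports the paired
    t statistic, its p value, the probability-of-superiority effect size
    of gap over no-gap, and the Pearson correlation of the paired
    thresholds.
    """
    df = records_to_frame(records)
    df = df[(df["condition"] == condition) & df["valid"]]
    wide = df.pivot(index="participant_id", columns="gap_ms", values="threshold_native")
    gaps = sorted(c for c in wide.columns if c > 0)
    if 0.0 not in wide.columns or not gaps:
        raise ValueError("need both gap and no-gap thresholds")
    wide = wide[[0.0, gaps[0]]].dropna()
    if len(wide) < 2:
        raise ValueError("fewer than 2 complete pairs")
    nogap = wide[0.0].to_numpy()
    gap = wide[gaps[0]].to_numpy()
    t_res = stats.ttest_rel(gap, nogap)
    if np.allclose(gap, nogap):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
    r = float(stats.pearsonr(gap, nogap).statistic) if len(wide) > 2 else float("nan")
    return ComparisonResult(
        condition=condition,
        t_statistic=t_stat,
        dof=len(wide) - 1,
        p_value=p_val,
        auc=paired_auc(gap - nogap),
        pearson_r=r,
        n_pairs=len(wide),
    )


@dataclass(frozen=True)
class IntensityRescaleResult:
    """Logistic refit of one session's data on a global-intensity axis."""

    formulation: str
    condition: str
    degenerate: bool                    # axis constant across levels (iso-feature)
    data: Optional[BinomialData]        # counts on the intensity axis
    fit: Optional[PsychometricResults]  # logistic fit, None when degenerate


def rescale_to_intensity(
    data: BinomialData,
    condition: str,
    formulation: str,
    reference: Optional[TrainSpec] = None,
    n_starts: int = 16,
    seed: int = 0,
) -> IntensityRescaleResult:
    """Map native levels to an intensity axis and refit with a logistic.

    A formulation constant across the level family (mean speed under
    shape changes, by stimulus design) yields a degenerate axis: the
    refit is skipped and flagged rather than forced.
    """
    if formulation not in kinematics.FORMULATIONS:
        raise ValueError(f"unknown intensity formulation {formulation!r}")
    reference = reference if reference is not None else TrainSpec()
    axis = np.array(
        [
            kinematics.intensity_of_spec(
                stimgen.comparison_spec(
                    stimgen.Trial(condition, True, float(lv), 0.0, 0)
                    if lv != (REFERENCE_WAVEFORM_HZ if condition == "shape" else REFERENCE_RATE_HZ)
                    else stimgen.Trial(condition, False, float(lv), 0.0, 0),
                    reference,
                ),
                formulation,
            )
            for lv in data.levels
        ]
    )
    span = axis.max() - axis.min()
    if span <= DEGENERATE_AXIS_TOL * abs(axis.mean()):
        return IntensityRescaleResult(formulation, condition, True, None, None)
    order = np.argsort(axis)
    rescaled = BinomialData(axis[order], data.n_trials[order], data.k_yes[order])
    fit = fit_ml(rescaled, sigmoid="logistic", n_starts=n_starts, seed=seed)
    return IntensityRescaleResult(formulation, condition, False, rescaled, fit)


def validity_census(records: Iterable[ThresholdRecord]) -> pd.DataFrame:
    """Counts of valid fits per condition x gap, with totals."""
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["condition", "gap_ms", "n_valid", "n_total"])
    census = (
        df.groupby(["condition", "gap_ms"])
        .agg(n_valid=("valid", "sum"), n_total=("valid", "size"))
        .reset_index()
    )
    census["n_valid"] = census["n_valid"].astype(int)
    return census


def pooled_data(sessions: Iterable[AggregatedSession], condition: str, gap_ms: float) -> BinomialData:
    """Pool change-trial counts across participants for one cell."""
    frames = [
        pd.DataFrame({"level": s.data.levels, "n": s.data.n_trials, "k": s.data.k_yes})
        for s in sessions
        if s.condition == condition and s.gap_ms == gap_ms
    ]
    if not frames:
        raise ValueError("no sessions in the requested cell")
    pooled = pd.concat(frames).groupby("level", as_index=False).sum().sort_values("level")
    return BinomialData(pooled["level"].to_numpy(), pooled["n"].to_numpy(), pooled["k"].to_numpy())


def run_end_to_end(
    n_participants: int = 25,
    seed: int = 0,
    out_dir: str | Path = "results",
    population=None,
    trials_per_level: int = stimgen.TRIALS_PER_LEVEL,
    catch_mode: str = "as_data",
    n_starts: int = 16,
) -> dict:
    """Simulate a cohort, fit every session, and write the result bundle.

    Writes thresholds.csv, census.csv, comparisons.json and
    intensity_overlays.csv plus a manifest with the seeds and settings;
    deterministic given the seed.  Returns the bundle in memory.
    """
    from . import observer_sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    responses = observer_sim.simulate_cohort(
        n_participants, population=population, seed=seed, trials_per_level=trials_per_level
    )
    sessions = aggregate(responses)
    records = fit_sessions(sessions, catch_mode=catch_mode, n_starts=n_starts, seed=seed)
    thresholds = records_to_frame(records)
    census = validity_census(records)

    comparisons = {}
    for condition in ("shape", "rate"):
        try:
            comparisons[condition] = asdict(compare_gap_nogap(records, condition))
        except ValueError as exc:
            comparisons[condition] = {"error": str(exc)}
    comparisons["auc_definition"] = (
        "probability of superiority of gap over no-gap thresholds "
        "from paired differences; ties count 1/2"
    )

    overlays = []
    for condition, gap_ms in {(s.condition, s.gap_ms) for s in sessions}:
        pool = pooled_data(sessions, condition, gap_ms)
        for tag in kinematics.FORMULATIONS:
            res = rescale_to_intensity(pool, condition, tag, seed=seed)
            row = {
                "condition": condition,
                "gap_ms": gap_ms,
                "formulation": tag,
                "degenerate": res.degenerate,
            }
            if res.fit is not None and res.fit.params is not None:
                row.update(
                    m=res.fit.params.m,
                    w=res.fit.params.w,
                    gamma=res.fit.params.gamma,
                    delta=res.fit.params.delta,
                    valid=res.fit.valid,
                )
            overlays.append(row)
    overlays_df = pd.DataFrame(overlays).sort_values(
        ["condition", "gap_ms", "formulation"]
    )

    thresholds.to_csv(out / "thresholds.csv", index=False)
    census.to_csv(out / "census.csv", index=False)
    overlays_df.to_csv(out / "intensity_overlays.csv", index=False)
    with open(out / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=2)
    manifest = {
        "seed": seed,
        "n_participants": n_participants,
        "trials_per_level": trials_per_level,
        "catch_mode": catch_mode,
        "n_starts": n_starts,
        "sessions_per_participant": len(observer_sim.SESSION_TYPES),
        "trials_per_session": {
            "shape": 2 * trials_per_level * len(stimgen.SHAPE_CHANGE_LEVELS_HZ),
            "rate": 2 * trials_per_level * len(stimgen.RATE_CHANGE_LEVELS_HZ),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "responses": responses,
        "thresholds": thresholds,
        "census": census,
        "comparisons": comparisons,
        "overlays": overlays_df,
        "manifest": manifest,
    }
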