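"""Psychometric mixture model: maximum-likelihood fitting, validity
classification, false-alarm correction and threshold extraction.

The detection probability at stimulus level ``x`` is modelled as

    P(x; m, w, gamma, delta) = gamma + (1 - delta - gamma) * S(x; m, w)

where ``S`` is a sigmoid (cumulative Gaussian by default, logistic as an
alternative), ``m`` the level at which ``S = 0.5`` (threshold), ``w``
the width — the interval over which ``S`` rises from 0.05 to 0.95 —
``gamma`` the false-alarm rate (lower asymptote) and ``delta`` the lapse
rate (upper asymptote).  For the cumulative Gaussian the width maps to
the Gaussian scale as ``sigma = w / (2 * z_0.95)``; for the logistic the
scale is ``w / (2 * ln 19)``.

Fits follow the statsmodels idiom: build a :class:`PsychometricModel`
from binomial data, call :meth:`~PsychometricModel.fit`, and work with
the returned :class:`PsychometricResults` (parameters, likelihood,
validity verdict, false-alarm-corrected threshold, ``summary()``).

A fit is *valid* only if the fitted curve reaches a detection
probability of 0.5 and the corrected threshold falls strictly inside the
tested level range; otherwise the result carries an explicit reason
(``did_not_reach_half``, ``threshold_on_limit`` or ``fit_failed``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.stats import qmc

__all__ = [
    "PsychometricParams",
    "BinomialData",
    "PsychometricModel",
    "PsychometricResults",
    "FitResult",
    "predict",
    "neg_log_likelihood",
    "fit_ml",
    "false_alarm_correct",
    "threshold",
]

Z95 = float(stats.norm.ppf(0.95))   # 1.6448536...
LN19 = math.log(19.0)
CLAMP_EPS = 1e-9
DEFAULT_LAPSE_CAP = 0.1
DEFAULT_N_STARTS = 16

Sigmoid = Literal["cumulative_gaussian", "logistic"]


@dataclass(frozen=True)
class PsychometricParams:
    """Mixture-model parameters (threshold, width, asymptotes)."""

    m: float
    w: float
    gamma: float = 0.0
    delta: float = 0.0
    sigmoid: Sigmoid = "cumulative_gaussian"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("width w must be positive")
        if not (0 <= self.gamma < 0.5) or not (0 <= self.delta < 0.5):
            raise ValueError("gamma and delta must lie in [0, 0.5)")
        if self.gamma + self.delta >= 1:
            raise ValueError("gamma + delta must be below 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.w, self.gamma, self.delta])


def _sigmoid(x: np.ndarray, m: float, w: float, kind: Sigmoid) -> np.ndarray:
    # special.ndtr / expit keep the likelihood cheap inside multi-start fits
    if kind == "cumulative_gaussian":
        return special.ndtr((x - m) / (w / (2.0 * Z95)))
    if kind == "logistic":
        return special.expit((x - m) / (w / (2.0 * LN19)))
    raise ValueError(f"unknown sigmoid {kind!r}")


def _sigmoid_inv(p: float, m: float, w: float, kind: Sigmoid) -> float:
    if kind == "cumulative_gaussian":
        return float(m + special.ndtri(p) * w / (2.0 * Z95))
    if kind == "logistic":
        return float(m + special.logit(p) * w / (2.0 * LN19))
    raise ValueError(f"unknown sigmoid {kind!r}")


def predict(params: PsychometricParams, x: float | np.ndarray) -> float | np.ndarray:
    """Detection probability P(x) = gamma + (1-delta-gamma) S(x; m, w)."""
    x = np.asarray(x, dtype=float)
    s = _sigmoid(x, params.m, params.w, params.sigmoid)
    p = params.gamma + (1.0 - params.delta - params.gamma) * s
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class BinomialData:
    """Per-level binomial response counts (levels strictly increasing)."""

    levels: np.ndarray
    n_trials: np.ndarray
    k_yes: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        n = np.asarray(self.n_trials, dtype=int)
        k = np.asarray(self.k_yes, dtype=int)
        if not (levels.size == n.size == k.size):
            raise ValueError("levels, n_trials, k_yes must have equal length")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(n <= 0) or np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= k <= n with n > 0 at every level")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n_trials", n)
        object.__setattr__(self, "k_yes", k)

    @property
    def proportions(self) -> np.ndarray:
        return self.k_yes / self.n_trials

    @property
    def span(self) -> float:
        return float(self.levels[-1] - self.levels[0])

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        level_col: str = "level",
        n_col: str = "n",
        k_col: str = "k",
    ) -> "BinomialData":
        df = df.sort_values(level_col)
        return cls(df[level_col].to_numpy(), df[n_col].to_numpy(), df[k_col].to_numpy())

    def with_point(self, level: float, n: int, k: int) -> "BinomialData":
        """Return a copy with one extra (level, n, k) point inserted."""
        idx = np.searchsorted(self.levels, level)
        if idx < self.levels.size and self.levels[idx] == level:
            raise ValueError(f"level {level} already present")
        return BinomialData(
            np.insert(self.levels, idx, level),
            np.insert(self.n_trials, idx, n),
            np.insert(self.k_yes, idx, k),
        )


def neg_log_likelihood(params: PsychometricParams, data: BinomialData) -> float:
    """Binomial negative log-likelihood with probability clamping."""
    p = np.clip(predict(params, data.levels), CLAMP_EPS, 1.0 - CLAMP_EPS)
    return float(-np.sum(data.k_yes * np.log(p) + (data.n_trials - data.k_yes) * np.log1p(-p)))


def false_alarm_correct(p: float | np.ndarray, gamma: float) -> float | np.ndarray:
    """High-threshold false-alarm correction ``(p - gamma) / (1 - gamma)``."""
    if not (0 <= gamma < 1):
        raise ValueError("gamma must lie in [0, 1)")
    out = np.clip((np.asarray(p, dtype=float) - gamma) / (1.0 - gamma), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _corrected_threshold(
    params: PsychometricParams, level_range: tuple[float, float]
) -> Optional[float]:
    """Level where the false-alarm-corrected curve crosses 0.5, or None.

    Solved in closed form through the sigmoid inverse, then checked
    against the range; a monotone bracket search (brentq) confirms the
    root numerically when it lies inside the range.
    """
    g, d = params.gamma, params.delta
    # corrected 0.5 <=> raw P = g + 0.5 (1 - g) <=> S = 0.5 (1 - g) / (1 - d - g)
    denom = 1.0 - d - g
    if denom <= 0:
        return None
    s_target = 0.5 * (1.0 - g) / denom
    if not (0.0 < s_target < 1.0):
        return None
    x = _sigmoid_inv(s_target, params.m, params.w, params.sigmoid)
    lo, hi = level_range
    if not (lo < x < hi):
        return x  # reported, but classified on-limit by the caller

    def f(xx: float) -> float:
        return false_alarm_correct(predict(params, xx), g) - 0.5

    if f(lo) < 0 < f(hi):
        return float(optimize.brentq(f, lo, hi, xtol=1e-10 * max(1.0, hi - lo)))
    return x


class PsychometricModel:
    """Maximum-likelihood model for binomial yes/no detection data.

    Parameters
    ----------
    data : BinomialData
        Per-level trial and yes counts over strictly increasing levels.
    sigmoid : {"cumulative_gaussian", "logistic"}
        Shape of the underlying sigmoid S.
    bounds : dict, optional
        Box bounds per parameter name; defaults are data-driven:
        ``m`` within the level range padded by the width cap, ``w`` in
        (0, 2 x span], ``gamma``/``delta`` in [0, 0.1].
    fix_gamma : float, optional
        Freeze the false-alarm rate (e.g. at the empirical catch-trial
        rate) instead of estimating it.
    """

    def __init__(
        self,
        data: BinomialData,
        sigmoid: Sigmoid = "cumulative_gaussian",
        bounds: Optional[dict[str, tuple[float, float]]] = None,
        fix_gamma: Optional[float] = None,
        lapse_cap: float = DEFAULT_LAPSE_CAP,
    ) -> None:
        if data.levels.size < 4:
            raise ValueError("need at least 4 levels to fit four parameters")
        self.data = data
        self.sigmoid: Sigmoid = sigmoid
        self.fix_gamma = fix_gamma
        span = data.span
        w_max = 2.0 * span
        default = {
            "m": (data.levels[0] - w_max, data.levels[-1] + w_max),
            "w": (1e-6 * span, w_max),
            "gamma": (0.0, lapse_cap),
            "delta": (0.0, lapse_cap),
        }
        if bounds:
            default.update(bounds)
        self.bounds = default

    # -- likelihood ---------------------------------------------------
    def _params_from_vector(self, theta: np.ndarray) -> PsychometricParams:
        if self.fix_gamma is None:
            m, w, g, d = theta
        else:
            m, w, d = theta
            g = self.fix_gamma
        return PsychometricParams(float(m), float(w), float(g), float(d), self.sigmoid)

    def nloglik(self, theta: np.ndarray, _levels: Optional[np.ndarray] = None) -> float:
        # inlined for speed: called thousands of times per multi-start fit
        if self.fix_gamma is None:
            m, w, g, d = theta
        else:
            m, w, d = theta
            g = self.fix_gamma
        if w <= 0 or g < 0 or d < 0 or g + d >= 1:
            return float("inf")
        levels = self.data.levels if _levels is None else _levels
        s = _sigmoid(levels, m, w, self.sigmoid)
        p = np.clip(g + (1.0 - d - g) * s, CLAMP_EPS, 1.0 - CLAMP_EPS)
        return float(
            -np.sum(self.data.k_yes * np.log(p) + (self.data.n_trials - self.data.k_yes) * np.log1p(-p))
        )

    # -- fitting ------------------------------------------------------
    def _free_bounds(self) -> list[tuple[float, float]]:
        names = ["m", "w", "delta"] if self.fix_gamma is not None else ["m", "w", "gamma", "delta"]
        return [self.bounds[n] for n in names]

    def _heuristic_start(self) -> np.ndarray:
        """Moment-style start: midpoint crossing of the raw proportions."""
        d = self.data
        p = d.proportions
        lo, hi = p.min(), p.max()
        mid = 0.5 * (lo + hi)
        above = np.flatnonzero(p >= mid)
        m0 = d.levels[above[0]] if above.size else float(np.median(d.levels))
        start = {"m": m0, "w": 0.5 * d.span, "gamma": min(float(lo), 0.05), "delta": 0.02}
        names = ["m", "w", "delta"] if self.fix_gamma is not None else ["m", "w", "gamma", "delta"]
        theta = np.array([start[n] for n in names])
        lo_b, hi_b = np.array(self._free_bounds()).T
        return np.clip(theta, lo_b, hi_b)

    def fit(
        self,
        n_starts: int = DEFAULT_N_STARTS,
        seed: int = 0,
    ) -> "PsychometricResults":
        """Bounded multi-start ML fit (L-BFGS-B from Latin-hypercube starts).

        Deterministic given ``seed``.  Ties between converged starts are
        broken by lowest negative log-likelihood, then lowest width.

        The level axis is standardized internally (affine map to unit
        span) so the optimizer sees O(1) variables whatever the axis
        units; all reported parameters are in native units.
        """
        x0 = float(self.data.levels[0])
        scale = self.data.span

        def to_scaled(theta: np.ndarray) -> np.ndarray:
            out = np.array(theta, dtype=float)
            out[0] = (out[0] - x0) / scale
            out[1] = out[1] / scale
            return out

        def to_native(theta: np.ndarray) -> np.ndarray:
            out = np.array(theta, dtype=float)
            out[0] = x0 + out[0] * scale
            out[1] = out[1] * scale
            return out

        z_levels = (self.data.levels - x0) / scale
        bounds_native = self._free_bounds()
        bounds = [
            ((b[0] - x0) / scale, (b[1] - x0) / scale) if i == 0
            else (b[0] / scale, b[1] / scale) if i == 1
            else b
            for i, b in enumerate(bounds_native)
        ]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
        starts = [to_scaled(self._heuristic_start())]
        if n_starts > 1:
            starts.extend(lo + (hi - lo) * sampler.random(n_starts - 1))

        objective = lambda theta: self.nloglik(theta, _levels=z_levels)
        best: Optional[optimize.OptimizeResult] = None
        for theta0 in starts:
            res = optimize.minimize(
                objective, theta0, method="L-BFGS-B", bounds=bounds
            )
            if not res.success or not np.isfinite(res.fun):
                continue
            if (
                best is None
                or res.fun < best.fun - 1e-12
                or (abs(res.fun - best.fun) <= 1e-12 and res.x[1] < best.x[1])
            ):
                best = res

        if best is None:
            return PsychometricResults(
                model=self,
                params=None,
                neg_log_lik=float("nan"),
                valid=False,
                invalid_reason="fit_failed",
                threshold_corrected=None,
            )

        params = self._params_from_vector(to_native(best.x))
        return self._classify(params, float(best.fun))

    def _classify(self, params: PsychometricParams, nll: float) -> "PsychometricResults":
        """Apply the validity rules to a fitted parameter set."""
        levels = self.data.levels
        lo, hi = float(levels[0]), float(levels[-1])
        raw = np.asarray(predict(params, np.array([lo, hi])))
        reason: Optional[str] = None
        thr: Optional[float] = None
        # criterion 1: the fitted curve must reach P = 0.5 within the range
        if raw.max() < 0.5:
            reason = "did_not_reach_half"
        else:
            thr = _corrected_threshold(params, (lo, hi))
            # criterion 2: corrected threshold strictly inside the range
            tol = 1e-6 * (hi - lo)
            if thr is None or not (lo + tol < thr < hi - tol):
                reason = "threshold_on_limit"
        return PsychometricResults(
            model=self,
            params=params,
            neg_log_lik=nll,
            valid=reason is None,
            invalid_reason=reason,
            threshold_corrected=thr if reason is None else None,
        )


@dataclass
class PsychometricResults:
    """Results of a psychometric ML fit.

    Attributes
    ----------
    params : PsychometricParams or None
        Fitted (m, w, gamma, delta); None when every start failed.
    neg_log_lik : float
    valid : bool
        True when the curve reaches 0.5 and the corrected threshold lies
        strictly inside the tested level range.
    invalid_reason : str or None
        One of ``did_not_reach_half``, ``threshold_on_limit``,
        ``fit_failed``.
    threshold_corrected : float or None
        Level at which the false-alarm-corrected curve crosses 0.5.
    """

    model: PsychometricModel
    params: Optional[PsychometricParams]
    neg_log_lik: float
    valid: bool
    invalid_reason: Optional[str]
    threshold_corrected: Optional[float]
    ci: Optional[dict[str, tuple[float, float]]] = None

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        if self.params is None:
            raise ValueError("fit failed; no parameters to predict with")
        return predict(self.params, x)

    def bootstrap_ci(
        self, n_boot: int = 200, seed: int = 0, alpha: float = 0.05, n_starts: int = 4
    ) -> dict[str, tuple[float, float]]:
        """Parametric-bootstrap percentile intervals for (m, w, gamma, delta)."""
        if self.params is None:
            raise ValueError("fit failed; nothing to bootstrap")
        rng = np.random.default_rng(seed)
        data = self.model.data
        p = np.clip(predict(self.params, data.levels), 0.0, 1.0)
        draws = []
        for _ in range(n_boot):
            k = rng.binomial(data.n_trials, p)
            boot = BinomialData(data.levels, data.n_trials, k)
            res = PsychometricModel(
                boot,
                sigmoid=self.model.sigmoid,
                bounds=self.model.bounds,
                fix_gamma=self.model.fix_gamma,
            ).fit(n_starts=n_starts, seed=int(rng.integers(2**31 - 1)))
            if res.params is not None:
                draws.append(res.params.as_array())
        arr = np.array(draws)
        q = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        names = ["m", "w", "gamma", "delta"]
        ci = {
            name: (float(np.percentile(arr[:, i], q[0])), float(np.percentile(arr[:, i], q[1])))
            for i, name in enumerate(names)
        }
        self.ci = ci
        return ci

    def summary(self) -> str:
        lines = ["Psychometric mixture-model fit", "=" * 34]
        if self.params is None:
            lines.append("fit failed: no start converged")
            return "\n".join(lines)
        p = self.params
        lines += [
            f"sigmoid           {p.sigmoid}",
            f"levels            {self.model.data.levels.size} "
            f"({self.model.data.levels[0]:g} .. {self.model.data.levels[-1]:g})",
            f"trials            {int(self.model.data.n_trials.sum())}",
            "-" * 34,
            f"threshold m       {p.m:12.4f}",
            f"width w           {p.w:12.4f}",
            f"false-alarm gamma {p.gamma:12.4f}"
            + ("  (fixed)" if self.model.fix_gamma is not None else ""),
            f"lapse delta       {p.delta:12.4f}",
            f"neg. log-lik      {self.neg_log_lik:12.4f}",
            "-" * 34,
            f"valid             {self.valid}"
            + (f"  ({self.invalid_reason})" if self.invalid_reason else ""),
        ]
        if self.threshold_corrected is not None:
            lines.append(f"corrected thresh. {self.threshold_corrected:12.4f}")
        if self.ci:
            lines.append("-" * 34)
            for name, (a, b) in self.ci.items():
                lines.append(f"{name:>5s} 95% CI      [{a:.4f}, {b:.4f}]")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: observed proportions and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.plot(d.levels, d.proportions, "ko", label="observed")
        if self.params is not None:
            xs = np.linspace(d.levels[0], d.levels[-1], 200)
            ax.plot(xs, self.predict(xs), "-", label="fit")
            if self.threshold_corrected is not None:
                ax.axvline(self.threshold_corrected, color="gray", ls="--")
        ax.axhline(0.5, color="gray", ls=":", lw=0.8)
        ax.set_xlabel("stimulus level")
        ax.set_ylabel('proportion "change"')
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax


# Backwards-compatible alias: a fit result is the Results object.
FitResult = PsychometricResults


def fit_ml(
    data: BinomialData,
    sigmoid: Sigmoid = "cumulative_gaussian",
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    fix_gamma: Optional[float] = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> PsychometricResults:
    """Functional wrapper: build the model and fit in one call."""
    return PsychometricModel(data, sigmoid=sigmoid, bounds=bounds, fix_gamma=fix_gamma).fit(
        n_starts=n_starts, seed=seed
    )


def threshold(result: PsychometricResults, level_range: Optional[tuple[float, float]] = None) -> float:
    """Corrected-curve 0.5 crossing of a valid fit within ``level_range``."""
    if result.params is None:
        raise ValueError("fit failed; no threshold")
    if level_range is None:
        d = result.model.data
        level_range = (float(d.levels[0]), float(d.levels[-1]))
    thr = _corrected_threshold(result.params, level_range)
    lo, hi = level_range
    if thr is None or not (lo < thr < hi):
        raise ValueError("no corrected 0.5 crossing inside the level range")
    return thr
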