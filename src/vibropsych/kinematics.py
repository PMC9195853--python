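"""Temporally global intensity formulations of a stimulus waveform.

Intensity candidates are time-averages, over the entire stimulus, of a
power of the absolute velocity or acceleration of the skin-indentation
trajectory: |v|, v^2, |v|^3, |a|, a^2 and |a|^3.  Mean absolute
velocity (mean speed) is the classical one; for a pulse family that
varies only the pulse width at a fixed pulse rate and amplitude, mean
speed is constant (each pulse contributes the same path length 4A), so
the pulse-shape stimulus family lies on a mean-speed iso-feature line.

Derivatives are taken by central finite differences on the commanded
trajectory; closed-form oracles for the raised-cosine pulses bound the
discretization error (tests exercise them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimgen import TrainSpec, Waveform, make_train

__all__ = [
    "FORMULATIONS",
    "IntensityValue",
    "velocity",
    "acceleration",
    "intensity",
    "iso_feature_deviation",
    "intensity_of_spec",
]

# tag -> (kinematic base, exponent, units)
FORMULATIONS: dict[str, tuple[str, int, str]] = {
    "mean_abs_v": ("v", 1, "um/s"),
    "mean_sq_v": ("v", 2, "um^2/s^2"),
    "mean_abs_v_cubed": ("v", 3, "um^3/s^3"),
    "mean_abs_a": ("a", 1, "um/s^2"),
    "mean_sq_a": ("a", 2, "um^2/s^4"),
    "mean_abs_a_cubed": ("a", 3, "um^3/s^6"),
}


@dataclass(frozen=True)
class IntensityValue:
    formulation: str
    value: float
    units: str
    window_ms: float


def velocity(w: Waveform) -> np.ndarray:
    """Finite-difference velocity (µm/s): central interior, one-sided ends."""
    if w.samples.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(w.samples, 1.0 / w.sample_rate_hz)


def acceleration(w: Waveform) -> np.ndarray:
    """Finite-difference acceleration (µm/s²)."""
    if w.samples.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = np.gradient(w.samples, 1.0 / w.sample_rate_hz)
    return np.gradient(v, 1.0 / w.sample_rate_hz)


def intensity(w: Waveform, formulation: str, mode: str = "mean") -> IntensityValue:
    """Intensity of a waveform under one formulation.

    The canonical value is the time-mean of |v|^p or |a|^p over all
    samples of the stimulus, rest periods included.  ``mode="sum"``
    returns the summed variant (mean × sample count), which differs by a
    constant factor and cancels in within-formulation comparisons.
    """
    try:
        base, power, units = FORMULATIONS[formulation]
    except KeyError:
        raise ValueError(f"unknown intensity formulation {formulation!r}") from None
    series = velocity(w) if base == "v" else acceleration(w)
    values = np.abs(series) ** power
    out = float(values.sum()) if mode == "sum" else float(values.mean())
    return IntensityValue(formulation, out, units, w.duration_ms)


def intensity_of_spec(spec: TrainSpec, formulation: str, mode: str = "mean") -> float:
    """Convenience: synthesize the train and return the scalar intensity."""
    return intensity(make_train(spec), formulation, mode=mode).value


def iso_feature_deviation(family: list[TrainSpec], formulation: str) -> float:
    """Max relative deviation of an intensity across a stimulus family.

    Zero means the family lies exactly on an iso-feature line of the
    formulation; the pulse-shape family under mean speed stays below
    0.5% (discretization of pulse boundaries prevents exact equality).
    """
    if not family:
        raise ValueError("family must be non-empty")
    values = np.array([intensity_of_spec(s, formulation) for s in family])
    mean = values.mean()
    if mean == 0:
        return 0.0
    return float(np.max(np.abs(values - mean)) / mean)
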