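"""Three-component model of 305-day milk yield across lactations.

The yield of a group of cows at lactation ``t`` is modelled as

    y_m(t) = A * exp(-exp(-b * t)) * D**t

where ``A`` (kg) is the potential 305-d yield, the double-exponential
maturation factor describes growth of milking capacity with body and udder
development (plateauing around the 5th–6th lactation; ``b`` is typically
0.4–0.5 per lactation), and ``D <= 1`` is the per-lactation degradation
base — the multiplicative decline of the milk-production system's
functional capacity.  Its first-lactation value ``D^1 = D`` is a viability
indicator: groups with higher ``D`` stay in the herd longer, and across
groups ``D`` relates linearly to the last-lactation number ``t_max``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .core import LinearFit, linear_fit
from .errors import InsufficientDataError, InvalidInputError, NonInvertibleError

__all__ = [
    "MilkYieldParams",
    "YieldSeries",
    "GroupRecord",
    "DegradationFit",
    "milk_yield_curve",
    "fit_degradation",
    "regress_D_on_tmax",
    "predict_tmax",
]


@dataclass(frozen=True)
class MilkYieldParams:
    """Parameters (A, b, D) of the maturation-times-degradation yield model."""

    A: float
    b: float
    D: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise InvalidInputError("potential yield A must be non-negative")
        if not (0.2 <= self.b <= 1.0):
            raise InvalidInputError("maturation rate b outside plausible range [0.2, 1]")
        if not (0.0 < self.D <= 1.0):
            raise InvalidInputError("degradation base D must lie in (0, 1]")


@dataclass(frozen=True)
class YieldSeries:
    """305-d milk yields at consecutive lactations starting from 1."""

    t: np.ndarray
    ym: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=int)
        ym = np.asarray(self.ym, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ym", ym)
        if len(t) != len(ym) or len(t) == 0:
            raise InvalidInputError("t and ym must be non-empty and aligned")
        if t[0] != 1 or np.any(np.diff(t) != 1):
            raise InvalidInputError("lactations must be consecutive from 1")
        if np.any(ym <= 0):
            raise InvalidInputError("yields must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class GroupRecord:
    """A last-lactation group: its t_max label and estimated D."""

    t_max: int
    D: float

    def __post_init__(self) -> None:
        if self.t_max < 4:
            raise InvalidInputError("group analysis starts at last-lactation 4")


@dataclass(frozen=True)
class DegradationFit:
    """Result of estimating the degradation base from a yield series."""

    D: float
    A: float
    fit: LinearFit
    b_assumed: float
    window: Tuple[int, int]


def maturation_factor(b: float, t) -> np.ndarray:
    """The double-exponential maturation component exp(-exp(-b t))."""
    return np.exp(-np.exp(-b * np.asarray(t, dtype=float)))


def milk_yield_curve(params: MilkYieldParams, t) -> np.ndarray:
    """Evaluate y_m(t) = A * exp(-exp(-b t)) * D^t."""
    t = np.asarray(t, dtype=float)
    return params.A * maturation_factor(params.b, t) * params.D ** t


def fit_degradation(
    series: YieldSeries,
    b_assumed: float = 0.45,
    window: Tuple[int, int] = (4, 10),
    scale: str = "log",
) -> DegradationFit:
    """Estimate the degradation base D (and potential A) from a yield series.

    The maturation factor is divided out using an assumed ``b`` (default
    0.45, the midpoint of the usual 0.4–0.5 range — beyond lactation 4 the
    factor is nearly saturated, so the choice matters little), then a linear
    trend is fitted to the corrected yields over ``window`` (default
    lactations 4–10) and extrapolated back to the first lactation:
    on the log scale ``D = exp(slope)`` and ``A = exp(intercept)``, exactly
    unbiased under the multiplicative model.  ``scale="linear"`` instead
    fits ``A * D^t`` to the corrected yields by nonlinear least squares, for
    sensitivity checks against the log-scale default.
    """
    lo, hi = window
    mask = (series.t >= lo) & (series.t <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError("need at least 3 yields inside the window")
    t = series.t[mask].astype(float)
    corrected = series.ym[mask] / maturation_factor(b_assumed, t)
    if scale == "log":
        fit = linear_fit(t, np.log(corrected))
        D = float(np.exp(fit.slope))
        A = float(np.exp(fit.intercept))
    elif scale == "linear":
        (A, D), _ = curve_fit(
            lambda tt, a, d: a * d ** tt, t, corrected,
            p0=(float(corrected[0]), 0.95), maxfev=10000,
        )
        fit = LinearFit(slope=float(np.log(D)), intercept=float(np.log(A)), r=0.0)
        A, D = float(A), float(D)
    else:
        raise InvalidInputError(f"unknown scale {scale!r}")
    return DegradationFit(D=D, A=A, fit=fit, b_assumed=b_assumed, window=window)


def regress_D_on_tmax(groups: Sequence[GroupRecord]) -> LinearFit:
    """OLS of the degradation base D on the last-lactation number t_max."""
    if len(groups) < 3:
        raise InsufficientDataError("need at least 3 last-lactation groups")
    t_max = np.array([g.t_max for g in groups], dtype=float)
    D = np.array([g.D for g in groups], dtype=float)
    return linear_fit(t_max, D)


def predict_tmax(D: float, fit: LinearFit) -> float:
    """Invert a D-on-t_max regression: t_max = (D - intercept) / slope."""
    if fit.slope == 0:
        raise NonInvertibleError("zero slope: relation cannot be inverted")
    return (D - fit.intercept) / fit.slope
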