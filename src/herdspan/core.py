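"""Gompertz hazard, discrete disposal-rate transform, and parameter fitting.

The central object is a lactation-indexed life table: a cohort of dairy cows
observed at successive lactation numbers ``t = 1, 2, ...`` with counts
``N_t``.  The relative disposal rate (culling for the sum of involuntary
reasons plus death) per lactation,

    y_t = (N_t - N_{t+1}) / N_t,

is treated as a discrete-time hazard and modelled by the Gompertz law
``y(t) = B * exp(c * t)``: ``c`` is the aging rate, ``B`` the baseline level
of the hazard at ``t = 0``.  Fitting is ordinary least squares of ``ln y``
on ``t`` — the same estimate a spreadsheet "exponential trendline" produces,
which keeps the procedure reproducible by non-specialists with herd
registration tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    FitDomainError,
    InsufficientDataError,
    InvalidCohortError,
    SingularFitError,
    UndefinedRateError,
)

__all__ = [
    "CohortSeries",
    "DisposalSeries",
    "GompertzParams",
    "LinearFit",
    "compute_disposal_series",
    "gompertz_hazard",
    "fit_gompertz",
    "viability_index",
    "linear_fit",
]


@dataclass(frozen=True)
class CohortSeries:
    """Cohort counts at consecutive lactation numbers.

    Parameters
    ----------
    t : array of int
        Lactation numbers, consecutive with step 1, first entry >= 1.
    N : array of float
        Cohort counts, non-negative and non-increasing.  Real-valued:
        registration data are integers but model trajectories are not.
    """

    t: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=int)
        N = np.asarray(self.N, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "N", N)
        if t.ndim != 1 or N.ndim != 1 or len(t) != len(N):
            raise InvalidCohortError("t and N must be 1-d arrays of equal length")
        if len(t) < 1:
            raise InvalidCohortError("a cohort series cannot be empty")
        if t[0] < 1:
            raise InvalidCohortError("lactation numbers are 1-based")
        if np.any(np.diff(t) != 1):
            raise InvalidCohortError("lactation numbers must be consecutive")
        if np.any(N < 0):
            raise InvalidCohortError("cohort counts must be non-negative")
        if np.any(np.diff(N) > 1e-9):
            raise InvalidCohortError("cohort counts must be non-increasing")

    @classmethod
    def from_counts(cls, counts: Sequence[float], start: int = 1) -> "CohortSeries":
        counts = np.asarray(counts, dtype=float)
        return cls(t=np.arange(start, start + len(counts)), N=counts)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n1(self) -> float:
        return float(self.N[0])

    def rounded_counts(self) -> np.ndarray:
        """Counts rounded half-away-from-zero to whole cows (display only)."""
        return np.floor(self.N + 0.5).astype(int)


@dataclass(frozen=True)
class DisposalSeries:
    """Per-lactation exits derived from a cohort series.

    ``y`` is the relative disposal rate ``dN_t / N_t`` (the discrete Gompertz
    hazard), ``dn`` the exit fraction ``dN_t / N_1``, and ``dN`` the absolute
    exits.  Entries are labelled by the origin lactation ``t`` of each
    transition, matching how herd registration tables are laid out.
    """

    t: np.ndarray
    y: np.ndarray
    dn: np.ndarray
    dN: np.ndarray
    N: np.ndarray = field(repr=False, default=None)  # origin counts, for windows

    def __post_init__(self) -> None:
        for name in ("t", "y", "dn", "dN"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "t", self.t.astype(int))
        if self.N is not None:
            object.__setattr__(self, "N", np.asarray(self.N, dtype=float))
        if np.any(self.y < 0) or np.any(self.dn < 0) or np.any(self.dN < 0):
            raise InvalidCohortError("disposal quantities must be non-negative")
        if self.dn.sum() > 1 + 1e-9:
            raise InvalidCohortError("exit fractions cannot sum beyond 1")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz hazard ``y(t) = B * exp(c * t)``.

    ``B`` is the level at ``t = 0``; the hazard at the first lactation is
    ``B * exp(c)`` (exposed as :attr:`hazard_at_first` to avoid the common
    ambiguity between the two).  ``r2`` is the coefficient of determination
    of the log-linear fit that produced the parameters (1.0 for exact
    parameters).
    """

    B: float
    c: float
    r2: float = 1.0

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise InvalidCohortError("Gompertz baseline B must be positive")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise InvalidCohortError("r2 must lie in [0, 1]")

    @property
    def hazard_at_first(self) -> float:
        """Hazard evaluated at the first lactation, ``B * exp(c)``."""
        return self.B * float(np.exp(self.c))


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept of an ordinary least-squares line plus Pearson r."""

    slope: float
    intercept: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise SingularFitError("|r| cannot exceed 1")

    @property
    def r2(self) -> float:
        return self.r ** 2

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def compute_disposal_series(cohort: CohortSeries) -> DisposalSeries:
    """Transform cohort counts into per-lactation disposal quantities.

    For each transition t -> t+1: exits ``dN_t = N_t - N_{t+1}`` (positive
    by convention), relative rate ``y_t = dN_t / N_t``, exit fraction
    ``dn_t = dN_t / N_1``.  The result has one entry fewer than the cohort.

    Raises
    ------
    UndefinedRateError
        If any count before the last lactation is zero (the rate at that
        lactation has no denominator).
    """
    N = cohort.N
    if len(N) < 2:
        raise InvalidCohortError("need at least 2 lactations to form exits")
    if N[0] <= 0:
        raise UndefinedRateError("initial cohort size must be positive")
    if np.any(N[:-1] == 0):
        raise UndefinedRateError("zero count before the final lactation")
    dN = N[:-1] - N[1:]
    y = dN / N[:-1]
    dn = dN / N[0]
    return DisposalSeries(t=cohort.t[:-1], y=y, dn=dn, dN=dN, N=N[:-1])


def gompertz_hazard(params: GompertzParams, t) -> float | np.ndarray:
    """Evaluate ``B * exp(c * t)``.

    The value is a rate, not a probability: callers using it as a
    per-lactation exit probability must cap it at 1.
    """
    return params.B * np.exp(params.c * np.asarray(t, dtype=float))


def _default_window_mask(disposal: DisposalSeries) -> np.ndarray:
    """Points usable for the log-linear fit: 0 < y < 1, and not in the tail
    where the destination cohort has dropped below one cow."""
    mask = (disposal.y > 0) & (disposal.y < 1)
    if disposal.N is not None:
        dest = disposal.N - disposal.dN  # N_{t+1}
        mask &= dest >= 1
    return mask


def fit_gompertz(
    disposal: DisposalSeries,
    window: Optional[Tuple[int, int]] = None,
) -> GompertzParams:
    """Fit the Gompertz hazard by OLS of ``ln y_t`` on ``t``.

    Parameters
    ----------
    window : (lo, hi), optional
        Inclusive lactation range to fit over.  Default: all points with
        ``0 < y_t < 1``, excluding trailing points whose destination count
        is below one cow.

    Returns
    -------
    GompertzParams
        ``c`` = slope, ``B`` = exp(intercept at t = 0), ``r2`` from the
        log-scale regression.
    """
    t = disposal.t
    y = disposal.y
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if np.any(mask & (y <= 0)):
            raise FitDomainError("window contains non-positive rates")
    else:
        mask = _default_window_mask(disposal)
    if mask.sum() < 2:
        raise InsufficientDataError("need at least 2 usable points to fit")
    fit = linear_fit(t[mask].astype(float), np.log(y[mask]))
    return GompertzParams(B=float(np.exp(fit.intercept)), c=fit.slope, r2=fit.r2)


def viability_index(disposal: DisposalSeries) -> float:
    """Reciprocal first-lactation disposal rate, ``1/y_1 = N_1 / dN_1``.

    The herd-level viability indicator: it is maximal at the first lactation
    and is the predictor of average productive life span.
    """
    y1 = float(disposal.y[0])
    if y1 <= 0:
        raise UndefinedRateError("viability index undefined for y_1 = 0")
    return 1.0 / y1


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of y on x with Pearson r.

    A zero-variance response yields ``r = 0`` with a warning (a flat line is
    a legitimate fit); zero-variance x is a singular design and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise InsufficientDataError("need >= 2 paired points")
    if np.ptp(x) == 0:
        raise SingularFitError("predictor values are all equal")
    if np.ptp(y) == 0:
        warnings.warn("zero-variance response: Pearson r reported as 0", stacklevel=2)
        return LinearFit(slope=0.0, intercept=float(y[0]), r=0.0)
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=float(res.rvalue))
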