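"""Cohort forecasting by numerical integration of the Gompertz depletion
recursion, productive-life-span (PLS) statistics, and herd-turnover
indicator profiles.

The forecast restores a cohort trajectory from a hazard: starting from an
initial cohort size ``N_1``, counts are depleted lactation by lactation.
Two indexing conventions exist for which hazard value governs the
transition ``t -> t+1``:

* ``"destination"`` (default): the hazard at the *destination* lactation,
  ``N_{t+1} = N_t * (1 - y(t+1))``.  This is the convention that reproduces
  published worked integrations of herd registration tables.
* ``"origin"``: the hazard at the origin lactation,
  ``N_{t+1} = N_t * (1 - y(t))``.

The average productive life span is the exit-weighted mean lactation,
``T = sum_t dn_t * t``; the remnant still alive at the end of the series is
reported separately as a fraction of ``N_1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    CohortSeries,
    DisposalSeries,
    GompertzParams,
    LinearFit,
    compute_disposal_series,
    gompertz_hazard,
    linear_fit,
)
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "ForecastResult",
    "PLSPredictor",
    "integrate_cohort",
    "average_pls",
    "max_pls",
    "predict_T",
    "regress_T_on_viability",
    "turnover_profiles",
]

HazardSpec = Union[GompertzParams, Sequence[float]]


@dataclass(frozen=True)
class ForecastResult:
    """A predicted cohort trajectory with its summary statistics.

    Attributes
    ----------
    cohort : CohortSeries
        The integrated (predicted) counts, real-valued.
    T : float
        Average productive life span in lactations, ``sum dn_t * t`` over
        predicted exits (remnant excluded).
    t_max : int
        Predicted maximum life span: the last lactation with at least one
        cow before a stop condition fired.
    remnant_fraction : float
        ``N_last / N_1``, the fraction still in the herd at ``t_max``.
    stop_reason : str
        Why integration stopped: ``"hazard_capped"`` (next hazard >= 1),
        ``"depleted"`` (next count < 1 cow), ``"exhausted"`` (hazard
        sequence ended), or ``"horizon"``.
    """

    cohort: CohortSeries
    T: float
    t_max: int
    remnant_fraction: float
    stop_reason: str

    @property
    def horizon_limited(self) -> bool:
        return self.stop_reason == "horizon"


@dataclass(frozen=True)
class PLSPredictor:
    """Linear predictor of average PLS from the viability index 1/y_1."""

    fit: LinearFit

    @property
    def r2(self) -> float:
        return self.fit.r2


def _hazard_at(hazard: HazardSpec, t: int) -> Optional[float]:
    """Hazard value at lactation t, or None if a finite sequence ran out."""
    if isinstance(hazard, GompertzParams):
        return float(gompertz_hazard(hazard, t))
    seq = np.asarray(hazard, dtype=float)
    if t < 1 or t > len(seq):
        return None
    return float(seq[t - 1])


def integrate_cohort(
    hazard: HazardSpec,
    n1: float,
    horizon: int = 20,
    convention: str = "destination",
) -> ForecastResult:
    """Integrate the depletion recursion from an initial cohort size.

    Parameters
    ----------
    hazard : GompertzParams or sequence of float
        Either Gompertz parameters (hazard evaluated analytically) or an
        explicit per-lactation rate sequence ``y_1, y_2, ...`` indexed by
        lactation number.
    n1 : float
        Initial cohort size at the first lactation (must be positive).
    horizon : int
        Maximum lactation number to integrate to.
    convention : {"destination", "origin"}
        Which lactation's hazard drives each transition (see module notes).

    The recursion stops when the driving hazard reaches 1 (every remaining
    cow would exit), when the next count would fall below one cow, when an
    explicit hazard sequence is exhausted, or at the horizon.  Counts are
    kept real-valued; use :meth:`CohortSeries.rounded_counts` for display.
    """
    if n1 <= 0:
        raise InvalidInputError("initial cohort size must be positive")
    if convention not in ("destination", "origin"):
        raise InvalidInputError(f"unknown convention {convention!r}")
    if horizon < 2:
        raise InvalidInputError("horizon must be at least 2 lactations")

    counts = [float(n1)]
    stop_reason = "horizon"
    for t in range(1, horizon):
        rate = _hazard_at(hazard, t + 1 if convention == "destination" else t)
        if rate is None:
            stop_reason = "exhausted"
            break
        if rate < 0:
            raise InvalidInputError("hazards must be non-negative")
        if rate >= 1:
            stop_reason = "hazard_capped"
            break
        nxt = counts[-1] * (1.0 - rate)
        if nxt < 1:
            stop_reason = "depleted"
            break
        counts.append(nxt)
    cohort = CohortSeries.from_counts(counts)
    disposal = compute_disposal_series(cohort) if len(cohort) >= 2 else None
    T = average_pls(disposal) if disposal is not None else 0.0
    return ForecastResult(
        cohort=cohort,
        T=T,
        t_max=int(cohort.t[-1]),
        remnant_fraction=float(cohort.N[-1] / cohort.N[0]),
        stop_reason=stop_reason,
    )


def average_pls(disposal: DisposalSeries) -> float:
    """Average productive life span ``T = sum_t dn_t * t`` over observed exits.

    The remnant cohort (cows still present at the last observed lactation)
    is not folded in; its weight is available as the remnant fraction.
    """
    if len(disposal) == 0:
        raise InsufficientDataError("empty disposal series")
    return float(np.sum(disposal.dn * disposal.t))


def max_pls(forecast: ForecastResult) -> int:
    """Predicted maximum life span: last lactation with >= 1 cow."""
    return forecast.t_max


def predict_T(index: float, predictor: PLSPredictor) -> float:
    """Predict average PLS from the viability index 1/y_1."""
    return predictor.fit.predict(index)


def regress_T_on_viability(pairs: Sequence[Tuple[float, float]]) -> PLSPredictor:
    """Fit the linear relation T = a * (1/y_1) + b across herds.

    Requires at least 3 (viability index, T) pairs.
    """
    if len(pairs) < 3:
        raise InsufficientDataError("need at least 3 (1/y1, T) pairs")
    arr = np.asarray(pairs, dtype=float)
    return PLSPredictor(fit=linear_fit(arr[:, 0], arr[:, 1]))


def turnover_profiles(disposal: DisposalSeries) -> pd.DataFrame:
    """The three herd-turnover indicator profiles, aligned on lactation.

    Columns
    -------
    y : relative disposal rate (the discrete Gompertz hazard).
    viability : 1/y, the viability indicator (NaN where y = 0).
    partial_pls : dn_t * t, the partial productive life span — the relative
        number of cows whose productive life equals that lactation number.
        Its column sum is the average PLS.
    """
    with np.errstate(divide="ignore"):
        inv = np.where(disposal.y > 0, 1.0 / disposal.y, np.nan)
    return pd.DataFrame(
        {
            "y": disposal.y,
            "viability": inv,
            "partial_pls": disposal.dn * disposal.t,
        },
        index=pd.Index(disposal.t, name="lactation"),
    )
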