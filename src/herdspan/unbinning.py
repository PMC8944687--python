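"""Reconstruction of per-lactation cohort counts from binned herd tables.

Herd age-composition reports often pool older animals into multi-lactation
bins (e.g. lactations 1, 2, 3 reported singly, then 4–5, 6–7, 8–9, 10+).
Life-table analysis needs per-lactation counts, so the multi-lactation bins
must be disaggregated.  The reconstruction here selects corrective split
coefficients by projection onto the Gompertz depletion trend: single-
lactation bins anchor an initial hazard fit, each pooled bin is split in
proportion to the fitted depletion trajectory (preserving the bin sum
exactly), the hazard is refitted to the full reconstructed series, and the
scheme iterates to convergence of the split fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CohortSeries,
    GompertzParams,
    compute_disposal_series,
    fit_gompertz,
    gompertz_hazard,
    linear_fit,
)
from .errors import InvalidCompositionError

__all__ = [
    "Bin",
    "CompositionTable",
    "MeanComposition",
    "DEFAULT_BIN_SCHEME",
    "resolve_bins",
    "mean_composition",
    "reconstruct_series",
]

#: A bin is an inclusive (lo, hi) lactation range; hi=None means open-ended.
Bin = Tuple[int, Optional[int]]

#: The standard reporting scheme: 1, 2, 3, 4–5, 6–7, 8–9, 10 and more.
DEFAULT_BIN_SCHEME: Tuple[Bin, ...] = (
    (1, 1), (2, 2), (3, 3), (4, 5), (6, 7), (8, 9), (10, None),
)


def resolve_bins(bins: Sequence[Bin], last_bin_width: int = 2) -> List[Tuple[int, int]]:
    """Close an open-ended final bin and validate ordering/contiguity."""
    resolved: List[Tuple[int, int]] = []
    for i, (lo, hi) in enumerate(bins):
        if hi is None:
            if i != len(bins) - 1:
                raise InvalidCompositionError("only the last bin may be open-ended")
            hi = lo + last_bin_width - 1
        if hi < lo:
            raise InvalidCompositionError(f"bin ({lo}, {hi}) is empty")
        resolved.append((int(lo), int(hi)))
    for (lo0, hi0), (lo1, _) in zip(resolved, resolved[1:]):
        if lo1 != hi0 + 1:
            raise InvalidCompositionError("bins must be contiguous and ordered")
    if resolved[0][0] != 1:
        raise InvalidCompositionError("bins must start at lactation 1")
    return resolved


@dataclass(frozen=True)
class CompositionTable:
    """Per-year herd age composition: totals plus percentages per bin."""

    bins: Tuple[Bin, ...]
    years: Tuple[int, ...]
    totals: Tuple[float, ...]
    percentages: Tuple[Tuple[float, ...], ...]  # one row per year

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple((lo, hi) for lo, hi in self.bins))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "totals", tuple(float(x) for x in self.totals))
        object.__setattr__(
            self, "percentages", tuple(tuple(map(float, row)) for row in self.percentages)
        )
        if not (len(self.years) == len(self.totals) == len(self.percentages)):
            raise InvalidCompositionError("years, totals and percentage rows must align")
        if len(self.years) == 0:
            raise InvalidCompositionError("need at least one year")
        resolve_bins(self.bins)  # structural check
        for year, row in zip(self.years, self.percentages):
            if len(row) != len(self.bins):
                raise InvalidCompositionError(f"year {year}: wrong number of bins")
            if abs(sum(row) - 100.0) > 0.5:
                raise InvalidCompositionError(
                    f"year {year}: percentages sum to {sum(row):g}, not 100 +/- 0.5"
                )

    def counts(self) -> np.ndarray:
        """Per-year per-bin counts, total * pct / 100."""
        return np.asarray(self.totals)[:, None] * np.asarray(self.percentages) / 100.0


@dataclass(frozen=True)
class MeanComposition:
    """Across-year means of a composition table."""

    bins: Tuple[Bin, ...]
    mean_total: float
    mean_pct: np.ndarray
    mean_counts: np.ndarray


def mean_composition(table: CompositionTable) -> MeanComposition:
    """Arithmetic means over years: percentages, per-bin counts, and total."""
    return MeanComposition(
        bins=table.bins,
        mean_total=float(np.mean(table.totals)),
        mean_pct=np.mean(np.asarray(table.percentages), axis=0),
        mean_counts=table.counts().mean(axis=0),
    )


def _initial_params(bins: List[Tuple[int, int]], counts: np.ndarray) -> GompertzParams:
    """Anchor fit from the leading single-lactation bins."""
    singles = [(lo, n) for (lo, hi), n in zip(bins, counts) if lo == hi]
    t = np.array([s[0] for s in singles], dtype=float)
    n = np.array([s[1] for s in singles], dtype=float)
    y = (n[:-1] - n[1:]) / n[:-1]
    fit = linear_fit(t[:-1], np.log(y))
    return GompertzParams(B=float(np.exp(fit.intercept)), c=fit.slope,
                          r2=min(fit.r2, 1.0))


def _trajectory(params: GompertzParams, horizon: int) -> np.ndarray:
    """Relative depletion trajectory under the fitted origin-labelled hazard."""
    M = np.empty(horizon)
    M[0] = 1.0
    for t in range(1, horizon):
        rate = min(float(gompertz_hazard(params, t)), 0.999)
        M[t] = M[t - 1] * (1.0 - rate)
    return M


def reconstruct_series(
    bin_counts: Sequence[float],
    bins: Sequence[Bin] = DEFAULT_BIN_SCHEME,
    last_bin_width: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CohortSeries:
    """Disaggregate binned counts into per-lactation cohort counts.

    Parameters
    ----------
    bin_counts : per-bin counts (e.g. across-year mean counts), positive.
    bins : bin scheme; the first three bins must be single lactations, which
        anchor the initial Gompertz trend.
    last_bin_width : lactations assigned to an open-ended final bin.

    Returns
    -------
    CohortSeries whose within-bin sums equal the inputs exactly (before any
    display rounding) and whose counts decrease strictly.

    Raises
    ------
    InvalidCompositionError
        If per-lactation bin means increase along the series (no decreasing
        reconstruction exists) or the anchor precondition fails.
    """
    resolved = resolve_bins(bins, last_bin_width=last_bin_width)
    counts = np.asarray(bin_counts, dtype=float)
    if len(counts) != len(resolved):
        raise InvalidCompositionError("one count per bin required")
    if np.any(counts <= 0):
        raise InvalidCompositionError("bin counts must be positive")
    if any(lo != hi for lo, hi in resolved[:3]):
        raise InvalidCompositionError("first three bins must be single lactations")
    widths = np.array([hi - lo + 1 for lo, hi in resolved], dtype=float)
    per_lact_mean = counts / widths
    if np.any(np.diff(per_lact_mean) >= 0):
        raise InvalidCompositionError("per-lactation bin means must decrease")

    horizon = resolved[-1][1]
    if all(lo == hi for lo, hi in resolved):
        return CohortSeries.from_counts(counts)

    params = _initial_params(resolved, counts)
    fractions = None
    converged = False
    series = None
    for _ in range(max_iter):
        M = _trajectory(params, horizon)
        series = np.empty(horizon)
        new_fractions = []
        for (lo, hi), n in zip(resolved, counts):
            seg = M[lo - 1 : hi]
            frac = seg / seg.sum()
            series[lo - 1 : hi] = n * frac
            new_fractions.extend(frac)
        new_fractions = np.asarray(new_fractions)
        if fractions is not None and np.max(np.abs(new_fractions - fractions)) < tol:
            converged = True
            break
        fractions = new_fractions
        disposal = compute_disposal_series(CohortSeries.from_counts(series))
        params = fit_gompertz(disposal, window=(1, horizon))
    if not converged:
        warnings.warn("reconstruction did not converge; returning best iterate",
                      stacklevel=2)
    if np.any(np.diff(series) >= 0):
        warnings.warn("reconstructed series is not strictly decreasing", stacklevel=2)
    return CohortSeries.from_counts(series)
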