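"""Seeded generators for cohort, mixture, composition and yield data.

These produce data with exactly the statistical structure the estimators
assume: cohorts depleted by a Gompertz hazard (expected-value trajectories
or integer counts with binomial exit noise), 305-d yield trajectories from
the maturation-times-degradation model with multiplicative lognormal noise,
and binned composition tables as the forward partner of the unbinning
reconstruction.  Every stochastic path draws from one seeded generator per
call — never global state — so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import CohortSeries, GompertzParams, gompertz_hazard
from .errors import InvalidInputError
from .forecast import integrate_cohort
from .heterogeneity import MixtureSpec, simulate_mixture
from .milk import MilkYieldParams, YieldSeries, milk_yield_curve
from .unbinning import Bin, CompositionTable, resolve_bins

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_yields",
    "bin_series",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for the generators.

    mode : "expected" (deterministic trajectories) or "binomial"
        (integer exits drawn per transition).
    noise_sd : standard deviation of multiplicative lognormal yield noise,
        as a fraction (0.05 = 5%).
    """

    seed: Optional[int] = None
    mode: str = "expected"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("expected", "binomial"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if self.mode == "binomial" and self.seed is None:
            raise InvalidInputError("stochastic mode requires a seed")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _binomial_cohort(
    hazard, n1: int, horizon: int, convention: str, rng: np.random.Generator
) -> CohortSeries:
    counts = [int(n1)]
    for t in range(1, horizon):
        lact = t + 1 if convention == "destination" else t
        if isinstance(hazard, GompertzParams):
            rate = float(gompertz_hazard(hazard, lact))
        else:
            seq = np.asarray(hazard, dtype=float)
            if lact > len(seq):
                break
            rate = float(seq[lact - 1])
        rate = min(rate, 1.0)
        exits = int(rng.binomial(counts[-1], rate))
        nxt = counts[-1] - exits
        counts.append(nxt)
        if nxt == 0:
            break
    return CohortSeries.from_counts(counts)


def generate_cohort(
    spec: Union[GompertzParams, MixtureSpec, Sequence[float]],
    n1: Optional[float] = None,
    config: SimulationConfig = SimulationConfig(),
    horizon: int = 20,
    convention: str = "destination",
) -> CohortSeries:
    """Generate a cohort series under a Gompertz (or mixture) hazard.

    In expected-value mode this reproduces the deterministic integration
    exactly; in binomial mode each transition draws exits from
    ``Binomial(N_t, min(1, rate))`` where the rate follows the chosen
    convention (destination by default, mirroring the integrator).
    Mixtures are only available in expected-value mode.
    """
    if isinstance(spec, MixtureSpec):
        if config.mode != "expected":
            raise InvalidInputError("binomial mode is per-cohort; pass GompertzParams")
        return simulate_mixture(spec, horizon=horizon)
    if n1 is None:
        raise InvalidInputError("n1 is required for a single-cohort spec")
    if config.mode == "expected":
        return integrate_cohort(spec, n1, horizon=horizon, convention=convention).cohort
    return _binomial_cohort(spec, int(n1), horizon, convention, config.rng())


def generate_yields(
    params: MilkYieldParams,
    t_max: int,
    config: SimulationConfig = SimulationConfig(),
) -> YieldSeries:
    """305-d yield trajectory for lactations 1..t_max with lognormal noise.

    ``ym_t = y_m(t) * exp(eps_t)`` with ``eps_t ~ Normal(0, noise_sd)``.
    With ``noise_sd = 0`` the model values are returned exactly.
    """
    if t_max < 1:
        raise InvalidInputError("t_max must be at least 1")
    t = np.arange(1, t_max + 1)
    ym = milk_yield_curve(params, t)
    if config.noise_sd > 0:
        if config.seed is None:
            raise InvalidInputError("noisy yields require a seed")
        ym = ym * np.exp(config.rng().normal(0.0, config.noise_sd, size=len(t)))
    return YieldSeries(t=t, ym=ym)


def bin_series(
    cohort: CohortSeries,
    bins: Sequence[Bin],
    year: int = 0,
    last_bin_width: int = 2,
) -> CompositionTable:
    """Aggregate a cohort series into a one-row composition table.

    The forward partner of the unbinning reconstruction: bin sums are exact
    and percentages are taken against the series total.  The bins must
    cover the series exactly.
    """
    resolved = resolve_bins(bins, last_bin_width=last_bin_width)
    if resolved[-1][1] != int(cohort.t[-1]) or resolved[0][0] != int(cohort.t[0]):
        raise InvalidInputError("bin scheme does not cover the cohort series")
    sums = []
    for lo, hi in resolved:
        sel = (cohort.t >= lo) & (cohort.t <= hi)
        sums.append(float(cohort.N[sel].sum()))
    total = float(cohort.N.sum())
    pct = [100.0 * s / total for s in sums]
    return CompositionTable(
        bins=tuple(bins), years=(year,), totals=(total,), percentages=(tuple(pct),)
    )
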