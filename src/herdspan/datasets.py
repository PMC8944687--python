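"""Built-in worked datasets.

Published herd-registration material for the Tosnensky district dairy herd
(Leningrad oblast, 1985–1988, Black-and-White cows): the four-year age
composition table, the reconstructed per-lactation cohort, and the
life-table rates derived from it; the four reference model populations used
to demonstrate the heterogeneity (Strehler–Mildvan) artifact; and the
published linear relations linking the viability indicators to productive
life span.  These let every analysis in the package be run end-to-end
without external files.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .core import CohortSeries, LinearFit
from .forecast import PLSPredictor
from .heterogeneity import MixtureSpec, SubcohortSpec
from .unbinning import DEFAULT_BIN_SCHEME, CompositionTable

__all__ = [
    "tosno_composition",
    "tosno_cohort",
    "TOSNO_PRINTED_RATES",
    "model_populations",
    "PLS_FROM_VIABILITY",
    "D_VS_TMAX",
    "D_VS_TMAX_SECOND_HERD",
]


def tosno_composition() -> CompositionTable:
    """Age composition of the Tosnensky district herd, 1985–1988.

    Bins: lactations 1, 2, 3, 4–5, 6–7, 8–9, 10 and more; one row per year
    with the herd total and the percentage in each bin.
    """
    return CompositionTable(
        bins=DEFAULT_BIN_SCHEME,
        years=(1985, 1986, 1987, 1988),
        totals=(20528, 20747, 20897, 20596),
        percentages=(
            (28.4, 21.6, 17.0, 21.1, 8.4, 2.8, 0.7),
            (27.4, 21.8, 17.5, 20.7, 9.3, 2.7, 0.6),
            (28.6, 20.9, 17.1, 21.6, 8.7, 2.6, 0.5),
            (28.2, 20.8, 17.2, 22.3, 8.4, 2.6, 0.5),
        ),
    )


def tosno_cohort() -> CohortSeries:
    """Reconstructed per-lactation cohort counts for the Tosnensky herd.

    Mean counts across 1985–1988 with the pooled 4–5 … 10+ bins restored to
    individual lactations 1..11.
    """
    return CohortSeries.from_counts(
        [5825, 4402, 3559, 2637, 1716, 1091, 675, 355, 185, 87, 31]
    )


#: Published per-lactation relative disposal rates y_t for the Tosnensky
#: cohort (lactations 1..10), as printed in the worked life table.  Late
#: rows were computed from rounded intermediate exits, so they differ from
#: the count ratios in the third decimal (e.g. 0.650 vs 56/87 = 0.644);
#: the printed values are the canonical input for reproducing the worked
#: integration.
TOSNO_PRINTED_RATES = np.array(
    [0.244, 0.192, 0.259, 0.349, 0.364, 0.381, 0.474, 0.480, 0.526, 0.650]
)

#: Published per-lactation retention factors 1 - y_t (four decimals) used in
#: the worked numerical integration from N_1 = 1500.  They carry one more
#: digit than the rate column (0.8085 vs 1 - 0.192), and the published
#: integrated counts are only reproduced at this precision.
TOSNO_PRINTED_RETENTION = np.array(
    [0.7558, 0.8085, 0.7410, 0.6506, 0.6359, 0.6188, 0.5256, 0.5200, 0.4735, 0.3500]
)

#: The rate sequence implied by the retention column; canonical input for
#: reproducing the worked integration (lactations 1..10).
TOSNO_INTEGRATION_RATES = 1.0 - TOSNO_PRINTED_RETENTION


def model_populations() -> Dict[int, MixtureSpec]:
    """The four reference model populations (common aging rate c = 0.15).

    MP1 is homogeneous; MP2 mixes two and MP3/MP4 three subcohorts that
    differ in baseline hazard B and initial size, producing progressively
    stronger attenuation of the apparent aging rate.
    """
    c = 0.15
    return {
        1: MixtureSpec(subcohorts=(SubcohortSpec(0.10, c, 1000),), label="MP1"),
        2: MixtureSpec(
            subcohorts=(SubcohortSpec(0.15, c, 600), SubcohortSpec(0.09, c, 400)),
            label="MP2",
        ),
        3: MixtureSpec(
            subcohorts=(
                SubcohortSpec(0.22, c, 300),
                SubcohortSpec(0.15, c, 300),
                SubcohortSpec(0.10, c, 400),
            ),
            label="MP3",
        ),
        4: MixtureSpec(
            subcohorts=(
                SubcohortSpec(0.26, c, 300),
                SubcohortSpec(0.20, c, 300),
                SubcohortSpec(0.11, c, 400),
            ),
            label="MP4",
        ),
    }


#: Published predictor of average productive life span from the viability
#: index across 15 Leningrad-oblast production units:
#: T = 0.26 * (1/y_1) + 1.2, R^2 = 0.99.
PLS_FROM_VIABILITY = PLSPredictor(
    fit=LinearFit(slope=0.26, intercept=1.2, r=float(np.sqrt(0.99)))
)

#: Published relation between the degradation base and last-lactation
#: number across seven Kholmogor last-lactation groups:
#: D = 0.88 + 0.008 * t_max  (r = 0.94), i.e. t_max = 125 D - 110.
D_VS_TMAX = LinearFit(slope=0.008, intercept=0.88, r=0.94)

#: The same relation in a second, smaller White-and-Black herd (n = 195):
#: D = 0.88 + 0.012 * t_max  (r = 0.84), i.e. t_max = 83 D - 73.
D_VS_TMAX_SECOND_HERD = LinearFit(slope=0.012, intercept=0.88, r=0.84)
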