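"""Published summary data from the Burkina Faso hybrid-maize trial network.

The underlying plot-level field records of the nine-location, nine-genotype
2018/2019 hybrid maize evaluation were never deposited; what is public are
summary tables.  This module carries those published summaries as in-memory
fixtures:

- the genotype x environment matrix of mean grain yields (t/ha) with the
  missing cells of genotypes not grown at some locations,
- the per-location printed genotypic/phenotypic variance, mean and
  heritability for grain yield,
- the genotype registry (commercial codes, designations, hybrid class).

Location codes: NEB1/NEB2 = Neboum 1/2, TM = Toumousseni, BAM = Bama,
SG = Soungalodaga, FN = Fina, DAK = Dakoro, YEN = Yendere, PD = Poundou.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trial_data import GenotypeRecord

ENVIRONMENT_CODES = ["NEB1", "NEB2", "TM", "BAM", "SG", "FN", "DAK", "YEN", "PD"]
GENOTYPE_CODES = [f"SD{i}" for i in range(1, 10)]

_NA = np.nan

# mean grain yield (t/ha) per genotype (row) and location (column);
# NaN where the genotype was not evaluated at that location
_YIELDS = [
    #  NEB1    NEB2    TM      BAM     SG      FN      DAK     YEN     PD
    [6.992, 6.524, 5.794, 9.054, 8.714, 6.522, 7.788, 7.971, 4.016],  # SD1
    [5.344, 6.063, 5.982, 6.488, 6.081, 4.315, 5.868, 4.134, 2.096],  # SD2
    [5.027, 5.724, 4.324, 5.521, 7.683, 5.648, 4.900, 6.063, 2.932],  # SD3
    [6.221, 5.644, 5.816, 7.249, 7.734, 6.480, 6.480, 4.775, 1.591],  # SD4
    [6.652, 6.283, 5.854, 6.451, 7.462, 4.333, 5.557, 7.543, 2.584],  # SD5
    [5.987, 3.853, 4.766, 8.272, 9.385, 5.636, 5.636, 3.217, 1.829],  # SD6
    [4.237, 3.777, 3.893, 5.543, 4.191, 2.004, _NA, 3.681, 1.060],    # SD7
    [_NA, _NA, _NA, 3.774, _NA, _NA, 2.528, _NA, _NA],                # SD8
    [4.626, 3.797, 2.960, _NA, 5.227, 2.786, 4.137, 2.675, 2.241],    # SD9
]

# per-location published grain-yield genetics: genotypic variance sigma_g2,
# phenotypic variance sigma_p2, location mean (t/ha), printed heritability
_YIELD_GENETICS = {
    "BAM": (2.59, 2.78, 5.08, 0.93),
    "DAK": (2.10, 2.50, 5.36, 0.84),
    "FN": (1.74, 2.35, 4.50, 0.74),
    "NEB1": (0.88, 0.96, 5.63, 0.91),
    "NEB2": (1.21, 1.42, 5.21, 0.85),
    "PD": (0.74, 0.81, 2.29, 0.91),
    "SG": (2.90, 3.11, 7.06, 0.93),
    "TM": (1.15, 1.26, 9.92, 0.91),
    "YEN": (3.75, 3.95, 5.01, 0.95),
}

#: Locations whose published mean-yield entry equals the column mean of the
#: published yield matrix at 2 decimals.  FN and TM are excluded: their
#: printed means (4.50, 9.92) disagree with their own column means (4.72,
#: 4.92), almost certainly typographically.
RECONCILABLE_MEAN_LOCATIONS = ["SG", "DAK", "YEN", "PD", "NEB2"]


def published_yield_matrix() -> pd.DataFrame:
    """Genotype x environment mean grain yields (t/ha), missing cells NaN."""
    return pd.DataFrame(_YIELDS, index=GENOTYPE_CODES, columns=ENVIRONMENT_CODES, dtype=float)


def published_yield_genetics() -> pd.DataFrame:
    """Per-location published sigma_g2, sigma_p2, mean yield and heritability."""
    return pd.DataFrame.from_dict(
        _YIELD_GENETICS, orient="index", columns=["sigma_g2", "sigma_p2", "mean", "h2"]
    ).rename_axis("environment")


def genotype_registry() -> list[GenotypeRecord]:
    """The nine evaluated hybrids: six commercial single/double crosses and
    three national checks."""
    return [
        GenotypeRecord("SD1", "WE3205", "single_cross", "KENYA"),
        GenotypeRecord("SD2", "WE4207", "single_cross", "SOUTH AFRICA"),
        GenotypeRecord("SD3", "SNK2778", "double_cross", "NIGERIA/ZAMBIA"),
        GenotypeRecord("SD4", "DK920", "single_cross", "NIGERIA"),
        GenotypeRecord("SD5", "DK234", "single_cross", "NIGERIA"),
        GenotypeRecord("SD6", "DK818", "single_cross", "NIGERIA"),
        GenotypeRecord("SD7", "SR21", "national_hybrid", "BURKINA FASO"),
        GenotypeRecord("SD8", "BONDOFA", "national_hybrid", "BURKINA FASO"),
        GenotypeRecord("SD9", "KOMSAYA", "composite", "BURKINA FASO"),
    ]


def missing_pattern() -> list[tuple[str, str]]:
    """(environment, genotype) pairs absent from the published yield matrix."""
    mat = published_yield_matrix()
    return [
        (env, geno)
        for geno in mat.index
        for env in mat.columns
        if pd.isna(mat.at[geno, env])
    ]
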