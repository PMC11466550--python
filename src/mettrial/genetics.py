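"""Variance components, broad-sense heritability and coefficients of variation.

Method-of-moments estimators from the per-environment RCBD mean squares:

    sigma_g^2 = (MS_geno - MS_error) / r      (truncated at 0, flagged)
    sigma_e^2 = MS_error / r
    sigma_p^2 = MS_geno / r  =  sigma_g^2 + sigma_e^2   (before truncation)

    H^2  = sigma_g^2 / sigma_p^2              (broad-sense heritability)
    GCV  = 100 * sqrt(sigma_g^2) / mean       (genotypic CV, %)
    PCV  = 100 * sqrt(sigma_p^2) / mean       (phenotypic CV, %)

Note the algebraic identity H^2 = 1 - MS_error/MS_geno whenever
MS_geno >= MS_error; it is asserted in the test suite against the two-step
computation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .anova import AnovaTable, anova_rcbd, least_significant_difference, residual_cv
from .trial_data import TrialDataset, TrialDataWarning


@dataclass(frozen=True)
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    sigma_p2: float
    negative_truncated: bool


@dataclass
class GeneticParams:
    environment: str
    trait: str
    sigma_g2: float
    sigma_e2: float
    sigma_p2: float
    h2: float
    gcv_pct: float
    pcv_pct: float
    mean: float
    p_genotype: float
    cv_pct: float
    lsd_5pct: float
    negative_truncated: bool


def variance_components(table: AnovaTable) -> VarianceComponents:
    """Genotypic, environmental (error) and phenotypic variance from an ANOVA."""
    if table.r <= 0:
        raise ValueError("number of replicates must be positive")
    sigma_e2 = table.ms_error / table.r
    sigma_g2_raw = (table.ms_geno - table.ms_error) / table.r
    truncated = sigma_g2_raw < 0
    sigma_g2 = max(sigma_g2_raw, 0.0)
    # phenotypic variance stays MS_geno / r = sigma_g2_raw + sigma_e2 untruncated
    sigma_p2 = table.ms_geno / table.r
    return VarianceComponents(sigma_g2, sigma_e2, sigma_p2, truncated)


def heritability(sigma_g2: float, sigma_p2: float) -> float:
    """Broad-sense heritability H^2 = sigma_g^2 / sigma_p^2.

    Returns NaN when the phenotypic variance is zero (undefined ratio);
    the result is clipped to [0, 1] against rounding overshoot.
    """
    if sigma_g2 < 0 or sigma_p2 < 0:
        raise ValueError("variances must be non-negative")
    if sigma_p2 == 0:
        return math.nan
    return min(max(sigma_g2 / sigma_p2, 0.0), 1.0)


def gcv_pcv(sigma_g2: float, sigma_p2: float, mean: float) -> tuple[float, float]:
    """Genotypic and phenotypic coefficients of variation, percent of the mean."""
    if mean <= 0:
        raise ValueError(f"trait mean must be positive for a CV, got {mean}")
    if sigma_g2 < 0 or sigma_p2 < 0:
        raise ValueError("variances must be non-negative")
    return 100.0 * math.sqrt(sigma_g2) / mean, 100.0 * math.sqrt(sigma_p2) / mean


def genetic_params_from_anova(table: AnovaTable, alpha: float = 0.05) -> GeneticParams:
    vc = variance_components(table)
    h2 = heritability(vc.sigma_g2, vc.sigma_p2)
    gcv, pcv = gcv_pcv(vc.sigma_g2, vc.sigma_p2, table.grand_mean)
    return GeneticParams(
        environment=table.environment,
        trait=table.trait,
        sigma_g2=vc.sigma_g2,
        sigma_e2=vc.sigma_e2,
        sigma_p2=vc.sigma_p2,
        h2=h2,
        gcv_pct=gcv,
        pcv_pct=pcv,
        mean=table.grand_mean,
        p_genotype=table.p_genotype,
        cv_pct=residual_cv(table),
        lsd_5pct=least_significant_difference(table, alpha),
        negative_truncated=vc.negative_truncated,
    )


def genetic_report(
    dataset: TrialDataset,
    traits: Optional[Sequence[str]] = None,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (environment x trait) genetic-parameter table.

    One row per combination: heritability, variance components, GCV/PCV,
    mean, genotype-effect p-value, residual CV and LSD.  Environments where
    the ANOVA fails for a trait are reported in an ``error`` column rather
    than aborting the whole report.
    """
    traits = list(traits) if traits is not None else [
        t for t in dataset.trait_names if t not in ("ear_weight_kg", "grain_moisture_pct")
    ]
    rows = []
    for env in dataset.environment_names:
        for trait in traits:
            try:
                table = anova_rcbd(dataset, env, trait)
                gp = genetic_params_from_anova(table, alpha)
                rows.append(
                    {
                        "environment": env,
                        "trait": trait,
                        "h2": gp.h2,
                        "sigma_g2": gp.sigma_g2,
                        "sigma_p2": gp.sigma_p2,
                        "sigma_e2": gp.sigma_e2,
                        "mean": gp.mean,
                        "gcv_pct": gp.gcv_pct,
                        "pcv_pct": gp.pcv_pct,
                        "p_genotype": gp.p_genotype,
                        "cv_pct": gp.cv_pct,
                        "lsd_5pct": gp.lsd_5pct,
                        "negative_truncated": gp.negative_truncated,
                        "error": None,
                    }
                )
            except Exception as exc:  # noqa: BLE001 - collected, not fatal
                warnings.warn(f"{env}/{trait}: {exc}", TrialDataWarning)
                rows.append(
                    {"environment": env, "trait": trait, "error": str(exc)}
                )
    return pd.DataFrame(rows)
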