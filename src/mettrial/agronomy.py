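"""Grain-yield standardization to a common moisture basis.

Plot ear weight is converted to grain yield in tons per hectare at a standard
moisture (15 % by default):

    yield [t/ha] = PE * (100 - H) / (100 - Hr) * (S * 100) / (NPA * 10)

where PE is ear weight per plot (kg), H the grain moisture at harvest (%),
Hr the standard moisture (%), S the shelling coefficient (grain fraction of
ear weight) and NPA the net harvested plot area (m^2).  Dimensionally:
1 kg of grain-equivalent on 1 m^2 at standard moisture with S = 1 is
10 t/ha, which the formula reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .trial_data import PlotConfig, TrialDataset, TrialDataWarning

ArrayLike = Union[float, np.ndarray]


class YieldDomainError(ValueError):
    """Inputs outside the physical domain of the yield formula."""


@dataclass(frozen=True)
class YieldInputs:
    pe_kg: float
    moisture_pct: float
    hr_pct: float = 15.0
    shelling: float = 0.8
    npa_m2: float = 8.0


def grain_yield_t_ha(
    pe_kg: ArrayLike,
    moisture_pct: ArrayLike,
    *,
    hr_pct: float = 15.0,
    shelling: float = 0.8,
    npa_m2: float,
) -> ArrayLike:
    """Standardized grain yield in t/ha from plot ear weight.

    Vectorized over ``pe_kg`` and ``moisture_pct``.  Raises
    :class:`YieldDomainError` when a moisture reaches 100 %, the shelling
    coefficient leaves (0, 1], the plot area is non-positive, or an ear
    weight is negative.
    """
    pe = np.asarray(pe_kg, dtype=float)
    h = np.asarray(moisture_pct, dtype=float)
    if np.any(pe < 0):
        raise YieldDomainError("ear weight must be >= 0")
    if np.any((h < 0) | (h >= 100)):
        raise YieldDomainError("grain moisture must be in [0, 100)")
    if not (0 <= hr_pct < 100):
        raise YieldDomainError(f"standard moisture must be in [0, 100), got {hr_pct}")
    if not (0 < shelling <= 1):
        raise YieldDomainError(f"shelling coefficient must be in (0, 1], got {shelling}")
    if not (npa_m2 > 0):
        raise YieldDomainError(f"net plot area must be positive, got {npa_m2}")
    out = pe * (100.0 - h) / (100.0 - hr_pct) * (shelling * 100.0) / (npa_m2 * 10.0)
    if out.ndim == 0:
        return float(out)
    return out


def ear_weight_for_yield(
    yield_t_ha: ArrayLike,
    moisture_pct: ArrayLike,
    *,
    hr_pct: float = 15.0,
    shelling: float = 0.8,
    npa_m2: float,
) -> ArrayLike:
    """Invert the standardization: the plot ear weight that yields a target.

    Used by the trial simulator so the derived yield of a generated plot
    equals its latent model value exactly.
    """
    y = np.asarray(yield_t_ha, dtype=float)
    h = np.asarray(moisture_pct, dtype=float)
    if np.any((h < 0) | (h >= 100)):
        raise YieldDomainError("grain moisture must be in [0, 100)")
    pe = y * (100.0 - hr_pct) / (100.0 - h) * (npa_m2 * 10.0) / (shelling * 100.0)
    if pe.ndim == 0:
        return float(pe)
    return pe


@dataclass
class SkippedPlot:
    environment: str
    genotype: str
    replicate: str
    missing: list[str]


@dataclass
class YieldDerivation:
    """Result of :func:`derive_yields`: the augmented dataset plus a skip report."""

    dataset: TrialDataset
    skipped: list[SkippedPlot] = field(default_factory=list)


def derive_yields(dataset: TrialDataset, config: Optional[PlotConfig] = None) -> YieldDerivation:
    """Fill ``grain_yield_t_ha`` for every plot with ear weight and moisture.

    Plots lacking either input trait are skipped (listed in the report, not
    fatal).  Pre-existing yield values are overwritten with a warning.
    """
    cfg = config or dataset.plot_config
    if cfg is None:
        raise YieldDomainError("a PlotConfig (net plot area, standard moisture, shelling) is required")
    df = dataset.observations.copy()
    for col in ("ear_weight_kg", "grain_moisture_pct"):
        if col not in df.columns:
            df[col] = np.nan
    if "grain_yield_t_ha" in df.columns and df["grain_yield_t_ha"].notna().any():
        warnings.warn("existing grain_yield_t_ha values are overwritten", TrialDataWarning)

    pe = df["ear_weight_kg"].to_numpy(float)
    h = df["grain_moisture_pct"].to_numpy(float)
    ok = np.isfinite(pe) & np.isfinite(h)
    yields = np.full(len(df), np.nan)
    if ok.any():
        yields[ok] = grain_yield_t_ha(
            pe[ok], h[ok], hr_pct=cfg.hr_pct, shelling=cfg.shelling, npa_m2=cfg.npa_m2
        )
    df["grain_yield_t_ha"] = yields

    skipped = [
        SkippedPlot(
            environment=row.environment,
            genotype=row.genotype,
            replicate=row.replicate,
            missing=[
                c
                for c, v in (("ear_weight_kg", row.ear_weight_kg), ("grain_moisture_pct", row.grain_moisture_pct))
                if not np.isfinite(v)
            ],
        )
        for row in df[~ok].itertuples(index=False)
    ]
    out = TrialDataset(
        df, genotypes=dataset.genotypes, environments=dataset.environments, plot_config=cfg
    )
    return YieldDerivation(dataset=out, skipped=skipped)
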