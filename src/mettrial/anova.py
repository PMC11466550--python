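"""Per-environment randomized-complete-block ANOVA, computed from first principles.

For one environment and one trait, with g genotypes each observed once in
every one of r blocks:

    SS_geno  = r * sum_i (ybar_i. - ybar..)^2         df = g - 1
    SS_block = g * sum_k (ybar_.k - ybar..)^2         df = r - 1
    SS_error = SS_total - SS_geno - SS_block          df = (g-1)(r-1)
    SS_total = sum_ik (y_ik - ybar..)^2               df = g*r - 1

F for genotype (and block) is the mean-square ratio against MS_error, with
p from the F distribution.  Blocks are treated as fixed; only MS_geno and
MS_error feed the downstream genetic parameters, so that choice is inert
for heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import TrialDataset, TrialDataWarning, TrialDataError, subset_by_environment


class InsufficientDataError(TrialDataError):
    pass


class UnbalancedDataError(TrialDataError):
    pass


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: Optional[float] = None
    f: Optional[float] = None
    p: Optional[float] = None


@dataclass
class AnovaTable:
    """One-environment RCBD ANOVA for a single trait."""

    environment: str
    trait: str
    g: int
    r: int
    grand_mean: float
    rows: list[AnovaRow]
    genotype_means: pd.Series = field(repr=False, default=None)
    dropped_genotypes: list[str] = field(default_factory=list)

    def row(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def ms_geno(self) -> float:
        return self.row("genotype").ms

    @property
    def ms_error(self) -> float:
        return self.row("error").ms

    @property
    def df_error(self) -> int:
        return self.row("error").df

    @property
    def p_genotype(self) -> float:
        return self.row("genotype").p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms, "F": r.f, "p": r.p}
                for r in self.rows
            ]
        )


def _f_test(ms_num: float, ms_err: float, df_num: int, df_err: int, ss_num: float):
    """F statistic and p-value, tolerating a degenerate zero error mean square."""
    if ms_err > 0:
        f = ms_num / ms_err
        return f, float(stats.f.sf(f, df_num, df_err))
    if ss_num > 0:
        return np.inf, 0.0  # perfect separation, no residual noise
    return np.nan, np.nan  # constant data: 0/0


def anova_rcbd(
    dataset: TrialDataset,
    environment_id: str,
    trait: str,
    *,
    drop_incomplete: bool = True,
) -> AnovaTable:
    """RCBD ANOVA of ``trait`` within one environment.

    Genotypes not observed in every replicate of the environment are dropped
    with a warning under the default policy (``drop_incomplete=True``),
    mirroring how sparse multi-location trials simply omit absent entries;
    with ``drop_incomplete=False`` unbalanced data raise
    :class:`UnbalancedDataError`.
    """
    sub = subset_by_environment(dataset, environment_id).observations
    if trait not in sub.columns:
        raise InsufficientDataError(f"trait {trait!r} not present in {environment_id}")
    sub = sub[sub[trait].notna()]
    if sub.empty:
        raise InsufficientDataError(f"no {trait!r} data in {environment_id}")

    cell = sub.pivot(index="genotype", columns="replicate", values=trait)
    incomplete = cell.index[cell.isna().any(axis=1)].tolist()
    if incomplete:
        if not drop_incomplete:
            raise UnbalancedDataError(
                f"{environment_id}/{trait}: incomplete replication for {incomplete}"
            )
        warnings.warn(
            f"{environment_id}/{trait}: dropping genotype(s) with missing replicates: "
            f"{', '.join(incomplete)}",
            TrialDataWarning,
        )
        cell = cell.dropna(axis=0)
    g, r = cell.shape
    if g < 2:
        raise InsufficientDataError(
            f"{environment_id}/{trait}: need >= 2 complete genotypes, have {g}"
        )
    if r < 2:
        raise InsufficientDataError(f"{environment_id}/{trait}: need >= 2 replicates, have {r}")

    y = cell.to_numpy(float)
    grand = y.mean()
    geno_means = y.mean(axis=1)
    block_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_geno = float(r * ((geno_means - grand) ** 2).sum())
    ss_block = float(g * ((block_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_geno - ss_block, 0.0)

    df_geno, df_block = g - 1, r - 1
    df_error = (g - 1) * (r - 1)
    ms_geno, ms_block, ms_error = ss_geno / df_geno, ss_block / df_block, ss_error / df_error
    f_geno, p_geno = _f_test(ms_geno, ms_error, df_geno, df_error, ss_geno)
    f_block, p_block = _f_test(ms_block, ms_error, df_block, df_error, ss_block)

    rows = [
        AnovaRow("genotype", df_geno, ss_geno, ms_geno, f_geno, p_geno),
        AnovaRow("block", df_block, ss_block, ms_block, f_block, p_block),
        AnovaRow("error", df_error, ss_error, ms_error),
        AnovaRow("total", g * r - 1, ss_total),
    ]
    return AnovaTable(
        environment=environment_id,
        trait=trait,
        g=g,
        r=r,
        grand_mean=float(grand),
        rows=rows,
        genotype_means=pd.Series(geno_means, index=cell.index, name=trait),
        dropped_genotypes=incomplete,
    )


def residual_cv(table: AnovaTable) -> float:
    """Residual coefficient of variation, % : 100 * sqrt(MS_error) / grand mean."""
    if table.grand_mean == 0:
        raise ZeroDivisionError("residual CV undefined for zero grand mean")
    return 100.0 * np.sqrt(table.ms_error) / table.grand_mean


def least_significant_difference(table: AnovaTable, alpha: float = 0.05) -> float:
    """Classical LSD between two genotype means at level ``alpha``:
    t(1 - alpha/2, df_error) * sqrt(2 * MS_error / r)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1 - alpha / 2, table.df_error)
    return float(t * np.sqrt(2.0 * table.ms_error / table.r))


def format_p(p: float) -> str:
    """p-value display convention: 4 decimals, '<0.0001' below that."""
    if p is None or np.isnan(p):
        return "NA"
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4f}"
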