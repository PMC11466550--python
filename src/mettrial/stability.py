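"""Across-environment analysis: combined ANOVA, environment ranking, stability.

The combined (multi-environment) ANOVA decomposes the balanced complete-case
subset into environment, block-within-environment, genotype, genotype x
environment and error strata, each F-tested against the pooled error.

Because no distribution-free stability statistic is universally standard for
small sparse trials, the stability ranking here is deliberately rank-based:
within each environment genotypes are ranked by mean yield (1 = best); a
genotype's stability score is its mean rank plus the standard deviation of
its ranks across environments, so a low score demands both high average
performance and consistency.  Environment quality is the unweighted mean of
per-genotype mean yields in that environment (each genotype counts once,
however many replicates it has).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaRow, InsufficientDataError, _f_test
from .trial_data import TrialDataset, TrialDataWarning


@dataclass
class CombinedAnova:
    trait: str
    g: int
    e: int
    r: int
    grand_mean: float
    rows: list[AnovaRow]
    excluded_genotypes: list[str] = field(default_factory=list)
    excluded_environments: list[str] = field(default_factory=list)

    def row(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def p_gxe(self) -> float:
        return self.row("genotype_x_environment").p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms, "F": r.f, "p": r.p}
                for r in self.rows
            ]
        )


def combined_anova(
    dataset: TrialDataset,
    trait: str,
    genotype_policy: str = "complete_cases",
) -> CombinedAnova:
    """Two-factor-with-blocks ANOVA over the balanced complete-case subset.

    ``genotype_policy``:

    - ``complete_cases`` (default): keep the genotypes observed with full
      replication in *every* included environment; environments keep their
      full genotype-present subset requirement.  Excluded genotypes are
      reported, never silently dropped.
    - ``listwise``: keep only environments in which every registry genotype
      is fully observed (drops environments instead of genotypes).
    """
    if genotype_policy not in ("complete_cases", "listwise"):
        raise ValueError(f"unknown genotype_policy {genotype_policy!r}")
    df = dataset.observations
    if trait not in df.columns:
        raise InsufficientDataError(f"trait {trait!r} not in dataset")
    df = df[df[trait].notna()]
    if df.empty:
        raise InsufficientDataError(f"no {trait!r} data")

    envs = sorted(df["environment"].unique())
    if len(envs) < 2:
        raise InsufficientDataError("combined ANOVA needs >= 2 environments")
    reps_per_env = df.groupby("environment")["replicate"].nunique()
    r = int(reps_per_env.min())
    if reps_per_env.nunique() != 1:
        raise InsufficientDataError(
            f"environments have unequal replicate counts: {reps_per_env.to_dict()}"
        )

    # genotype x environment completeness (full replication) table
    counts = df.groupby(["genotype", "environment"])[trait].size().unstack(fill_value=0)
    complete = counts.eq(r)

    if genotype_policy == "complete_cases":
        keep_g = complete.index[complete.all(axis=1)].tolist()
        keep_e = envs
        excluded_g = [g for g in counts.index if g not in keep_g]
        excluded_e: list[str] = []
        if len(keep_g) < 2:
            bottleneck = complete.sum(axis=1).sort_values().index[:3].tolist()
            raise InsufficientDataError(
                "fewer than 2 genotypes are complete in every environment; "
                f"bottleneck genotypes: {bottleneck}"
            )
    else:  # listwise
        keep_e = complete.columns[complete.all(axis=0)].tolist()
        keep_g = counts.index.tolist()
        excluded_e = [e for e in envs if e not in keep_e]
        excluded_g = []
        if len(keep_e) < 2:
            raise InsufficientDataError("fewer than 2 environments contain every genotype")
    if excluded_g or excluded_e:
        warnings.warn(
            f"combined ANOVA excludes genotypes {excluded_g} environments {excluded_e}",
            TrialDataWarning,
        )

    sub = df[df["genotype"].isin(keep_g) & df["environment"].isin(keep_e)]
    g, e = len(keep_g), len(keep_e)
    n = g * e * r
    if len(sub) != n:
        raise InsufficientDataError(
            f"complete-case subset is not balanced: expected {n} plots, found {len(sub)}"
        )

    y = sub[trait].to_numpy(float)
    grand = y.mean()
    env_mean = sub.groupby("environment")[trait].mean()
    gen_mean = sub.groupby("genotype")[trait].mean()
    cell_mean = sub.groupby(["genotype", "environment"])[trait].mean().unstack()
    block_mean = sub.groupby(["environment", "replicate"])[trait].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_env = float(g * r * ((env_mean - grand) ** 2).sum())
    ss_gen = float(e * r * ((gen_mean - grand) ** 2).sum())
    interaction_dev = cell_mean.sub(gen_mean, axis=0).sub(env_mean, axis=1) + grand
    ss_ge = float(r * (interaction_dev**2).to_numpy().sum())
    ss_block = float(
        g * ((block_mean - env_mean.reindex(block_mean.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    ss_error = max(ss_total - ss_env - ss_gen - ss_ge - ss_block, 0.0)

    df_env, df_gen = e - 1, g - 1
    df_ge = (g - 1) * (e - 1)
    df_block = e * (r - 1)
    df_error = e * (g - 1) * (r - 1)
    ms = {
        "environment": ss_env / df_env,
        "genotype": ss_gen / df_gen,
        "genotype_x_environment": ss_ge / df_ge,
        "block_within_environment": ss_block / df_block,
        "error": ss_error / df_error,
    }
    rows = []
    for source, ss_val, dfree in [
        ("environment", ss_env, df_env),
        ("block_within_environment", ss_block, df_block),
        ("genotype", ss_gen, df_gen),
        ("genotype_x_environment", ss_ge, df_ge),
    ]:
        f, p = _f_test(ms[source], ms["error"], dfree, df_error, ss_val)
        rows.append(AnovaRow(source, dfree, ss_val, ms[source], f, p))
    rows.append(AnovaRow("error", df_error, ss_error, ms["error"]))
    rows.append(AnovaRow("total", n - 1, ss_total))
    return CombinedAnova(
        trait=trait,
        g=g,
        e=e,
        r=r,
        grand_mean=float(grand),
        rows=rows,
        excluded_genotypes=excluded_g,
        excluded_environments=excluded_e,
    )


# ---------------------------------------------------------------------------
# Genotype x environment mean-yield matrix, environment ranking, stability


def yield_matrix(dataset: TrialDataset, trait: str = "grain_yield_t_ha") -> pd.DataFrame:
    """Genotype (rows) x environment (columns) matrix of per-genotype means."""
    df = dataset.observations
    if trait not in df.columns:
        raise InsufficientDataError(f"trait {trait!r} not in dataset")
    mat = df.pivot_table(index="genotype", columns="environment", values=trait, aggfunc="mean")
    return mat.reindex(index=sorted(mat.index), columns=sorted(mat.columns))


def _as_matrix(data: Union[TrialDataset, pd.DataFrame], trait: str) -> pd.DataFrame:
    if isinstance(data, TrialDataset):
        return yield_matrix(data, trait)
    return data


def rank_environments(
    data: Union[TrialDataset, pd.DataFrame], trait: str = "grain_yield_t_ha"
) -> pd.DataFrame:
    """Mean yield and descending rank per environment (1 = most productive).

    Accepts either a dataset or a precomputed genotype x environment mean
    matrix.  The environment mean is the unweighted mean over the genotypes
    present there; empty environments are excluded with a warning.  Tied
    means receive mid-ranks.
    """
    mat = _as_matrix(data, trait)
    means = mat.mean(axis=0, skipna=True)
    empty = means.index[means.isna()].tolist()
    if empty:
        warnings.warn(f"environments without {trait} data excluded: {empty}", TrialDataWarning)
        means = means.dropna()
    ranks = pd.Series(stats.rankdata(-means.to_numpy()), index=means.index)
    out = pd.DataFrame({"mean_yield": means, "rank": ranks})
    return out.sort_values("rank")


@dataclass
class StabilityReport:
    genotype_table: pd.DataFrame  # mean_yield, n_environments, mean_rank, rank_sd, score
    environment_table: pd.DataFrame  # mean_yield, rank
    ranks: pd.DataFrame  # genotype x environment within-environment ranks
    excluded_genotypes: list[str]
    min_coverage: float


def stability_ranking(
    data: Union[TrialDataset, pd.DataFrame],
    trait: str = "grain_yield_t_ha",
    min_coverage: float = 0.5,
) -> StabilityReport:
    """Rank-based genotype stability over a multi-environment trial.

    Within each environment the present genotypes are ranked by mean yield
    (1 = best, ties mid-ranked).  Per genotype the report carries the mean
    rank, the rank standard deviation over the environments it covers, and
    the stability score mean_rank + rank_sd (lower = better: the genotype is
    both high-performing and consistent).  Genotypes covering fewer than
    ``min_coverage`` of the environments are excluded with a warning.
    """
    mat = _as_matrix(data, trait)
    if mat.shape[1] < 2:
        raise InsufficientDataError("stability needs >= 2 environments")
    coverage = mat.notna().sum(axis=1) / mat.shape[1]
    excluded = coverage.index[coverage < min_coverage].tolist()
    if excluded:
        warnings.warn(
            f"genotypes below {min_coverage:.0%} environment coverage excluded: {excluded}",
            TrialDataWarning,
        )
    kept = mat.drop(index=excluded)
    if kept.empty or kept.notna().sum(axis=1).max() < 2:
        raise InsufficientDataError("no genotype covers >= 2 environments")

    # within-environment ranks over the genotypes present there (incl. the
    # excluded ones: a sparse genotype still competes where it was grown)
    ranks = mat.rank(axis=0, ascending=False, method="average")
    kept_ranks = ranks.drop(index=excluded)

    table = pd.DataFrame(
        {
            "mean_yield": kept.mean(axis=1),
            "n_environments": kept.notna().sum(axis=1),
            "mean_rank": kept_ranks.mean(axis=1),
            "rank_sd": kept_ranks.std(axis=1, ddof=1).fillna(0.0),
        }
    )
    table["score"] = table["mean_rank"] + table["rank_sd"]
    table = table.sort_values(["score", "mean_rank"])
    return StabilityReport(
        genotype_table=table,
        environment_table=rank_environments(mat, trait),
        ranks=ranks,
        excluded_genotypes=excluded,
        min_coverage=min_coverage,
    )
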