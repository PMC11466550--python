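"""Student-Newman-Keuls stepwise multiple range test with compact letter display.

Genotype means are sorted (descending) and contiguous stretches of p ordered
means are compared against the critical range

    W_p = q(alpha, p, df_error) * sqrt(MS_error / r)

with q the upper-alpha quantile of the studentized range distribution.
Ranges are examined largest first; a range found non-significant *protects*
every sub-range (they are declared non-significant without testing), which is
what distinguishes SNK from unordered pairwise testing.  Letters are assigned
to the maximal non-significant stretches: means sharing a letter are not
significantly different at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaTable, anova_rcbd
from .trial_data import TrialDataset

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def studentized_range_quantile(alpha: float, p: int, df: float) -> float:
    """Upper-``alpha`` quantile of the studentized range of ``p`` means.

    Monotone increasing in p and decreasing in df.  For p = 2 it equals
    sqrt(2) times the two-sided t quantile, which ties the SNK decision for
    two groups to an ordinary t test.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if p < 2:
        raise ValueError(f"stretch size must be >= 2, got {p}")
    if df < 1:
        raise ValueError(f"error degrees of freedom must be >= 1, got {df}")
    return float(stats.studentized_range.ppf(1.0 - alpha, p, df))


@dataclass
class SnkEntry:
    genotype: str
    mean: float
    letters: str


@dataclass
class SnkGrouping:
    """Sorted means with significance letters and the critical ranges used."""

    entries: list[SnkEntry]
    alpha: float
    ms_error: float
    df_error: float
    r: int
    critical_ranges: dict[int, float]  # stretch size p -> W_p
    letters_from: str = "top"

    def letters_for(self, genotype: str) -> str:
        for e in self.entries:
            if e.genotype == genotype:
                return e.letters
        raise KeyError(genotype)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"genotype": e.genotype, "mean": e.mean, "letters": e.letters} for e in self.entries]
        )


def _nonsignificant_intervals(means: np.ndarray, w: dict[int, float]) -> list[tuple[int, int]]:
    """Accepted (non-significant) maximal stretches over descending means.

    Implements the protected stepwise sweep: spans are tested in decreasing
    size; a span inside an already-accepted span is never tested.
    """
    g = len(means)
    accepted: list[tuple[int, int]] = []
    for span in range(g, 1, -1):
        for i in range(0, g - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in accepted):
                continue  # protected by a wider non-significant range
            if means[i] - means[j] <= w[span]:
                accepted.append((i, j))
    # keep only maximal intervals (the sweep can accept nested ones when a
    # protected range is skipped but a shifted overlap is accepted)
    maximal = [
        (a, b)
        for a, b in accepted
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in accepted)
    ]
    return sorted(maximal)


def snk_grouping(
    means: Union[Mapping[str, float], pd.Series],
    ms_error: float,
    df_error: float,
    r: int,
    alpha: float = 0.05,
    letters_from: str = "top",
) -> SnkGrouping:
    """SNK compact letter display for a set of treatment means.

    Parameters
    ----------
    means
        Genotype -> mean mapping (the per-genotype means of a balanced RCBD).
    ms_error, df_error
        Error mean square and its degrees of freedom from the ANOVA.
    r
        Common number of replicates behind each mean.
    letters_from
        ``"top"`` letters the highest-mean group "a" (common practice);
        ``"bottom"`` letters from the lowest mean up, as some published
        tables do.  Purely cosmetic relabelling of the same stretches.
    """
    if isinstance(means, Mapping):
        means = pd.Series(means, dtype=float)
    if len(means) < 2:
        raise ValueError("need at least 2 means to separate")
    if ms_error < 0:
        raise ValueError("MS_error must be >= 0")
    if r < 2:
        raise ValueError("need r >= 2 replicates")
    if letters_from not in ("top", "bottom"):
        raise ValueError("letters_from must be 'top' or 'bottom'")

    order = means.sort_values(ascending=False, kind="mergesort")
    m = order.to_numpy(float)
    g = len(m)
    se = np.sqrt(ms_error / r)
    if ms_error > 0:
        w = {p: studentized_range_quantile(alpha, p, df_error) * se for p in range(2, g + 1)}
    else:
        w = {p: 0.0 for p in range(2, g + 1)}  # degenerate: only exact ties merge

    intervals = _nonsignificant_intervals(m, w)
    covered = set()
    for a, b in intervals:
        covered.update(range(a, b + 1))
    stretches = sorted(intervals + [(i, i) for i in range(g) if i not in covered])
    if letters_from == "bottom":
        stretches = stretches[::-1]

    letter_sets: list[set[str]] = [set() for _ in range(g)]
    for k, (a, b) in enumerate(stretches):
        for i in range(a, b + 1):
            letter_sets[i].add(_LETTERS[k])

    entries = [
        SnkEntry(genotype=str(order.index[i]), mean=float(m[i]), letters="".join(sorted(letter_sets[i])))
        for i in range(g)
    ]
    return SnkGrouping(
        entries=entries,
        alpha=alpha,
        ms_error=float(ms_error),
        df_error=float(df_error),
        r=int(r),
        critical_ranges=w,
        letters_from=letters_from,
    )


def snk_from_anova(table: AnovaTable, alpha: float = 0.05, letters_from: str = "top") -> SnkGrouping:
    """Convenience: run the SNK grouping straight off an :class:`AnovaTable`."""
    return snk_grouping(
        table.genotype_means,
        ms_error=table.ms_error,
        df_error=table.df_error,
        r=table.r,
        alpha=alpha,
        letters_from=letters_from,
    )


def snk_for_environment(
    dataset: TrialDataset,
    environment_id: str,
    trait: str,
    alpha: float = 0.05,
    letters_from: str = "top",
) -> SnkGrouping:
    table = anova_rcbd(dataset, environment_id, trait)
    return snk_from_anova(table, alpha=alpha, letters_from=letters_from)
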