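"""Independent, deliberately naive reference implementations used as oracles.

Everything here is written as plain double loops / top-down recursion so it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_rcbd(values: dict[tuple[str, str], float]) -> dict[str, float]:
    """RCBD sums of squares by explicit enumeration of cell/marginal means.

    ``values`` maps (genotype, replicate) -> observation, one complete cell
    per pair.
    """
    genos = sorted({g for g, _ in values})
    reps = sorted({r for _, r in values})
    n = len(genos) * len(reps)
    grand = sum(values.values()) / n
    geno_mean = {g: sum(values[(g, r)] for r in reps) / len(reps) for g in genos}
    rep_mean = {r: sum(values[(g, r)] for g in genos) / len(genos) for r in reps}
    ss_total = sum((v - grand) ** 2 for v in values.values())
    ss_geno = len(reps) * sum((geno_mean[g] - grand) ** 2 for g in genos)
    ss_block = len(genos) * sum((rep_mean[r] - grand) ** 2 for r in reps)
    ss_error = sum(
        (values[(g, r)] - geno_mean[g] - rep_mean[r] + grand) ** 2 for g in genos for r in reps
    )
    return {
        "grand_mean": grand,
        "ss_total": ss_total,
        "ss_geno": ss_geno,
        "ss_block": ss_block,
        "ss_error": ss_error,
    }


def snk_oracle_letters(means_desc: list[float], w: dict[int, float]) -> list[str]:
    """Compact letter display by the textbook top-down SNK recursion.

    Starting from the full range, a range whose extremes differ by no more
    than its critical value is retained (all its sub-ranges become
    non-significant, untested); otherwise the two one-shorter sub-ranges are
    examined.  Letters then mark the maximal retained ranges plus uncovered
    singletons, from the top mean down.
    """
    g = len(means_desc)
    nonsig: set[tuple[int, int]] = set()

    def visit(i: int, j: int) -> None:
        if j <= i:
            return
        if any(a <= i and j <= b for a, b in nonsig):
            return
        if means_desc[i] - means_desc[j] <= w[j - i + 1]:
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    nonsig.add((a, b))
        else:
            visit(i, j - 1)
            visit(i + 1, j)

    visit(0, g - 1)
    maximal = [
        (a, b)
        for a, b in nonsig
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in nonsig)
    ]
    covered = {i for a, b in maximal for i in range(a, b + 1)}
    stretches = sorted(maximal + [(i, i) for i in range(g) if i not in covered])
    letters = ["" for _ in range(g)]
    for k, (a, b) in enumerate(stretches):
        for i in range(a, b + 1):
            letters[i] += "abcdefghijklmnopqrstuvwxyz"[k]
    return ["".join(sorted(s)) for s in letters]


def spreadsheet_stability(matrix: "np.ndarray", genotypes, environments):
    """Mean rank / rank SD / score per genotype via explicit column loops.

    ``matrix`` is genotype x environment with NaN for absent cells; ranks
    are 1 = best within each column, mid-ranks for ties, sample SD.
    """
    n_g, n_e = matrix.shape
    ranks = np.full_like(matrix, np.nan, dtype=float)
    for j in range(n_e):
        col = matrix[:, j]
        present = [i for i in range(n_g) if not np.isnan(col[i])]
        for i in present:
            higher = sum(1 for i2 in present if col[i2] > col[i])
            tied = sum(1 for i2 in present if col[i2] == col[i])
            ranks[i, j] = higher + (tied + 1) / 2.0
    out = {}
    for i, g in enumerate(genotypes):
        rr = ranks[i, ~np.isnan(ranks[i])]
        if len(rr) == 0:
            continue
        mean_rank = rr.mean()
        sd = rr.std(ddof=1) if len(rr) > 1 else 0.0
        out[g] = {"mean_rank": mean_rank, "rank_sd": sd, "score": mean_rank + sd}
    return out
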