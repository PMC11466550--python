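import numpy as np
import pandas as pd
import pytest

from mettrial import (
    SimulationConfig,
    TraitModel,
    TrialDataset,
    combined_anova,
    rank_environments,
    simulate_met,
    stability_ranking,
    yield_matrix,
)
from mettrial.anova import InsufficientDataError
from mettrial.datasets import (
    RECONCILABLE_MEAN_LOCATIONS,
    published_yield_genetics,
    published_yield_matrix,
)
from mettrial.trial_data import TrialDataWarning

from oracles import spreadsheet_stability


def _additive_dataset() -> TrialDataset:
    # y = mu + g_i + e_j exactly: no interaction, no block, no noise
    rows = []
    for j, env in enumerate(("E1", "E2", "E3")):
        for i, geno in enumerate(("G1", "G2", "G3", "G4")):
            for rep in ("R1", "R2"):
                rows.append(
                    {
                        "environment": env,
                        "genotype": geno,
                        "replicate": rep,
                        "grain_yield_t_ha": 5.0 + 0.5 * i + 0.3 * j,
                    }
                )
    return TrialDataset(pd.DataFrame(rows))


class TestCombinedAnova:
    def test_pure_additive_effects_have_zero_interaction(self):
        table = combined_anova(_additive_dataset(), "grain_yield_t_ha")
        assert table.row("genotype_x_environment").ss == pytest.approx(0.0, abs=1e-12)
        assert table.row("error").ss == pytest.approx(0.0, abs=1e-12)
        assert table.row("genotype").ss > 0 and table.row("environment").ss > 0

    def test_df_and_ss_additivity(self):
        ds, _ = simulate_met(SimulationConfig(n_genotypes=5, n_environments=4, seed=8))
        table = combined_anova(ds, "grain_yield_t_ha")
        strata = ("environment", "block_within_environment", "genotype",
                  "genotype_x_environment", "error")
        assert sum(table.row(s).df for s in strata) == table.row("total").df
        assert sum(table.row(s).ss for s in strata) == pytest.approx(
            table.row("total").ss, rel=1e-9
        )

    def test_matches_least_squares_decomposition(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        sm_api = pytest.importorskip("statsmodels.api")
        ds, _ = simulate_met(SimulationConfig(n_genotypes=4, n_environments=3, seed=21))
        table = combined_anova(ds, "grain_yield_t_ha")
        df = ds.observations.rename(columns={"grain_yield_t_ha": "y"})
        fit = smf.ols(
            "y ~ C(environment) + C(environment):C(replicate) + C(genotype)"
            " + C(genotype):C(environment)",
            data=df,
        ).fit()
        aov = sm_api.stats.anova_lm(fit, typ=1)
        assert table.row("environment").ss == pytest.approx(
            aov.loc["C(environment)", "sum_sq"], rel=1e-9
        )
        assert table.row("genotype").ss == pytest.approx(
            aov.loc["C(genotype)", "sum_sq"], rel=1e-9
        )
        assert table.row("genotype_x_environment").ss == pytest.approx(
            aov.loc["C(genotype):C(environment)", "sum_sq"], rel=1e-9
        )
        assert table.row("block_within_environment").ss == pytest.approx(
            aov.loc["C(environment):C(replicate)", "sum_sq"], rel=1e-9
        )
        assert table.row("error").ss == pytest.approx(aov.loc["Residual", "sum_sq"], rel=1e-8, abs=1e-10)

    def test_complete_cases_excludes_sparse_genotypes(self, sparse_like_paper):
        with pytest.warns(TrialDataWarning):
            table = combined_anova(sparse_like_paper, "grain_yield_t_ha")
        assert set(table.excluded_genotypes) == {"SD7", "SD8", "SD9"}
        assert table.g == 6 and table.e == 9 and table.r == 3

    def test_listwise_requires_fully_covered_environments(self, sparse_like_paper):
        # no two locations carry all nine genotypes (the two with SD8 lack
        # SD9 or SD7), so the listwise policy must refuse
        with pytest.raises(InsufficientDataError):
            combined_anova(sparse_like_paper, "grain_yield_t_ha", genotype_policy="listwise")

    def test_listwise_keeps_complete_environments(self):
        ds, _ = simulate_met(
            SimulationConfig(n_genotypes=4, n_environments=3, seed=6, missing=(("E3", "G1"),))
        )
        with pytest.warns(TrialDataWarning):
            table = combined_anova(ds, "grain_yield_t_ha", genotype_policy="listwise")
        assert table.excluded_environments == ["E3"]
        assert table.e == 2 and table.g == 4

    def test_single_environment_rejected(self):
        ds, _ = simulate_met(SimulationConfig(n_genotypes=4, n_environments=1, seed=0))
        with pytest.raises(InsufficientDataError):
            combined_anova(ds, "grain_yield_t_ha")

    def test_gxe_power_at_strong_interaction(self):
        # with sigma2_ge = 1.0 the interaction F test should reject nearly
        # always at the trial's own dimensions
        model = TraitModel(20.0, 2.5, 1.5, 1.0, 0.1, 0.8)
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            cfg = SimulationConfig(
                traits={"grain_yield_t_ha": model}, seed=40_000 + rep
            )
            ds, _ = simulate_met(cfg)
            hits += combined_anova(ds, "grain_yield_t_ha").p_gxe < 0.05
        assert hits / n_reps > 0.90


class TestEnvironmentRanking:
    def test_published_matrix_reproduces_reported_location_means(self):
        ranking = rank_environments(published_yield_matrix())
        published = published_yield_genetics()["mean"]
        for env in RECONCILABLE_MEAN_LOCATIONS:
            assert round(ranking.loc[env, "mean_yield"], 2) == pytest.approx(published[env])

    def test_poundou_last_and_soungalodaga_on_top(self):
        ranking = rank_environments(published_yield_matrix())
        assert ranking["rank"].idxmax() == "PD"
        assert ranking.loc["SG", "rank"] <= 2

    def test_identical_environments_share_midrank(self):
        mat = pd.DataFrame(
            {"E1": [3.0, 2.0], "E2": [3.0, 2.0], "E3": [3.0, 2.0]}, index=["G1", "G2"]
        )
        ranking = rank_environments(mat)
        assert np.allclose(ranking["rank"], 2.0)

    def test_label_permutation_equivariance(self):
        mat = published_yield_matrix()
        perm = mat.rename(columns={"SG": "PD", "PD": "SG"})
        a = rank_environments(mat)
        b = rank_environments(perm)
        assert a.loc["SG", "rank"] == b.loc["PD", "rank"]
        assert a.loc["PD", "rank"] == b.loc["SG", "rank"]

    def test_empty_environment_excluded_with_warning(self):
        mat = published_yield_matrix()
        mat["GHOST"] = np.nan
        with pytest.warns(TrialDataWarning, match="GHOST"):
            ranking = rank_environments(mat)
        assert "GHOST" not in ranking.index


class TestStabilityRanking:
    def test_published_matrix_row_mean_for_top_genotype(self):
        with pytest.warns(TrialDataWarning):
            report = stability_ranking(published_yield_matrix())
        assert round(report.genotype_table.loc["SD1", "mean_yield"], 2) == 7.04

    def test_top_yielder_scores_better_than_national_check(self):
        with pytest.warns(TrialDataWarning):
            report = stability_ranking(published_yield_matrix())
        t = report.genotype_table
        assert t.loc["SD1", "score"] < t.loc["SD7", "score"]

    def test_sparse_genotype_excluded_by_coverage(self):
        with pytest.warns(TrialDataWarning, match="SD8"):
            report = stability_ranking(published_yield_matrix())
        assert report.excluded_genotypes == ["SD8"]
        assert "SD8" not in report.genotype_table.index

    def test_matches_spreadsheet_oracle(self):
        mat = published_yield_matrix()
        with pytest.warns(TrialDataWarning):
            report = stability_ranking(mat)
        oracle = spreadsheet_stability(mat.to_numpy(), list(mat.index), list(mat.columns))
        for geno, row in report.genotype_table.iterrows():
            assert row["mean_rank"] == pytest.approx(oracle[geno]["mean_rank"])
            assert row["rank_sd"] == pytest.approx(oracle[geno]["rank_sd"])
            assert row["score"] == pytest.approx(oracle[geno]["score"])

    def test_uniform_winner_has_minimal_score(self):
        mat = pd.DataFrame(
            {
                "E1": [9.0, 5.0, 4.0],
                "E2": [8.0, 4.0, 5.0],
                "E3": [7.0, 5.5, 5.0],
            },
            index=["W", "X", "Y"],
        )
        report = stability_ranking(mat, min_coverage=0.0)
        t = report.genotype_table
        assert t.loc["W", "mean_rank"] == 1.0
        assert t.loc["W", "rank_sd"] == 0.0
        assert t.index[0] == "W"

    def test_score_invariant_to_environment_shift(self):
        mat = published_yield_matrix()
        shifted = mat.copy()
        shifted["SG"] = shifted["SG"] + 2.0  # ranks within SG unchanged
        with pytest.warns(TrialDataWarning):
            a = stability_ranking(mat).genotype_table["score"]
        with pytest.warns(TrialDataWarning):
            b = stability_ranking(shifted).genotype_table["score"]
        pd.testing.assert_series_equal(a, b)

    def test_within_environment_ranks_are_a_permutation(self, sparse_like_paper):
        with pytest.warns(TrialDataWarning):
            report = stability_ranking(sparse_like_paper)
        for env in report.ranks.columns:
            col = report.ranks[env].dropna()
            assert sorted(col) == list(np.arange(1, len(col) + 1, dtype=float))

    def test_yield_matrix_shape(self, sparse_like_paper):
        mat = yield_matrix(sparse_like_paper)
        assert mat.shape == (9, 9)
        assert mat.isna().sum().sum() == 9  # the published dash pattern
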