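import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mettrial import PlotConfig, TrialDataset, anova_rcbd, least_significant_difference, residual_cv
from mettrial.anova import InsufficientDataError, UnbalancedDataError
from mettrial.trial_data import TrialDataWarning

from conftest import random_rcbd_dataset
from oracles import brute_force_rcbd


def _dataset_from_matrix(y: np.ndarray) -> TrialDataset:
    g, r = y.shape
    rows = [
        {
            "environment": "E1",
            "genotype": f"G{i + 1}",
            "replicate": f"R{k + 1}",
            "grain_yield_t_ha": float(abs(y[i, k])),
        }
        for i in range(g)
        for k in range(r)
    ]
    return TrialDataset(pd.DataFrame(rows))


class TestOracleEquivalence:
    @pytest.mark.parametrize("g,r,seed", [(3, 2, 0), (4, 2, 1), (5, 3, 2), (5, 3, 3), (2, 3, 4)])
    def test_matches_brute_force_enumeration(self, g, r, seed):
        ds = random_rcbd_dataset(np.random.default_rng(seed), g, r)
        table = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        vals = {
            (row.genotype, row.replicate): row.grain_yield_t_ha
            for row in ds.observations.itertuples()
        }
        oracle = brute_force_rcbd(vals)
        assert table.grand_mean == pytest.approx(oracle["grand_mean"], rel=1e-12)
        assert table.row("genotype").ss == pytest.approx(oracle["ss_geno"], rel=1e-10)
        assert table.row("block").ss == pytest.approx(oracle["ss_block"], rel=1e-10)
        assert table.row("error").ss == pytest.approx(oracle["ss_error"], rel=1e-10, abs=1e-12)
        assert table.row("total").ss == pytest.approx(oracle["ss_total"], rel=1e-10)

    def test_matches_ols_decomposition(self):
        # independent route: least-squares fit with genotype + block factors
        smf = pytest.importorskip("statsmodels.formula.api")
        sm_api = pytest.importorskip("statsmodels.api")
        ds = random_rcbd_dataset(np.random.default_rng(7), 6, 3)
        table = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        df = ds.observations.rename(columns={"grain_yield_t_ha": "y"})
        fit = smf.ols("y ~ C(genotype) + C(replicate)", data=df).fit()
        aov = sm_api.stats.anova_lm(fit, typ=2)
        assert table.row("genotype").ss == pytest.approx(aov.loc["C(genotype)", "sum_sq"], rel=1e-9)
        assert table.row("block").ss == pytest.approx(aov.loc["C(replicate)", "sum_sq"], rel=1e-9)
        assert table.row("error").ss == pytest.approx(aov.loc["Residual", "sum_sq"], rel=1e-9)
        assert table.p_genotype == pytest.approx(aov.loc["C(genotype)", "PR(>F)"], rel=1e-9)

    def test_hand_computed_tiny_table(self, tiny_balanced):
        # E1 means: G1 5.1, G2 4.3, G3 6.1; grand 5.1666...
        table = anova_rcbd(tiny_balanced, "E1", "grain_yield_t_ha")
        assert table.g == 3 and table.r == 2
        assert table.row("genotype").ss == pytest.approx(3.2533333333, rel=1e-9)
        assert table.row("block").ss == pytest.approx(0.0266666667, abs=1e-9)
        assert table.row("error").ss == pytest.approx(0.0933333333, abs=1e-9)


class TestDegenerateInputs:
    def test_zero_noise_has_no_block_or_error_variation(self, zero_noise):
        table = anova_rcbd(zero_noise, "E1", "plant_height_m")
        assert table.row("block").ss == pytest.approx(0.0, abs=1e-12)
        assert table.row("error").ss == pytest.approx(0.0, abs=1e-12)
        # genotype signal with (numerically) no residual: F explodes
        assert table.row("genotype").f > 1e10

    def test_constant_data_all_ss_zero(self):
        ds = _dataset_from_matrix(np.full((4, 3), 2.5))
        table = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        for source in ("genotype", "block", "error", "total"):
            assert table.row(source).ss == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(table.row("genotype").f)


class TestInvariants:
    @given(
        y=hnp.arrays(
            np.float64,
            shape=st.tuples(st.integers(2, 6), st.integers(2, 4)),
            elements=st.floats(0.1, 100.0),
        )
    )
    def test_ss_and_df_additivity(self, y):
        table = anova_rcbd(_dataset_from_matrix(y), "E1", "grain_yield_t_ha")
        parts = sum(table.row(s).ss for s in ("genotype", "block", "error"))
        total = table.row("total").ss
        assert parts == pytest.approx(total, rel=1e-9, abs=1e-9)
        assert (
            table.row("genotype").df + table.row("block").df + table.row("error").df
            == table.row("total").df
        )

    def test_permuting_replicate_labels_preserves_genotype_ss(self, rng):
        ds = random_rcbd_dataset(rng, 5, 3)
        base = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        df = ds.observations.copy()
        df["replicate"] = df["replicate"].map({"R1": "R3", "R2": "R1", "R3": "R2"})
        perm = anova_rcbd(TrialDataset(df), "E1", "grain_yield_t_ha")
        assert perm.row("genotype").ss == pytest.approx(base.row("genotype").ss, rel=1e-12)

    def test_permuting_genotype_labels_preserves_block_ss(self, rng):
        ds = random_rcbd_dataset(rng, 4, 3)
        base = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        df = ds.observations.copy()
        df["genotype"] = df["genotype"].map({"G1": "G4", "G2": "G3", "G3": "G1", "G4": "G2"})
        perm = anova_rcbd(TrialDataset(df), "E1", "grain_yield_t_ha")
        assert perm.row("block").ss == pytest.approx(base.row("block").ss, rel=1e-12)


class TestUnbalancedPolicy:
    def _lopsided(self, rng):
        ds = random_rcbd_dataset(rng, 4, 3)
        df = ds.observations
        return TrialDataset(df[~((df["genotype"] == "G4") & (df["replicate"] == "R3"))])

    def test_default_drops_incomplete_genotypes_with_warning(self, rng):
        ds = self._lopsided(rng)
        with pytest.warns(TrialDataWarning, match="G4"):
            table = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        assert table.g == 3
        assert table.dropped_genotypes == ["G4"]

    def test_strict_mode_errors(self, rng):
        with pytest.raises(UnbalancedDataError):
            anova_rcbd(self._lopsided(rng), "E1", "grain_yield_t_ha", drop_incomplete=False)

    def test_too_few_genotypes_after_dropping(self, rng):
        ds = random_rcbd_dataset(rng, 2, 3)
        df = ds.observations
        trimmed = TrialDataset(df[~((df["genotype"] == "G2") & (df["replicate"] == "R3"))])
        with pytest.warns(TrialDataWarning):
            with pytest.raises(InsufficientDataError):
                anova_rcbd(trimmed, "E1", "grain_yield_t_ha")


class TestResidualCvAndLsd:
    def test_hand_value(self, rng):
        ds = random_rcbd_dataset(rng, 5, 3)
        table = anova_rcbd(ds, "E1", "grain_yield_t_ha")
        expected = 100.0 * np.sqrt(table.ms_error) / table.grand_mean
        assert residual_cv(table) == pytest.approx(expected)

    def test_cv_is_scale_invariant(self, rng):
        ds = random_rcbd_dataset(rng, 5, 3)
        base = residual_cv(anova_rcbd(ds, "E1", "grain_yield_t_ha"))
        df = ds.observations.copy()
        df["grain_yield_t_ha"] *= 3.7
        scaled = residual_cv(anova_rcbd(TrialDataset(df), "E1", "grain_yield_t_ha"))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_cv_zero_when_no_residual(self, zero_noise):
        table = anova_rcbd(zero_noise, "E1", "rows_per_ear")
        assert residual_cv(table) == pytest.approx(0.0, abs=1e-6)

    def test_lsd_uses_t_quantile(self, rng):
        from scipy import stats

        table = anova_rcbd(random_rcbd_dataset(rng, 5, 3), "E1", "grain_yield_t_ha")
        expected = stats.t.ppf(0.975, table.df_error) * np.sqrt(2 * table.ms_error / table.r)
        assert least_significant_difference(table) == pytest.approx(expected)
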