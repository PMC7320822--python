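import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicnet._stats import adjust_bh
from omicnet.differential import (
    TERMS,
    compute_group_fold_changes,
    fit_factorial_anova,
    select_differential_features,
)
from omicnet.io import FACTORS, FeatureMatrix, ValidationError
from omicnet.simulate import SimulationConfig, simulate_de_matrix, simulate_design

from .conftest import make_design
from .oracles import anova_oracle


def matrix_on(design, values, kind="transcript"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:  # matrices need >=2 features; pad a filler row
        filler = np.linspace(0.0, 1.0, values.shape[1])[None, :]
        values = np.vstack([values, filler])
    df = pd.DataFrame(values, index=[f"F{i}" for i in range(values.shape[0])],
                      columns=design.sample_ids)
    return FeatureMatrix(df, kind)


class TestAnovaOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projection_oracle_on_balanced_data(self, seed):
        """SS, df, F and p of every term agree with a hat-matrix projection
        oracle to relative 1e-8 on random balanced 2x2x2 designs."""
        design = make_design(2, 2, 2, 2)
        rng = np.random.default_rng(seed)
        fm = matrix_on(design, rng.normal(0, 1, size=(4, len(design.sample_ids))))
        res = fit_factorial_anova(fm, design)
        from scipy import stats as sps
        for fi, fid in enumerate(fm.feature_ids):
            oracle = anova_oracle(fm.values[fi], design.table)
            for term in TERMS:
                ss_o, df_o = oracle[term]
                assert res.df[term] == df_o
                np.testing.assert_allclose(res.sum_sq.loc[fid, term], ss_o,
                                           rtol=1e-8, atol=1e-12)
                f_o = (ss_o / df_o) / (oracle["residual"][0] / oracle["residual"][1])
                np.testing.assert_allclose(res.F.loc[fid, term], f_o, rtol=1e-8)
                p_o = sps.f.sf(f_o, df_o, oracle["residual"][1])
                np.testing.assert_allclose(res.p.loc[fid, term], p_o,
                                           rtol=1e-8, atol=1e-300)
            np.testing.assert_allclose(res.sum_sq.loc[fid, "residual"],
                                       oracle["residual"][0], rtol=1e-8)

    def test_pure_location_effect_isolated(self):
        design = make_design(2, 2, 2, 2)
        rng = np.random.default_rng(0)
        loc = (design.table["location"] == "L2").to_numpy().astype(float)
        y = 5.0 + 2.0 * loc + rng.normal(0, 1e-6, size=len(loc))
        res = fit_factorial_anova(matrix_on(design, y), design)
        assert res.p.loc["F0", "location"] < 1e-10
        # the planted effect owns essentially all the variation: every other
        # term's SS is noise-sized (p for those terms is uniform, not large)
        ss = res.sum_sq.loc["F0"]
        assert ss["location"] / ss.sum() > 1 - 1e-9
        for term in TERMS:
            if term != "location":
                assert ss[term] < 1e-9 * ss["location"]

    def test_dfs_sum_to_n_minus_one(self, design_3x3x6):
        rng = np.random.default_rng(1)
        fm = matrix_on(design_3x3x6,
                       rng.normal(size=(2, len(design_3x3x6.sample_ids))))
        res = fit_factorial_anova(fm, design_3x3x6)
        assert res.df.sum() == len(design_3x3x6.sample_ids) - 1

    def test_saturated_model_rejected(self):
        design = make_design(2, 2, 2, 1)  # no replication
        rng = np.random.default_rng(0)
        fm = matrix_on(design, rng.normal(size=(2, 8)))
        with pytest.raises(ValidationError, match="replicates"):
            fit_factorial_anova(fm, design)

    def test_statsmodels_cross_check_type3(self):
        """Independent route: statsmodels OLS + Type-III anova_lm with sum
        contrasts on an unbalanced design."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        design = make_design(2, 2, 2, 2)
        # drop one sample -> unbalanced
        sub = design.table.iloc[:-1].copy()
        from omicnet.io import SampleDesign
        design_u = SampleDesign(sub)
        rng = np.random.default_rng(3)
        fm = matrix_on(design_u, rng.normal(size=(1, len(sub))))
        res = fit_factorial_anova(fm, design_u)

        df = sub.copy()
        df["y"] = fm.values[0]
        model = smf.ols(
            "y ~ C(variety, Sum) * C(location, Sum) * C(stage, Sum)", data=df
        ).fit()
        table = sm.stats.anova_lm(model, typ=3)
        name_map = {
            "variety": "C(variety, Sum)",
            "location": "C(location, Sum)",
            "stage": "C(stage, Sum)",
            "variety:location": "C(variety, Sum):C(location, Sum)",
            "variety:stage": "C(variety, Sum):C(stage, Sum)",
            "location:stage": "C(location, Sum):C(stage, Sum)",
            "variety:location:stage":
                "C(variety, Sum):C(location, Sum):C(stage, Sum)",
        }
        for term, sm_name in name_map.items():
            np.testing.assert_allclose(res.sum_sq.loc["F0", term],
                                       table.loc[sm_name, "sum_sq"], rtol=1e-8)
            np.testing.assert_allclose(res.p.loc["F0", term],
                                       table.loc[sm_name, "PR(>F)"], rtol=1e-8)

    def test_type_one_error_nominal(self):
        """Null features: each term's rejection rate at 0.05 stays within the
        binomial 99% band."""
        design = make_design(2, 2, 2, 2)
        rng = np.random.default_rng(0)
        fm = matrix_on(design, rng.normal(size=(1000, len(design.sample_ids))))
        res = fit_factorial_anova(fm, design)
        for term in TERMS:
            rate = (res.p[term] < 0.05).mean()
            assert abs(rate - 0.05) <= 0.0178  # 2.58 * sqrt(.05*.95/1000)


class TestBh:
    def test_textbook_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(adjust_bh([0.5]), [0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_preserving_and_dominates_raw(self, p):
        from .oracles import bh_oracle
        adj = adjust_bh(p)
        np.testing.assert_allclose(adj, bh_oracle(np.array(p)), atol=1e-12)
        assert (adj >= np.array(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFoldChange:
    def test_max_pairwise_gap(self, design_3x3x6):
        lvl = design_3x3x6.table["location"]
        y = np.where(lvl == "L1", 0.0, np.where(lvl == "L2", 1.0, 3.0))
        fm = matrix_on(design_3x3x6, y)
        fc = compute_group_fold_changes(fm, design_3x3x6, "location")
        assert np.isclose(fc["F0"], 3.0)

    def test_constant_feature_zero(self, design_3x3x6):
        fm = matrix_on(design_3x3x6, np.full(len(design_3x3x6.sample_ids), 2.0))
        assert compute_group_fold_changes(fm, design_3x3x6, "stage")["F0"] == 0.0

    def test_sample_permutation_invariant(self, design_3x3x6):
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(design_3x3x6.sample_ids))
        fm = matrix_on(design_3x3x6, y)
        fc = compute_group_fold_changes(fm, design_3x3x6, "variety")
        perm = rng.permutation(len(y))
        fm_p = FeatureMatrix(fm.data.iloc[:, perm], "transcript")
        fc_p = compute_group_fold_changes(fm_p, design_3x3x6, "variety")
        np.testing.assert_allclose(fc.to_numpy(), fc_p.to_numpy())


class TestSelection:
    def _run(self, n_features=2000, n_de=100, seed=0, alpha=0.01, sd_mult=2.0):
        cfg = SimulationConfig(design=(3, 3, 6, 2))
        design = simulate_design(cfg)
        noise = 0.5
        fm, de_ids = simulate_de_matrix(design, n_features, n_de, "location",
                                        effect=2 * noise, noise_sd=noise, seed=seed)
        res = fit_factorial_anova(fm, design)
        fc = pd.DataFrame(
            {f"fc_{f}": compute_group_fold_changes(fm, design, f) for f in FACTORS})
        table = select_differential_features(res.p[list(FACTORS)], fc,
                                             alpha=alpha, sd_mult=sd_mult)
        return table, de_ids

    def test_planted_de_recovery(self):
        """Sensitivity >= 0.9 and empirical FDR <= 0.05 for 100 planted
        location effects of 2 x noise SD among 2,000 features."""
        table, de_ids = self._run(seed=0)
        called = table.de_features("location")
        sens = len(called & de_ids) / len(de_ids)
        fdr = len(called - de_ids) / max(len(called), 1)
        assert sens >= 0.9
        assert fdr <= 0.05

    def test_fc_filter_only_removes(self):
        table, _ = self._run(seed=1)
        loose, _ = self._run(seed=1, sd_mult=0.0)
        assert table.de_features("location") <= loose.de_features("location")

    def test_permissive_thresholds_flag_all(self):
        table, _ = self._run(n_features=50, n_de=50, seed=2, alpha=1.1, sd_mult=0.0)
        assert table.table["de_location"].all()

    def test_infinite_sd_mult_flags_none(self):
        table, _ = self._run(n_features=50, n_de=50, seed=2, sd_mult=np.inf)
        assert not table.table["de_location"].any()

    def test_summary_counts_consistent(self):
        table, _ = self._run(n_features=200, n_de=20, seed=3)
        s = table.summary()
        assert s["counts"]["location"] == len(table.de_features("location"))
        assert s["union"] >= max(s["counts"].values())
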