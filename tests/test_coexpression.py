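import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from omicnet.coexpression import (
    GREY,
    build_modules,
    compute_adjacency,
    compute_eigengenes,
    compute_kme,
    compute_tom,
    detect_modules,
    pick_soft_threshold,
    scale_free_fit_index,
    CoexpressionNetwork,
)
from omicnet.io import FeatureMatrix, ValidationError
from omicnet.simulate import SimulationConfig, simulate_dataset

from .conftest import random_matrix
from .oracles import tom_oracle


def planted_modules_dataset(seed=0):
    """5 modules x 50 features, 250 background, n=108, within-cor 0.8."""
    cfg = SimulationConfig(
        n_genes=500, n_metabolites=60, n_modules_gene=5, n_modules_metab=2,
        module_size_gene=50, module_size_metab=15, within_module_cor=0.8,
        plant_regulator=False, seed=seed,
    )
    return simulate_dataset(cfg)


class TestAdjacency:
    def test_identical_features_give_unit_weight(self):
        fm = random_matrix(4, 10, seed=0)
        fm.data.iloc[1] = fm.data.iloc[0]
        net = compute_adjacency(fm, beta=7.0)
        assert np.isclose(net.adjacency[0, 1], 1.0)

    def test_power_arithmetic(self):
        # r = 0.5, beta = 2 -> a = 0.25 (constructed via exact vectors)
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0, -1.0, 1.0, -1.0, 1.0])  # r = 0
        z = (x + np.sqrt(3) * y) / 2.0  # cor(x, z) = 0.5
        df = pd.DataFrame([x, z], index=["a", "b"],
                          columns=[f"s{i}" for i in range(8)])
        net = compute_adjacency(FeatureMatrix(df, "transcript"), beta=2.0)
        assert np.isclose(net.adjacency[0, 1], 0.25)

    def test_monotone_decreasing_in_beta(self):
        fm = random_matrix(6, 12, seed=1)
        a1 = compute_adjacency(fm, 2.0).adjacency
        a2 = compute_adjacency(fm, 8.0).adjacency
        off = ~np.eye(6, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()

    def test_zero_variance_feature_named(self):
        fm = random_matrix(4, 10, seed=2)
        fm.data.iloc[2] = 3.14
        with pytest.raises(ValidationError, match="F002"):
            compute_adjacency(fm, 7.0)


class TestTom:
    def test_fully_connected_gives_unit_tom(self):
        a = np.ones((3, 3))
        net = CoexpressionNetwork(1.0, ["a", "b", "c"], a)
        tom = compute_tom(net).tom
        np.testing.assert_allclose(tom, 1.0)

    def test_disconnected_gives_zero_off_diagonal(self):
        a = np.eye(4)
        net = CoexpressionNetwork(1.0, list("abcd"), a)
        tom = compute_tom(net).tom
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(tom[off], 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = CoexpressionNetwork(1.0, [f"f{i}" for i in range(n)], a)
        tom = compute_tom(net).tom
        expected = tom_oracle(a)
        np.testing.assert_allclose(tom, expected, atol=1e-12)
        assert (tom >= 0).all() and (tom <= 1).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestScaleFreeFit:
    def test_power_law_connectivity_fits_well(self):
        rng = np.random.default_rng(0)
        # exact discrete power-law degree sample
        k = (rng.pareto(2.0, size=3000) + 1.0) * 2.0
        fit, slope = scale_free_fit_index(k)
        assert fit >= 0.95
        assert slope < 0

    def test_uniform_connectivity_fits_poorly(self):
        rng = np.random.default_rng(1)
        k = rng.uniform(10, 11, size=500)
        fit, _ = scale_free_fit_index(k)
        assert fit < 0.8

    def test_default_beta_falls_back(self):
        fm = random_matrix(60, 12, seed=2)  # pure noise: no power fits
        table, beta = pick_soft_threshold(fm, powers=(1, 2), r2_min=0.99)
        assert beta == 7.0
        assert len(table) == 2

    def test_single_power_single_row(self):
        fm = random_matrix(60, 12, seed=3)
        table, _ = pick_soft_threshold(fm, powers=(7,), r2_min=0.0)
        assert len(table) == 1


class TestModuleDetection:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n1, n2 = 6, 5
        a = np.full((n1 + n2, n1 + n2), 0.01)
        a[:n1, :n1] = 0.95
        a[n1:, n1:] = 0.95
        a += rng.uniform(0, 0.01, size=a.shape)
        a = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(a, 1.0)
        net = compute_tom(CoexpressionNetwork(1.0, [f"f{i}" for i in range(n1 + n2)], a))
        ms = detect_modules(net, min_size=3)
        truth = [0] * n1 + [1] * n2
        assert adjusted_rand_score(truth, ms.assignment.to_numpy()) == 1.0

    def test_min_size_above_n_gives_all_grey(self):
        fm = random_matrix(10, 8, seed=1)
        net = compute_tom(compute_adjacency(fm, 7.0))
        ms = detect_modules(net, min_size=11)
        assert (ms.assignment == GREY).all()

    def test_relabeling_features_preserves_partition(self):
        ds = planted_modules_dataset(seed=1)
        fm = ds.genes
        perm = np.random.default_rng(0).permutation(fm.n_features)
        fm_p = FeatureMatrix(fm.data.iloc[perm], "transcript")
        ms = detect_modules(compute_tom(compute_adjacency(fm, 7.0)), min_size=30)
        ms_p = detect_modules(compute_tom(compute_adjacency(fm_p, 7.0)), min_size=30)
        joined = ms.assignment.loc[fm_p.feature_ids]
        assert adjusted_rand_score(joined.to_numpy(), ms_p.assignment.to_numpy()) == 1.0

    def test_planted_module_recovery_ari(self):
        """5 modules of 50 + 250 background at within-cor 0.8: ARI >= 0.9."""
        ds = planted_modules_dataset(seed=0)
        _, ms = build_modules(ds.genes, beta=7.0, min_size=30)
        truth = [ds.truth.module_assignment_true[f] for f in ds.genes.feature_ids]
        ari = adjusted_rand_score(truth, ms.assignment.to_numpy())
        assert ari >= 0.9

    def test_module_names_follow_size_order(self):
        ds = planted_modules_dataset(seed=2)
        _, ms = build_modules(ds.genes, beta=7.0, min_size=10)
        names = ms.module_names
        sizes = [len(ms.members(m)) for m in names]
        assert sizes == sorted(sizes, reverse=True)
        assert names[0] == "turquoise"


class TestEigengenes:
    def test_near_identical_members_recover_profile(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        X = base + rng.normal(0, 0.01, size=(20, 30))
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(30)])
        fm = FeatureMatrix(df, "transcript")
        from omicnet.coexpression import ModuleSet
        ms = ModuleSet(pd.Series("turquoise", index=fm.feature_ids))
        ms = compute_eigengenes(fm, ms)
        me = ms.eigengenes["turquoise"].to_numpy()
        assert abs(np.corrcoef(me, base)[0, 1]) >= 0.999
        assert np.isclose(me.var(), 1.0, atol=1e-9)

    def test_sign_convention_mean_member_correlation_nonnegative(self):
        ds = planted_modules_dataset(seed=3)
        _, ms = build_modules(ds.genes, beta=7.0, min_size=30)
        for mod in ms.module_names:
            members = ms.members(mod)
            kmes = ms.kme.loc[members, mod]
            assert kmes.mean() >= 0

    def test_flipping_members_flips_eigengene(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        X = base + rng.normal(0, 0.05, size=(10, 20))
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(20)])
        from omicnet.coexpression import ModuleSet
        ms1 = compute_eigengenes(FeatureMatrix(df, "transcript"),
                                 ModuleSet(pd.Series("blue", index=df.index)))
        ms2 = compute_eigengenes(FeatureMatrix(-df, "transcript"),
                                 ModuleSet(pd.Series("blue", index=df.index)))
        np.testing.assert_allclose(ms1.eigengenes["blue"].to_numpy(),
                                   -ms2.eigengenes["blue"].to_numpy(), atol=1e-8)


class TestKme:
    def test_feature_equal_to_eigengene_has_unit_kme(self):
        ds = planted_modules_dataset(seed=4)
        _, ms = build_modules(ds.genes, beta=7.0, min_size=30)
        mod = ms.module_names[0]
        me = ms.eigengenes[mod]
        df = ds.genes.data.copy()
        df.loc["SELF"] = me.to_numpy()
        fm = FeatureMatrix(df, "transcript")
        ms2 = compute_kme(fm, ms)
        assert np.isclose(ms2.kme.loc["SELF", mod], 1.0)
        assert ms2.kme_p.loc["SELF", mod] < 1e-100

    def test_kme_p_matches_t_distribution(self):
        # r = 0.5, n = 27 -> t = 2.887, p ~ 0.0078
        r, n = 0.5, 27
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n - 2)
        assert np.isclose(t, 2.8868, atol=1e-3)
        assert np.isclose(p, 0.0078, atol=2e-4)
        from omicnet._stats import correlation_pvalues
        np.testing.assert_allclose(correlation_pvalues(np.array([r]), n), [p],
                                   rtol=1e-10)

    def test_hub_gene_attains_top_own_module_kme(self):
        """The planted hub (largest loading) tops its module's kME ranking in
        most replicates."""
        wins = 0
        reps = 10
        for seed in range(reps):
            cfg = SimulationConfig(
                n_genes=200, n_metabolites=60, n_modules_gene=2, n_modules_metab=2,
                module_size_gene=50, module_size_metab=15, seed=seed,
            )
            ds = simulate_dataset(cfg)
            _, ms = build_modules(ds.genes, beta=7.0, min_size=30)
            reg = ds.truth.planted_regulator
            mod = ms.assignment.get(reg, GREY)
            if mod == GREY:
                continue
            members = [m for m in ms.members(mod)
                       if m not in ds.truth.regulator_targets_true.get(reg, set())]
            top = ms.kme.loc[members, mod].idxmax()
            wins += int(top == reg)
        assert wins >= 0.9 * reps
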