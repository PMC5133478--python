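import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from triocausal.data_io import ExpressionMatrix
from triocausal.filtering import snp_probe_gwas
from triocausal.synthetic import CohortSpec, simulate_cohort
from triocausal.wgcna import (
    GREY,
    NetworkConfig,
    adjacency,
    build_modules,
    detect_modules,
    eigengene,
    linkage_to_newick,
    module_trait_association,
    pick_soft_threshold,
    topological_overlap,
)


def expr(values):
    return ExpressionMatrix(
        values, pd.DataFrame({"probe_id": [f"p{j}" for j in range(values.shape[1])]}),
        [f"i{k}" for k in range(values.shape[0])])


def random_adjacency(rng, m):
    a = rng.uniform(0.0, 1.0, (m, m))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def tom_reference(a):
    """Triple-loop topological overlap, straight from the definition."""
    m = a.shape[0]
    t = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            ell = sum(a[i, u] * a[u, j] for u in range(m) if u not in (i, j))
            ki = sum(a[i, u] for u in range(m) if u != i)
            kj = sum(a[j, u] for u in range(m) if u != j)
            t[i, j] = (ell + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return t


class TestAdjacency:
    def test_matches_elementwise_pearson_power(self, rng):
        X = rng.normal(size=(5, 4))
        a = adjacency(expr(X), NetworkConfig(soft_power=6))
        for i in range(4):
            for j in range(4):
                r, _ = stats.pearsonr(X[:, i], X[:, j])
                expected = 1.0 if i == j else abs(r) ** 6
                assert a[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_probe_has_unit_adjacency(self, rng):
        x = rng.normal(size=30)
        a = adjacency(expr(np.column_stack([x, x, rng.normal(size=30)])), 6)
        assert a[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_probes_near_zero_offdiagonal(self, rng):
        a = adjacency(expr(rng.normal(size=(2000, 6))), 6)
        off = a[np.triu_indices(6, k=1)]
        assert off.max() < 1e-6

    def test_zero_variance_probe_named_in_error(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="p1"):
            adjacency(expr(X), 6)


class TestTopologicalOverlap:
    def test_identity_maps_to_identity(self):
        np.testing.assert_allclose(topological_overlap(np.eye(5)), np.eye(5))

    def test_complete_graph_has_full_overlap(self):
        a = np.ones((4, 4))
        np.testing.assert_allclose(topological_overlap(a), np.ones((4, 4)))

    def test_matches_triple_loop_reference(self, rng):
        for _ in range(25):
            a = random_adjacency(rng, 6)
            np.testing.assert_allclose(topological_overlap(a), tom_reference(a),
                                       atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 12))
    def test_tom_symmetric_unit_diagonal_in_range(self, seed, m):
        a = random_adjacency(np.random.default_rng(seed), m)
        t = topological_overlap(a)
        np.testing.assert_allclose(t, t.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(t), 1.0)
        assert t.min() >= 0.0 and t.max() <= 1.0

    def test_invalid_input_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(rng.uniform(size=(4, 4)))
        bad = random_adjacency(rng, 4)
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(ValueError, match="0, 1"):
            topological_overlap(bad)


class TestSoftThreshold:
    def test_singleton_candidate_returned(self, rng):
        power, table = pick_soft_threshold(expr(rng.normal(size=(30, 10))), [6])
        assert power == 6 and list(table["power"]) == [6]

    def test_modular_data_reaches_fit_target(self):
        _, e, _, _ = simulate_cohort(CohortSpec(n=300, n_snps=5, n_probes=150,
                                                module_sizes=(50, 50),
                                                loadings=0.85, seed=40))
        power, table = pick_soft_threshold(e, (2, 4, 6, 8, 10))
        chosen = table.set_index("power").loc[power, "r_squared"]
        assert chosen >= 0.5  # scale-free-ish; exact R2 depends on draw
        assert power in (2, 4, 6, 8, 10)

    def test_pure_noise_falls_back_to_max_r2(self, rng):
        power, table = pick_soft_threshold(expr(rng.normal(size=(60, 40))),
                                           (2, 6, 10))
        defined = table.dropna(subset=["r_squared"])
        assert power in list(defined["power"])


class TestModuleDetection:
    def test_perfect_blocks_recovered_exactly(self):
        tom = np.zeros((8, 8))
        tom[:4, :4] = 1.0
        tom[4:, 4:] = 1.0
        cfg = NetworkConfig(min_module_size=2, cut_height=0.5)
        labels = detect_modules(tom, cfg)
        groups = {lab: set(labels.index[labels == lab]) for lab in labels.unique()}
        assert len(groups) == 2
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"probe{j}" for j in range(4)),
            frozenset(f"probe{j}" for j in range(4, 8))}

    def test_equal_tom_single_module_or_grey_by_cut_side(self):
        tom = np.full((6, 6), 0.4)
        np.fill_diagonal(tom, 1.0)
        cfg_above = NetworkConfig(min_module_size=3, cut_height=0.7)
        labels = detect_modules(tom, cfg_above)  # merge height 0.6 < 0.7
        assert (labels == "turquoise").all()
        cfg_below = NetworkConfig(min_module_size=3, cut_height=0.5)
        labels2 = detect_modules(tom, cfg_below)  # cut below all merges
        assert (labels2 == GREY).all()

    def test_planted_modules_high_ari_and_color_order(self):
        spec = CohortSpec(n=300, n_snps=5, n_probes=130,
                          module_sizes=(60, 40, 20), loadings=0.85,
                          coupling=0.0, seed=41)
        _, e, _, truth = simulate_cohort(spec)
        ms = build_modules(e, NetworkConfig(min_module_size=10))
        true_lab = [truth["module_assignment"][p] for p in e.probe_ids]
        ari = adjusted_rand_score(true_lab, list(ms.assignment))
        assert ari >= 0.9
        # largest module gets the first colour
        sizes = ms.assignment[ms.assignment != GREY].value_counts()
        assert sizes.idxmax() == "turquoise"

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(100, 12))
        X[:, :6] += np.outer(rng.normal(size=100), np.full(6, 1.0))
        a = adjacency(expr(X), 6)
        tom = topological_overlap(a)
        perm = rng.permutation(12)
        a_p = adjacency(expr(X[:, perm]), 6)
        np.testing.assert_allclose(a_p, a[np.ix_(perm, perm)], atol=1e-12)
        cfg = NetworkConfig(min_module_size=3)
        lab = detect_modules(tom, cfg, probe_ids=[f"p{j}" for j in range(12)])
        lab_p = detect_modules(topological_overlap(a_p), cfg,
                               probe_ids=[f"p{j}" for j in perm])
        for pid in lab.index:
            same_a = set(lab.index[lab == lab[pid]])
            same_b = set(lab_p.index[lab_p == lab_p[pid]])
            assert same_a == same_b


class TestEigengene:
    def test_identical_probes_give_that_probe_standardised(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, x, x])
        assign = pd.Series(["blue"] * 3, index=["p0", "p1", "p2"])
        eg, ve = eigengene(expr(X), assign)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(eg["blue"].to_numpy(), z, atol=1e-8)
        assert ve["blue"] == pytest.approx(1.0, abs=1e-12)

    def test_two_uncorrelated_probes_explain_half(self, rng):
        X = rng.normal(size=(500, 2))
        assign = pd.Series(["blue", "blue"], index=["p0", "p1"])
        _, ve = eigengene(expr(X), assign)
        r = abs(stats.pearsonr(X[:, 0], X[:, 1])[0])
        # 2x2 correlation eigenvalues are 1 +- r: top share is (1+|r|)/2
        assert ve["blue"] == pytest.approx((1 + r) / 2, abs=1e-10)

    def test_orientation_positive_mean_member_correlation(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            f = r.normal(size=120)
            X = np.outer(f, r.uniform(0.5, 1.0, 8)) + r.normal(size=(120, 8))
            assign = pd.Series(["tan"] * 8, index=[f"p{j}" for j in range(8)])
            eg, _ = eigengene(expr(X), assign)
            corrs = [stats.pearsonr(eg["tan"], X[:, j])[0] for j in range(8)]
            assert np.mean(corrs) > 0
            assert eg["tan"].std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_recovers_planted_factor(self):
        spec = CohortSpec(n=500, n_snps=5, n_probes=10, module_sizes=(10,),
                          loadings=0.9, coupling=0.0, snp_factor_effect=0.0,
                          seed=42)
        _, e, _, truth = simulate_cohort(spec)
        assign = pd.Series(["turquoise"] * 10, index=e.probe_ids)
        eg, _ = eigengene(e, assign)
        f = np.array(truth["factors"])[:, 0]
        assert abs(stats.pearsonr(eg["turquoise"], f)[0]) >= 0.9

    def test_constant_probe_rejected(self):
        X = np.column_stack([np.full(20, 1.0), np.arange(20.0)])
        assign = pd.Series(["blue", "blue"], index=["p0", "p1"])
        with pytest.raises(ValueError, match="constant"):
            eigengene(expr(X), assign)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, rng):
        eg = pd.DataFrame({"tan": rng.normal(size=60)},
                          index=[f"i{k}" for k in range(60)])
        res = module_trait_association(eg, {"SBP": eg["tan"]})
        row = res.iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["p"] < 1e-50

    def test_bonferroni_arithmetic_over_24_by_2_grid(self, rng):
        """A raw p of 0.0002 under 24 modules x 2 traits adjusts to 0.0096
        and stays significant at 0.05."""
        eg = pd.DataFrame(rng.normal(size=(400, 24)),
                          columns=[f"m{j}" for j in range(24)],
                          index=[f"i{k}" for k in range(400)])
        traits = {"SBP": pd.Series(rng.normal(size=400), index=eg.index),
                  "DBP": pd.Series(rng.normal(size=400), index=eg.index)}
        res = module_trait_association(eg, traits)
        np.testing.assert_allclose(res["p_bonferroni"],
                                   np.minimum(1.0, res["p"] * 48), rtol=1e-12)
        assert min(1.0, 0.0002 * 48) == pytest.approx(0.0096)  # < 0.05: significant

    def test_null_familywise_error_controlled(self, rng):
        hits = 0
        reps = 120
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            eg = pd.DataFrame(r.normal(size=(100, 12)),
                              columns=[f"m{j}" for j in range(12)],
                              index=range(100))
            y = pd.Series(r.normal(size=100), index=eg.index)
            res = module_trait_association(eg, {"T": y})
            hits += res["significant"].any()
        # Bonferroni guarantees FWER <= 0.05; allow binomial wiggle
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_linkage_newick_export_parses_and_keeps_leaves(rng):
    import dendropy

    X = rng.normal(size=(30, 6))
    d = 1.0 - topological_overlap(adjacency(expr(X), 6))
    np.fill_diagonal(d, 0.0)
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(d, checks=False), "average")
    nwk = linkage_to_newick(Z, [f"p{j}" for j in range(6)])
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert {l.taxon.label for l in tree.leaf_node_iter()} == {f"p{j}" for j in range(6)}


def test_eigengene_gwas_recovers_planted_snp():
    """Running the SNP scan with the planted module's eigengene as the
    phenotype pinpoints the planted eQTL — the module-based filtering route."""
    spec = CohortSpec(n=500, n_snps=40, n_probes=60, module_sizes=(30,),
                      loadings=0.85, seed=43)
    g, e, _, truth = simulate_cohort(spec)
    ms = build_modules(e, NetworkConfig(min_module_size=10))
    assert "turquoise" in ms.labels
    scan = snp_probe_gwas(g, ms.eigengenes["turquoise"].to_numpy())
    assert scan.table.iloc[0]["id"] == truth["causal_snp"]
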