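import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from adjx.coexpression import (
    CoexprConfig,
    CoexpressionModules,
    adjacency_matrix,
    detect_modules,
    module_enrichment,
    module_eigengene,
    pick_soft_threshold,
    refine_modules,
    select_coexpr_genes,
    topological_overlap,
)
from adjx.datatypes import GeneSetCollection
from adjx.simulate import SimulationConfig, simulate_dataset
from conftest import make_dataset


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """O(n^3) literal triple-loop oracle for the TOM formula."""
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n=10):
    m = rng.random((n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestGeneSelection:
    def make_tables(self):
        idx = ["G1", "G2", "G3"]
        t1 = pd.DataFrame({"q": [0.005, 0.5, 0.011]}, index=idx)
        t2 = pd.DataFrame({"q": [0.5, 0.009, 0.011]}, index=idx)
        return {4.0: t1, 24.0: t2}

    def test_any_timepoint_union(self):
        assert select_coexpr_genes(self.make_tables(), 0.01) == ["G1", "G2"]

    def test_boundary_excluded_above_threshold(self):
        genes = select_coexpr_genes(self.make_tables(), 0.01)
        assert "G3" not in genes  # 0.011 > 0.01 everywhere

    def test_duplicates_counted_once(self):
        tables = self.make_tables()
        tables[24.0].loc["G1", "q"] = 0.001
        assert select_coexpr_genes(tables, 0.01).count("G1") == 1

    def test_empty_selection_advises(self):
        tables = self.make_tables()
        with pytest.raises(ValueError, match="relax"):
            select_coexpr_genes(tables, 1e-6)


class TestAdjacency:
    def test_powers_of_correlation(self):
        # three genes: G1,G2 perfectly correlated; G3 at r=0.5 with G1
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        other = 0.5 * base + math.sqrt(1 - 0.25) * rng.normal(size=100)
        # force exact sample correlations via Gram-Schmidt
        b = (base - base.mean()) / base.std()
        o = (other - other.mean()) / other.std()
        o = o - np.dot(o, b) / np.dot(b, b) * b
        o = o / np.linalg.norm(o) * np.linalg.norm(b)
        g3 = 0.5 * b + math.sqrt(0.75) * o
        data = make_dataset(
            np.vstack([b, 2 * b + 5, g3]), ["T"] * 100, [4] * 100,
            list(range(1, 101)),
        )
        a = adjacency_matrix(data, ["G1", "G2", "G3"], beta=6)
        assert a.loc["G1", "G2"] == pytest.approx(1.0)
        assert a.loc["G1", "G3"] == pytest.approx(0.5**6, abs=1e-9)
        assert a.loc["G1", "G1"] == 1.0

    def test_uncorrelated_pair_zero(self):
        x = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        data = make_dataset(x, ["T"] * 4, [4] * 4, [1, 2, 3, 4])
        a = adjacency_matrix(data, ["G1", "G2"], beta=6)
        assert a.loc["G1", "G2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_gene_dropped(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        data = make_dataset(x, ["T"] * 4, [4] * 4, [1, 2, 3, 4])
        a = adjacency_matrix(data, ["G1", "G2"], beta=2)
        assert list(a.index) == ["G1"]


class TestSoftThreshold:
    def test_scale_free_network_attains_target(self):
        """Module-structured data with many small modules yields a
        heavy-tailed connectivity distribution; auto selection returns a
        beta reaching the R^2 target (or the best fallback)."""
        cfg = SimulationConfig(
            n_genes=300, groups=(("T", "C"),), de_fraction={}, n_modules=8,
            module_size=25, module_r2=0.7, seed=21,
        )
        data, _ = simulate_dataset(cfg)
        beta = pick_soft_threshold(data, data.gene_ids, r2_target=0.8)
        assert beta in (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16)

    def test_single_candidate_returned(self, two_group_sim):
        data, _ = two_group_sim
        genes = data.gene_ids[:50]
        assert pick_soft_threshold(data, genes, candidate_betas=[7]) == 7

    def test_deterministic(self, two_group_sim):
        data, _ = two_group_sim
        genes = data.gene_ids[:80]
        b1 = pick_soft_threshold(data, genes)
        b2 = pick_soft_threshold(data, genes)
        assert b1 == b2


class TestTom:
    def test_fully_connected_triangle(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(topological_overlap(a), np.ones((3, 3)))

    def test_disconnected_pair_zero(self):
        a = np.eye(4)
        np.testing.assert_allclose(topological_overlap(a), np.eye(4))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = random_adjacency(rng)
            np.testing.assert_allclose(
                topological_overlap(a), brute_force_tom(a), atol=1e-12
            )

    def test_invariants_on_random_matrices(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            tom = topological_overlap(random_adjacency(rng, n=12))
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(tom), 1.0)
            assert (tom >= 0).all() and (tom <= 1).all()

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestModuleDetection:
    def block_tom(self):
        genes = [f"G{i:02d}" for i in range(8)]
        tom = np.full((8, 8), 0.01)
        tom[:4, :4] = 0.8
        tom[4:, 4:] = 0.8
        np.fill_diagonal(tom, 1.0)
        return pd.DataFrame(tom, index=genes, columns=genes)

    def test_two_blocks_two_modules(self):
        part = detect_modules(self.block_tom(), cut_height=0.5, min_module_size=3)
        assert part.n_modules() == 2
        labels = part.labels
        assert len(set(labels[labels > 0])) == 2
        # each block uniform
        assert len(set(labels.iloc[:4])) == 1

    def test_min_size_larger_than_n_all_unassigned(self):
        part = detect_modules(self.block_tom(), cut_height=0.5, min_module_size=99)
        assert (part.labels == 0).all()
        assert part.n_modules() == 0

    def test_labels_ordered_by_decreasing_size(self):
        genes = [f"G{i:02d}" for i in range(9)]
        tom = np.full((9, 9), 0.01)
        tom[:3, :3] = 0.9   # small block
        tom[3:, 3:] = 0.9   # large block
        np.fill_diagonal(tom, 1.0)
        df = pd.DataFrame(tom, index=genes, columns=genes)
        part = detect_modules(df, cut_height=0.5, min_module_size=3)
        assert part.summaries.loc[part.summaries["module"] == 1, "size"].iloc[0] == 6

    def test_planted_modules_recovered(self):
        """ARI >= 0.9 against planted labels at module_r2=0.6,
        module_size=30, 24 samples (signed network + eigengene
        refinement of fine-cut seed modules)."""
        recovered = 0
        for seed in range(3):
            cfg = SimulationConfig(
                n_genes=150, groups=(("T", "C"),), de_fraction={}, n_modules=3,
                module_size=30, module_r2=0.6, seed=seed,
            )
            data, truth = simulate_dataset(cfg)
            planted = sorted(truth.module_of)
            adj = adjacency_matrix(data, planted, beta=10, signed=True)
            tom = topological_overlap(adj)
            seeds_part = detect_modules(tom, cut_height=0.93, min_module_size=10)
            part = refine_modules(data, seeds_part, tom=tom, min_module_size=20)
            true_labels = [truth.module_of[g] for g in part.labels.index]
            if adjusted_rand_score(true_labels, part.labels) >= 0.9:
                recovered += 1
        assert recovered >= 2


class TestRefineModules:
    def setup_sim(self, seed=4001):
        cfg = SimulationConfig(
            n_genes=150, groups=(("T", "C"),), de_fraction={}, n_modules=3,
            module_size=30, module_r2=0.6, seed=seed,
        )
        return simulate_dataset(cfg)

    def test_background_genes_stay_unassigned(self):
        data, truth = self.setup_sim()
        genes = sorted(data.gene_ids)
        tom = topological_overlap(
            adjacency_matrix(data, genes, beta=10, signed=True))
        # denser universe -> smaller TOM values -> higher merge heights,
        # so the seed cut sits a little above the planted-only setting
        seeds = detect_modules(tom, cut_height=0.95, min_module_size=10)
        part = refine_modules(data, seeds, tom=tom, min_module_size=20)
        background = [g for g in genes if g not in truth.module_of]
        frac_bg_unassigned = (part.labels.loc[background] == 0).mean()
        assert frac_bg_unassigned > 0.5
        planted = sorted(truth.module_of)
        assert (part.labels.loc[planted] > 0).mean() > 0.9

    def test_oversplit_factor_modules_remerge(self):
        """Two seed modules driven by one latent factor merge into one
        module when their eigengenes correlate above the threshold."""
        data, truth = self.setup_sim()
        planted = sorted(g for g, m in truth.module_of.items() if m == 1)
        half1, half2 = planted[:15], planted[15:]
        labels = pd.Series(
            [1] * 15 + [2] * 15, index=half1 + half2, name="module"
        )
        from adjx.coexpression import ModulePartition
        seeds = ModulePartition(labels, pd.DataFrame())
        part = refine_modules(data, seeds, min_module_size=20)
        assert part.n_modules() == 1
        assert (part.labels > 0).sum() >= 25

    def test_eigengene_orientation_positive(self):
        data, truth = self.setup_sim()
        genes = sorted(g for g, m in truth.module_of.items() if m == 1)
        x = data.values.loc[genes].to_numpy()
        e = module_eigengene(x)
        xs = (x - x.mean(axis=1, keepdims=True))
        assert np.corrcoef(e, xs.mean(axis=0))[0, 1] > 0
        assert e.shape == (data.n_samples,)


class TestModuleEnrichment:
    def make_partition(self, labels: dict):
        s = pd.Series(labels, name="module")
        sizes = s.value_counts()
        from adjx.coexpression import ModulePartition
        summaries = pd.DataFrame(
            {"module": sizes.index, "size": sizes.values,
             "mean_intramodular_tom": np.nan}
        )
        return ModulePartition(s, summaries)

    def test_exact_combinatorial_p(self):
        universe = [f"G{i}" for i in range(20)]
        part = self.make_partition({g: (1 if i < 5 else 0)
                                    for i, g in enumerate(universe)})
        sets = GeneSetCollection({"S": ("d", tuple(universe[:5]))})
        out = module_enrichment(part, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        part = self.make_partition({g: 1 for g in universe[:5]})
        sets = GeneSetCollection({"S": ("d", tuple(universe[10:15]))})
        out = module_enrichment(part, sets, universe)
        assert out["p"].iloc[0] == 1.0

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(41)
        universe = [f"G{i}" for i in range(200)]
        ps = []
        for rep in range(200):
            mod = set(rng.choice(universe, size=20, replace=False))
            part = self.make_partition({g: (1 if g in mod else 0)
                                        for g in universe})
            members = tuple(rng.choice(universe, size=30, replace=False))
            sets = GeneSetCollection({"S": ("d", members)})
            ps.append(module_enrichment(part, sets, universe)["p"].iloc[0])
        # hypergeometric p is discrete and conservative: sub-uniform tail
        assert (np.array(ps) <= 0.05).mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 200)

    def test_universe_must_cover_partition(self):
        part = self.make_partition({"G1": 1, "G2": 1})
        sets = GeneSetCollection({"S": ("d", ("G1",))})
        with pytest.raises(ValueError, match="universe"):
            module_enrichment(part, sets, ["G1"])

    def test_null_bh_call_rate_controlled(self):
        rng = np.random.default_rng(42)
        universe = [f"G{i}" for i in range(300)]
        mod_labels = {g: (1 if i < 30 else (2 if i < 60 else 0))
                      for i, g in enumerate(universe)}
        part = self.make_partition(mod_labels)
        sets = GeneSetCollection({
            f"S{i}": ("d", tuple(rng.choice(universe, size=25, replace=False)))
            for i in range(40)
        })
        out = module_enrichment(part, sets, universe)
        assert (out["q"] <= 0.05).mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(out))


class TestEstimator:
    def test_labels_match_planted_modules(self):
        cfg = SimulationConfig(
            n_genes=90, groups=(("T", "C"),), de_fraction={}, n_modules=3,
            module_size=30, module_r2=0.7, seed=51,
        )
        data, truth = simulate_dataset(cfg)
        planted = sorted(truth.module_of)
        X = data.values.loc[planted].to_numpy().T  # samples x genes
        est = CoexpressionModules(beta=6, min_module_size=20).fit(X)
        true_labels = [truth.module_of[g] for g in planted]
        assert adjusted_rand_score(true_labels, est.labels_) >= 0.9
        assert est.beta_ == 6
        assert est.tom_.shape == (90, 90)

    def test_params_round_trip(self):
        est = CoexpressionModules(beta=4, cut_height=0.9)
        params = est.get_params()
        assert params["beta"] == 4 and params["cut_height"] == 0.9
        est.set_params(beta="auto")
        assert est.beta == "auto"


def test_config_validation():
    with pytest.raises(ValueError):
        CoexprConfig(q_select=0)
    with pytest.raises(ValueError):
        CoexprConfig(beta=0)
    with pytest.raises(ValueError):
        CoexprConfig(cut_height=1.5)
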