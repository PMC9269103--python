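import numpy as np
import pytest
from conftest import (
    ls_oracle_topology,
    nj_bipartitions,
    random_additive_tree,
    three_population_spec,
)

from ssrforge import (
    DistanceMatrix,
    GenotypeMatrix,
    bootstrap_tree,
    dpsa,
    dpsa_matrix,
    neighbor_joining,
    simulate_genotypes,
    write_newick,
)
from ssrforge.distance import support_for_clade


def _matrix(calls, loci):
    inds = sorted({i for i, _ in calls})
    return GenotypeMatrix(inds, loci, calls)


class TestDpsa:
    def test_identical_and_fully_distinct(self):
        calls = {
            ("a", "L1"): (100, 102), ("a", "L2"): (200, 202),
            ("b", "L1"): (100, 102), ("b", "L2"): (200, 202),
            ("c", "L1"): (104, 106), ("c", "L2"): (204, 206),
        }
        m = _matrix(calls, ["L1", "L2"])
        assert dpsa(m, "a", "b") == 0.0
        assert dpsa(m, "a", "c") == 1.0

    def test_hand_counted_half_sharing(self):
        calls = {
            ("a", "L1"): (100, 102), ("a", "L2"): (200, 200),
            ("b", "L1"): (100, 104), ("b", "L2"): (200, 202),
        }
        m = _matrix(calls, ["L1", "L2"])
        assert dpsa(m, "a", "b") == pytest.approx(0.5)  # 1 - (1+1)/4

    def test_duplicated_allele_matched_at_most_once(self):
        calls = {("a", "L1"): (100, 100), ("b", "L1"): (100, 102)}
        m = _matrix(calls, ["L1"])
        assert dpsa(m, "a", "b") == pytest.approx(0.5)  # one match, not two

    def test_missing_loci_use_pairwise_complete_normalization(self):
        calls = {
            ("a", "L1"): (100, 102), ("a", "L2"): None,
            ("b", "L1"): (100, 102), ("b", "L2"): (200, 202),
        }
        m = _matrix(calls, ["L1", "L2"])
        assert dpsa(m, "a", "b") == 0.0  # only L1 is co-typed
        none_shared = {("a", "L1"): None, ("b", "L1"): (1, 2)}
        with pytest.raises(ValueError):
            dpsa(_matrix(none_shared, ["L1"]), "a", "b")

    def test_values_quantized_to_half_per_locus_steps(self):
        spec = three_population_spec(seed=13, n_per_pop=4, n_loci=12)
        m, _ = simulate_genotypes(spec)
        dm = dpsa_matrix(m)
        steps = dm.values * 24  # 12 loci, all co-typed
        assert np.allclose(steps, np.round(steps), atol=1e-9)
        assert dm.values.min() >= 0 and dm.values.max() <= 1
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)


class TestNeighborJoining:
    def test_quartet_recovers_split_and_branch_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        bips = nj_bipartitions(tree, labels)
        assert bips == {frozenset({2, 3})}  # AB|CD
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_deterministic_on_ultrametric_ties(self):
        labels = ["A", "B", "C", "D"]
        d = np.ones((4, 4)) - np.eye(4)
        t1 = write_newick(neighbor_joining(DistanceMatrix(labels, d)))
        t2 = write_newick(neighbor_joining(DistanceMatrix(labels, d)))
        assert t1 == t2

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"], -np.ones((3, 3)) + np.eye(3) * 1)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("n", [5, 6])
    def test_matches_exhaustive_least_squares_oracle(self, n):
        """On additive matrices NJ finds the same topology as exhaustive
        least-squares search over all unrooted topologies."""
        rng = np.random.default_rng(100 + n)
        labels = [f"T{i}" for i in range(n)]
        for _ in range(5):
            true_bips, dist = random_additive_tree(rng, n)
            oracle_bips, sse = ls_oracle_topology(dist, n)
            assert sse < 1e-12
            assert oracle_bips == true_bips
            tree = neighbor_joining(DistanceMatrix(labels, dist))
            assert nj_bipartitions(tree, labels) == true_bips

    @pytest.mark.parametrize("n", [7, 8])
    def test_recovers_generating_topology_at_larger_n(self, n):
        rng = np.random.default_rng(200 + n)
        labels = [f"T{i}" for i in range(n)]
        for _ in range(10):
            true_bips, dist = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, dist))
            assert nj_bipartitions(tree, labels) == true_bips

    def test_additive_path_lengths_reproduced(self):
        rng = np.random.default_rng(77)
        _, dist = random_additive_tree(rng, 8)
        labels = [f"T{i}" for i in range(8)]
        tree = neighbor_joining(DistanceMatrix(labels, dist))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(8):
            for j in range(i + 1, 8):
                assert pdm.distance(taxa[f"T{i}"], taxa[f"T{j}"]) == pytest.approx(
                    dist[i, j], abs=1e-9
                )


class TestBootstrap:
    def test_disjoint_populations_get_high_support(self):
        spec = three_population_spec(seed=7, n_per_pop=6, n_loci=12)
        m, _ = simulate_genotypes(spec)
        full, consensus = bootstrap_tree(m, n_reps=100, seed=3)
        for pop in ("P1", "P2", "P3"):
            members = {i for i, p in zip(m.individuals, m.populations) if p == pop}
            support = support_for_clade(full, members)
            assert support is not None and support >= 95.0
        assert consensus is not None

    def test_seed_reproducibility(self):
        spec = three_population_spec(seed=5, n_per_pop=4, n_loci=8)
        m, _ = simulate_genotypes(spec)
        t1, _ = bootstrap_tree(m, n_reps=30, seed=11)
        t2, _ = bootstrap_tree(m, n_reps=30, seed=11)
        assert write_newick(t1) == write_newick(t2)

    def test_degenerate_duplicated_individuals_still_defined(self):
        calls = {}
        for i in range(4):
            calls[(f"dup{i}", "L1")] = (100, 102)
            calls[(f"dup{i}", "L2")] = (200, 202)
        calls[("out", "L1")] = (110, 112)
        calls[("out", "L2")] = (210, 212)
        m = GenotypeMatrix([f"dup{i}" for i in range(4)] + ["out"], ["L1", "L2"], calls)
        full, _ = bootstrap_tree(m, n_reps=20, seed=1)
        for node in full.preorder_node_iter():
            if not node.is_leaf() and node is not full.seed_node:
                assert node.label is not None
                assert 0 <= float(node.label) <= 100

    def test_single_locus_is_an_error(self):
        calls = {(f"s{i}", "L1"): (100, 102) for i in range(3)}
        m = GenotypeMatrix([f"s{i}" for i in range(3)], ["L1"], calls)
        with pytest.raises(ValueError, match="2 loci"):
            bootstrap_tree(m, n_reps=10, seed=0)
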