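import shutil

import numpy as np
import pytest

import oracles
from coretree.align import LocusAlignment
from coretree.fixtures import caterpillar_tree, random_tree, simulate_alignment
from coretree.screen import LocusSelection
from coretree.trees import (
    PhylogeneticTree,
    build_all_trees,
    build_tree,
    neighbor_joining,
    pairwise_distances,
)


def _tree_distances(tree: PhylogeneticTree, labels):
    """Additive tip-to-tip path distances of a generating tree."""
    import dendropy

    dtree = dendropy.Tree.get(data=tree.newick, schema="newick")
    pdm = dtree.phylogenetic_distance_matrix()
    index = {t.label: t for t in dtree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                index[labels[i]], index[labels[j]]
            )
    return d


class TestNeighborJoining:
    def test_four_point_quartet(self):
        # additive: AB|CD with internal edge of length 2
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        newick = neighbor_joining(labels, d)
        splits = oracles.bipartitions(newick)
        assert len(splits) == 1
        (split,) = splits
        assert frozenset([frozenset("AB"), frozenset("CD")]) == split

    def test_three_taxa_unique_topology(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        newick = neighbor_joining(["A", "B", "C"], d)
        assert oracles.bipartitions(newick) == set()
        assert {"A", "B", "C"} == oracles._tips(oracles.parse_newick(newick))

    @pytest.mark.parametrize("n,seed", [(5, 0), (5, 1), (6, 2), (6, 3), (6, 4)])
    def test_additive_matrix_recovers_topology_vs_enumeration_oracle(
        self, n, seed
    ):
        """On an additive matrix NJ must return the unique topology that
        satisfies the four-point condition for every quartet (brute-force
        enumeration over all unrooted topologies)."""
        labels = [f"g{i:02d}" for i in range(n)]
        tree = random_tree(n, rng_seed=seed, internal_range=(0.2, 0.5),
                           pendant_range=(0.1, 0.3))
        d = _tree_distances(tree, labels)
        want = oracles.topology_by_four_point_condition(labels, d)
        got = oracles.bipartitions(neighbor_joining(labels, d))
        assert got == want
        # and equals the generating topology itself
        assert got == oracles.bipartitions(tree.newick)

    def test_two_taxa(self):
        newick = neighbor_joining(["A", "B"], np.array([[0, 3], [3, 0.0]]))
        assert newick == "(A:1.500000,B:1.500000);"


class TestBuildTree:
    def test_simulated_eight_taxon_recovery(self):
        tree = caterpillar_tree(8, internal_length=0.4, pendant_length=0.1)
        alignment = simulate_alignment(tree, length=2000, rng_seed=1)
        inferred = build_tree(alignment, method="internal-nj")
        rf, _ = oracles.rf_by_enumeration(tree.newick, inferred.newick)
        assert rf == 0

    def test_deterministic_newick_bytes(self):
        tree = random_tree(6, rng_seed=7)
        alignment = simulate_alignment(tree, length=300, rng_seed=2)
        first = build_tree(alignment).newick
        second = build_tree(alignment).newick
        assert first == second

    def test_tip_set_equals_alignment_rows(self):
        tree = random_tree(5, rng_seed=8)
        alignment = simulate_alignment(tree, length=200, rng_seed=3)
        inferred = build_tree(alignment)
        assert inferred.tips() == set(alignment.rows)

    def test_newick_roundtrip_isomorphic(self, tmp_path):
        tree = random_tree(6, rng_seed=9)
        alignment = simulate_alignment(tree, length=200, rng_seed=4)
        inferred = build_tree(alignment)
        path = inferred.write(tmp_path / "t.nwk")
        back = PhylogeneticTree.read(path)
        assert oracles.bipartitions(back.newick) == oracles.bipartitions(
            inferred.newick
        )

    def test_all_gap_row_error(self):
        alignment = LocusAlignment(
            locus_id="L", rows={"a": "MK", "b": "MK", "c": "--"}
        )
        with pytest.raises(ValueError, match="c"):
            build_tree(alignment)

    def test_too_few_taxa(self):
        alignment = LocusAlignment(locus_id="L", rows={"a": "MK", "b": "MK"})
        with pytest.raises(ValueError):
            build_tree(alignment)

    def test_unknown_method(self):
        alignment = LocusAlignment(
            locus_id="L", rows={"a": "MK", "b": "MK", "c": "MR"}
        )
        from coretree._errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            build_tree(alignment, method="parsimony")

    @pytest.mark.skipif(shutil.which("fasttree") is None,
                        reason="fasttree not installed")
    def test_fasttree_adapter(self):
        tree = caterpillar_tree(6, internal_length=0.4, pendant_length=0.1)
        alignment = simulate_alignment(tree, length=500, rng_seed=5)
        inferred = build_tree(alignment, method="fasttree")
        assert inferred.tips() == set(alignment.rows)
        assert inferred.internal_supports()  # fasttree emits local supports
        rf, _ = oracles.rf_by_enumeration(tree.newick, inferred.newick)
        assert rf == 0


class TestPairwiseDistances:
    def test_poisson_correction(self):
        rows = {"a": "AAAA", "b": "AAAT"}
        labels, d = pairwise_distances(rows)
        assert d[0, 1] == pytest.approx(-np.log(1 - 0.25))

    def test_gap_columns_excluded(self):
        rows = {"a": "AA-A", "b": "AT-A"}
        _, d = pairwise_distances(rows)
        assert d[0, 1] == pytest.approx(-np.log(1 - 1 / 3))

    def test_saturated_pair_clamped(self):
        rows = {"a": "A" * 10, "b": "C" * 10}
        _, d = pairwise_distances(rows)
        assert d[0, 1] == pytest.approx(-np.log(0.05))


class TestBuildAllTrees:
    def _selection(self, loci):
        return LocusSelection(
            loci=sorted(loci), members={}, presence_threshold=100.0,
            maxloci=None, seed_genome="g00",
        )

    def test_one_tree_per_locus(self, tmp_path):
        tree = random_tree(5, rng_seed=10)
        alignments = {
            f"L{i}": simulate_alignment(tree, length=120, rng_seed=20 + i)
            for i in range(5)
        }
        for locus, alignment in alignments.items():
            alignment.locus_id = locus
        result = build_all_trees(
            self._selection(alignments), alignments, out_dir=tmp_path
        )
        assert sorted(result) == sorted(alignments)
        assert len(list(tmp_path.glob("*.nwk"))) == 5

    def test_small_locus_skipped_with_warning(self, caplog):
        tree = random_tree(4, rng_seed=11)
        alignments = {
            "L0": simulate_alignment(tree, length=100, rng_seed=30),
            "L1": LocusAlignment(locus_id="L1", rows={"a": "MK", "b": "MK"}),
        }
        alignments["L0"].locus_id = "L0"
        import logging

        with caplog.at_level(logging.WARNING):
            result = build_all_trees(self._selection(alignments), alignments)
        assert sorted(result) == ["L0"]
        assert any("L1" in r.message for r in caplog.records)

    def test_common_generating_tree_gives_identical_topologies(self):
        tree = caterpillar_tree(6, internal_length=0.5, pendant_length=0.1)
        alignments = {}
        for i in range(4):
            alignment = simulate_alignment(tree, length=1500, rng_seed=40 + i)
            alignment.locus_id = f"L{i}"
            alignments[f"L{i}"] = alignment
        result = build_all_trees(self._selection(alignments), alignments)
        want = oracles.bipartitions(tree.newick)
        for locus, inferred in result.items():
            assert oracles.bipartitions(inferred.newick) == want, locus
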