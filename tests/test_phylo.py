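"""Jukes-Cantor distances, NJ reconstruction, bootstrap, branch assignment."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio import tree as skbio_tree

from rdnaprof.phylo import (
    MAX_JC_DISTANCE,
    bootstrap_support,
    branch_assign,
    jc_distance,
    jc_distance_matrix,
    nj_tree,
    write_newick,
)


class TestJCDistance:
    def test_identical_sequences_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_ten_percent(self):
        # p = 0.1 -> d = -(3/4) ln(1 - 0.4/3) = 0.107326...
        seq_a = "A" * 100
        seq_b = "C" * 10 + "A" * 90
        expected = -0.75 * math.log(1 - 0.4 / 3)
        assert jc_distance(seq_a, seq_b) == pytest.approx(expected)
        assert jc_distance(seq_a, seq_b) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_is_capped_and_flagged_value(self):
        seq_a = "A" * 4
        seq_b = "C" * 3 + "A"  # p = 0.75
        assert jc_distance(seq_a, seq_b) == MAX_JC_DISTANCE

    def test_distance_dominates_p(self):
        for n_diff in range(1, 74):
            seq_a = "A" * 100
            seq_b = "C" * n_diff + "A" * (100 - n_diff)
            p = n_diff / 100
            assert jc_distance(seq_a, seq_b) >= p

    def test_pairwise_deletion_of_gap_columns(self):
        # the gap/N column is excluded, so p = 1/5 over comparable columns
        d = jc_distance("AC-GTA", "ACNGTT")
        expected = -0.75 * math.log(1 - (1 / 5) * 4 / 3)
        assert d == pytest.approx(expected)

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError):
            jc_distance("---", "AAA")

    def test_matrix_agrees_with_scalar(self):
        seqs = ["ACGTACGTAA", "ACGTACGTAT", "TTTTACGTAA"]
        dm = jc_distance_matrix(seqs, ["a", "b", "c"])
        for i, x in enumerate(seqs):
            for j, y in enumerate(seqs):
                if i != j:
                    assert dm.data[i, j] == pytest.approx(jc_distance(x, y))


def additive_matrix():
    """4-taxon additive metric from a known tree:
    ((A:2,B:3):1,(C:4,D:5)) with internal edge 1."""
    labels = ["A", "B", "C", "D"]
    d = {
        ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
        ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
    }
    mat = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i < j:
                mat[i, j] = mat[j, i] = d[(x, y)]
    return DistanceMatrix(mat, ids=labels)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float),
            ids=["a", "b", "c"],
        )
        tree = nj_tree(dm)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        # three-point formulas: a = (dab+dac-dbc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(5.0)

    def test_additive_four_taxon_metric_recovered_exactly(self):
        tree = nj_tree(additive_matrix())
        # topology: A+B vs C+D
        dists = tree.tip_tip_distances()
        original = additive_matrix()
        for x in "ABCD":
            for y in "ABCD":
                if x != y:
                    assert dists[x, y] == pytest.approx(original[x, y])
        # the AB|CD split must exist (one cherry forms a clade; the other
        # pair attaches at the trifurcating root of the unrooted tree)
        clades = {
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips(include_self=False)
        }
        assert frozenset("AB") in clades or frozenset("CD") in clades

    def test_closest_ultrametric_pair_joins_first(self):
        labels = ["a", "b", "c", "d"]
        mat = np.array([
            [0, 2, 10, 10],
            [2, 0, 10, 10],
            [10, 10, 0, 6],
            [10, 10, 6, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(mat, ids=labels))
        lca = tree.lowest_common_ancestor(["a", "b"])
        assert {t.name for t in lca.tips()} == {"a", "b"}

    def test_agrees_with_skbio_nj_on_random_additive_matrices(self, rng):
        # independent cross-check against scikit-bio's NJ implementation
        for trial in range(5):
            # random additive metric from a random 6-taxon tree
            n = 6
            labels = [f"t{i}" for i in range(n)]
            lengths = rng.uniform(0.5, 3.0, size=2 * n)
            # build a caterpillar tree metric
            mat = np.zeros((n, n))
            positions = np.cumsum(lengths[:n])
            depths = lengths[n:]
            for i in range(n):
                for j in range(n):
                    if i != j:
                        mat[i, j] = (
                            abs(positions[i] - positions[j])
                            + depths[i] + depths[j]
                        )
            mat = (mat + mat.T) / 2  # remove float round-off asymmetry
            dm = DistanceMatrix(mat, ids=labels)
            mine = nj_tree(dm)
            theirs = skbio_tree.nj(dm)
            d_mine = mine.tip_tip_distances()
            d_theirs = theirs.tip_tip_distances()
            for x in labels:
                for y in labels:
                    if x != y:
                        assert d_mine[x, y] == pytest.approx(
                            d_theirs[x, y], abs=1e-6)

    def test_too_few_taxa_raise(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_negative_lengths_clamped_and_flagged(self):
        mat = np.array([
            [0, 1, 10, 9],
            [1, 0, 9, 10],
            [10, 9, 0, 1],
            [9, 10, 1, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(mat, ids=list("abcd")))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


def two_cluster_alignment(n_per_side=6, length=40, seed=0, noise=1):
    """Two diverged families; ``noise`` private mutations per leaf."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    d = "".join(bases[i] for i in rng.integers(0, 4, length))
    s = list(d)
    for pos in rng.choice(length, size=length // 4, replace=False):
        s[pos] = bases[(bases.index(s[pos]) + 1) % 4]
    s = "".join(s)
    alignment = []
    for i in range(n_per_side):
        alignment.append((f"D{i}", _mutate(d, rng, noise)))
        alignment.append((f"S{i}", _mutate(s, rng, noise)))
    return alignment


def _mutate(seq, rng, n):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = "ACGT"[(("ACGT").index(out[pos]) + 1) % 4]
    return "".join(out)


class TestBootstrap:
    def test_strong_split_gets_full_support(self):
        # identical sequences within each family, strongly partitioned
        # columns between them: every replicate recovers the D/S split
        alignment = two_cluster_alignment(noise=0)
        tree = bootstrap_support(alignment, n_replicates=50, seed=1)
        labels_d = {name for name, _ in alignment if name.startswith("D")}
        # find the edge separating D from S and check its support
        supports = []
        for node in tree.non_tips():
            side = {t.name for t in node.tips()}
            if side == labels_d or side == (
                {name for name, _ in alignment} - labels_d
            ):
                supports.append(getattr(node, "support", None))
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_in_range_and_deterministic(self):
        alignment = two_cluster_alignment(n_per_side=4, seed=2)
        t1 = bootstrap_support(alignment, n_replicates=30, seed=3)
        t2 = bootstrap_support(alignment, n_replicates=30, seed=3)
        s1 = sorted(
            getattr(n, "support", -1) for n in t1.non_tips()
            if hasattr(n, "support")
        )
        s2 = sorted(
            getattr(n, "support", -1) for n in t2.non_tips()
            if hasattr(n, "support")
        )
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)


class TestBranchAssign:
    def test_two_cluster_assignment_matches_truth(self):
        alignment = two_cluster_alignment()
        dm = jc_distance_matrix(
            [seq for _, seq in alignment], [name for name, _ in alignment])
        tree = nj_tree(dm)
        assignment = branch_assign(tree, "D0", "S0")
        for name, _ in alignment:
            assert assignment[name] == name[0]

    def test_missing_reference_raises(self):
        alignment = two_cluster_alignment(n_per_side=3)
        dm = jc_distance_matrix(
            [seq for _, seq in alignment], [name for name, _ in alignment])
        tree = nj_tree(dm)
        with pytest.raises(ValueError):
            branch_assign(tree, "D0", "nope")

    def test_agreement_with_nearest_consensus_classifier(self):
        # cross-module property: tree-branch assignment vs Hamming classifier
        from rdnaprof.homoeologue import (
            FragmentSample, classify_fragments, select_diagnostic_window,
        )

        alignment = two_cluster_alignment(n_per_side=8, length=50, seed=5)
        names = [n for n, _ in alignment]
        seqs = [s for _, s in alignment]
        tree = nj_tree(jc_distance_matrix(seqs, names))
        tree_labels = branch_assign(tree, "D0", "S0")

        d_ref = dict(alignment)["D0"]
        s_ref = dict(alignment)["S0"]
        window = select_diagnostic_window(d_ref, s_ref, width=50)
        sample = FragmentSample(fragments=list(zip(names, seqs)))
        sample, _ = classify_fragments(sample, window)
        agree = sum(
            1 for n in names
            if sample.labels[n] == tree_labels[n]
        )
        assert agree / len(names) >= 0.99


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_preserved(self, tmp_path):
        from skbio import TreeNode

        alignment = two_cluster_alignment(n_per_side=4, seed=7)
        tree = bootstrap_support(alignment, n_replicates=20, seed=8)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        loaded = TreeNode.read(str(path), format="newick")
        orig = {frozenset(t.name for t in n.tips()): round(n.length or 0, 6)
                for n in tree.non_tips()}
        back = {frozenset(t.name for t in n.tips()): round(n.length or 0, 6)
                for n in loaded.non_tips()}
        assert orig == back
        orig_supports = sorted(
            f"{n.support:g}" for n in tree.non_tips() if hasattr(n, "support")
        )
        back_supports = sorted(
            n.name for n in loaded.non_tips() if n.name
        )
        assert orig_supports == back_supports
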