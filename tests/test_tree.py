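"""Neighbour joining, bootstrap, monophyly and threshold clustering."""

import io

import numpy as np
import pytest
from skbio.tree import TreeNode

from barcode_audit import (
    bipartitions,
    bootstrap_supports,
    monophyly_report,
    nj_tree,
    threshold_clusters,
)
from barcode_audit.tree import MONOPHYLETIC, NON_MONOPHYLETIC, TRIVIAL

from conftest import dm_from_array, make_library, random_additive_tree


def _path_lengths(tree: TreeNode, names):
    dm = tree.tip_tip_distances()
    return np.array([[dm[a, b] for b in names] for a in names])


class TestNeighbourJoining:
    def test_recovers_classic_additive_matrix(self):
        # textbook 4-taxon additive matrix
        d = np.array(
            [
                [0, 5, 9, 9],
                [5, 0, 10, 10],
                [9, 10, 0, 8],
                [9, 10, 8, 0],
            ],
            dtype=float,
        )
        m = dm_from_array(d, ids=list("abcd"))
        tree = nj_tree(m, clamp_negative=False)
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        np.testing.assert_allclose(
            _path_lengths(tree, list("abcd")), d, atol=1e-9
        )

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            names, d = random_additive_tree(n, rng)
            tree = nj_tree(dm_from_array(d, ids=names), clamp_negative=False)
            np.testing.assert_allclose(_path_lengths(tree, names), d, atol=1e-8)

    def test_tie_break_deterministic(self):
        # fully symmetric matrix: every Q value ties; the rule picks the
        # lexicographically smallest pair, so {c, d} remains as the split
        d = np.full((4, 4), 1.0) - np.eye(4)
        tree = nj_tree(dm_from_array(d, ids=list("dcba")))
        assert bipartitions(tree) == {frozenset({"c", "d"})}

    def test_agrees_with_external_nj_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(11)
        names, d = random_additive_tree(9, rng)
        ours = nj_tree(dm_from_array(d, ids=names), clamp_negative=False)
        theirs = sk_nj(SkDM(d, names))
        assert bipartitions(ours) == bipartitions(theirs)

    def test_negative_branch_clamped_path_preserved(self):
        # matrix engineered to produce a negative limb estimate
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.45],
                [0.1, 0.0, 0.5, 0.55],
                [0.4, 0.5, 0.0, 0.3],
                [0.45, 0.55, 0.3, 0.0],
            ]
        )
        tree = nj_tree(dm_from_array(d, ids=list("abcd")), clamp_negative=True)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0
        # cherry path lengths survive the clamp
        raw = nj_tree(dm_from_array(d, ids=list("abcd")), clamp_negative=False)
        pl_raw = _path_lengths(raw, list("abcd"))
        pl_clamped = _path_lengths(tree, list("abcd"))
        # the clamped cherry keeps its internal pairwise path length
        split = next(iter(bipartitions(tree)))
        pair = sorted(split)
        i, j = [list("abcd").index(x) for x in pair]
        assert pl_clamped[i, j] == pytest.approx(pl_raw[i, j], abs=1e-12)

    def test_undefined_cells_dropped_greedily(self):
        d = np.array(
            [
                [0.0, 0.1, 0.2, np.nan],
                [0.1, 0.0, 0.25, np.nan],
                [0.2, 0.25, 0.0, np.nan],
                [np.nan, np.nan, np.nan, 0.0],
            ]
        )
        tree = nj_tree(dm_from_array(d, ids=list("abcd")))
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]

    def test_too_few_specimens_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(dm_from_array(np.zeros((2, 2)), ids=list("ab")))

    def test_identical_leaves_form_a_clade(self):
        # zero-distance leaves are joined first, so duplicated sequences
        # always come out as a clade regardless of Q ties elsewhere
        rng = np.random.default_rng(21)
        names, d = random_additive_tree(8, rng)
        # duplicate two leaves at distance zero
        n = len(names)
        dd = np.zeros((n + 2, n + 2))
        dd[:n, :n] = d
        for extra, src in ((n, 2), (n + 1, 2)):
            dd[extra, :n] = d[src, :]
            dd[:n, extra] = d[src, :]
        names = names + ["Ldup1", "Ldup2"]
        tree = nj_tree(dm_from_array(dd, ids=names))
        clones = frozenset({names[2], "Ldup1", "Ldup2"})
        assert clones in bipartitions(tree)
        # the clone clade sits at zero internal path length
        dm = tree.tip_tip_distances()
        assert dm[names[2], "Ldup1"] == pytest.approx(0.0, abs=1e-12)

    def test_trifurcating_root(self):
        rng = np.random.default_rng(3)
        names, d = random_additive_tree(7, rng)
        tree = nj_tree(dm_from_array(d, ids=names))
        assert len(tree.children) == 3


class TestMonophyly:
    def _tree(self, newick):
        return TreeNode.read(io.StringIO(newick))

    def test_clean_clades(self):
        t = self._tree("((a1:1,a2:1):1,(b1:1,b2:1):1,c1:1);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        rep = monophyly_report(t, labels).set_index("species")
        assert rep.loc["A", "status"] == MONOPHYLETIC
        assert rep.loc["B", "status"] == MONOPHYLETIC
        assert rep.loc["C", "status"] == TRIVIAL

    def test_interleaved_species_flagged_with_conflicts(self):
        t = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1,c1:1);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        rep = monophyly_report(t, labels).set_index("species")
        assert rep.loc["A", "status"] == NON_MONOPHYLETIC
        assert rep.loc["B", "status"] == NON_MONOPHYLETIC
        assert "B" in rep.loc["A", "conflicting"]

    def test_unrooted_complement_counts_as_monophyletic(self):
        # A's leaves are exactly the complement of the (b1,b2) clade: on an
        # unrooted tree that *is* an exclusive group
        t = self._tree("((b1:1,b2:1):1,a1:1,(a2:1,a3:1):1);")
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        rep = monophyly_report(t, labels).set_index("species")
        assert rep.loc["A", "status"] == MONOPHYLETIC
        assert rep.loc["B", "status"] == MONOPHYLETIC

    def test_unlabelled_leaf_rejected(self):
        t = self._tree("(a1:1,a2:1,b1:1);")
        with pytest.raises(ValueError, match="b1"):
            monophyly_report(t, {"a1": "A", "a2": "A"})


class TestBootstrap:
    def _lib(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 400))

        def mutate(seq, k, salt):
            r = np.random.default_rng(salt)
            s = list(seq)
            for site in r.choice(400, size=k, replace=False):
                s[site] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[site]]
            return "".join(s)

        far = mutate(base, 80, 9)  # ~20% divergent, well below saturation
        return make_library(
            {
                "A1": base,
                "A2": mutate(base, 2, 1),
                "B1": far,
                "B2": mutate(far, 2, 2),
            },
            species={"A1": "Sp A", "A2": "Sp A", "B1": "Sp B", "B2": "Sp B"},
        )

    def test_seed_determinism(self):
        lib = self._lib()
        t1, s1 = bootstrap_supports(lib, n_replicates=25, seed=42)
        t2, s2 = bootstrap_supports(lib, n_replicates=25, seed=42)
        assert s1 == s2
        assert str(t1) == str(t2)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_supports(self._lib(), n_replicates=5)

    def test_single_replicate_support_is_zero_or_hundred(self):
        _, supports = bootstrap_supports(self._lib(), n_replicates=1, seed=1)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_clear_split_gets_full_support(self):
        tree, supports = bootstrap_supports(self._lib(), n_replicates=50, seed=7)
        split = frozenset({"B1", "B2"})
        assert supports[split] == 100.0
        # support is attached as the internal node name
        internal = [n.name for n in tree.non_tips(include_self=False)]
        assert "100" in internal


class TestThresholdClusters:
    def test_chain_transitivity(self):
        d = np.array(
            [
                [0.000, 0.010, 0.030],
                [0.010, 0.000, 0.010],
                [0.030, 0.010, 0.000],
            ]
        )
        assignment = threshold_clusters(dm_from_array(d, ids=list("abc")), 2.2)
        assert len(set(assignment.assignments.values())) == 1

    def test_threshold_separates_above_joins_below(self):
        # the cut is strict (d < threshold); probe just either side of it
        # rather than the exact float boundary
        for dist, expected in ((0.0221, 2), (0.0219, 1)):
            d = np.array([[0.0, dist], [dist, 0.0]])
            assignment = threshold_clusters(dm_from_array(d, ids=list("ab")), 2.2)
            assert assignment.n_clusters_of(["a", "b"]) == expected

    def test_undefined_pairs_contribute_no_edge(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        assignment = threshold_clusters(dm_from_array(d, ids=list("ab")), 2.2)
        assert assignment.n_clusters_of(["a", "b"]) == 2

    def test_labels_in_first_appearance_order(self):
        d = np.array(
            [
                [0.00, 0.30, 0.01],
                [0.30, 0.00, 0.30],
                [0.01, 0.30, 0.00],
            ]
        )
        assignment = threshold_clusters(dm_from_array(d, ids=list("xyz")), 2.2)
        assert assignment.assignments == {"x": "C0001", "y": "C0002", "z": "C0001"}

    def test_monotone_coarsening(self):
        rng = np.random.default_rng(9)
        n = 12
        raw = rng.uniform(0.001, 0.2, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        m = dm_from_array(d)
        fine = threshold_clusters(m, 1.0)
        coarse = threshold_clusters(m, 8.0)
        # every fine cluster maps into exactly one coarse cluster
        for members in fine.clusters().values():
            assert len({coarse.assignments[s] for s in members}) == 1
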