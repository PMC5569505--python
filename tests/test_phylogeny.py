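"""Supermatrix construction, p-distances, NJ exactness, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magsom import phylogeny as ph
from magsom import synthetic as syn


class TestExtractMarkers:
    def test_basic_and_duplicates(self):
        df = pd.DataFrame(
            [
                {"taxon": "t1", "marker": "rpS3", "sequence": "A" * 180},
                {"taxon": "t1", "marker": "rpS3", "sequence": "A" * 120},
                {"taxon": "t1", "marker": "rpL2", "sequence": "C" * 90},
                {"taxon": "t2", "marker": "rpS3", "sequence": "G" * 150},
                {"taxon": "t1", "marker": "not_a_marker", "sequence": "T" * 10},
            ]
        )
        blocks, log = ph.extract_markers(df)
        assert len(blocks["rpS3"]["t1"]) == 180
        assert len(log) == 1 and "180" in log[0]
        assert "not_a_marker" not in blocks


class TestConcatenate:
    def _blocks(self, taxa, markers, length=10):
        rng = np.random.default_rng(1)
        return {
            m: {
                t: "".join(rng.choice(list(syn.AMINO_ACIDS), size=length))
                for t in taxa
            }
            for m in markers
        }

    def test_row_length_conservation(self):
        blocks = {
            "rpL2": {t: "A" * 10 for t in "xyz"},
            "rpL3": {t: "C" * 20 for t in "xyz"},
        }
        sm = ph.concatenate(blocks, ph.SET15, min_markers=2)
        assert sm.length == 30
        assert all(len(s) == 30 for s in sm.sequences.values())
        assert sm.partition_lines() == ["rpL2 = 1-10", "rpL3 = 11-30"]

    def test_missing_block_gap_filled(self):
        blocks = {
            "rpL2": {"x": "A" * 10, "y": "A" * 10, "z": "A" * 10},
            "rpL3": {"x": "C" * 20, "y": "C" * 20},
        }
        sm = ph.concatenate(blocks, ph.SET15, min_markers=1)
        assert sm.sequences["z"][10:30] == "-" * 20

    def test_min_marker_inclusion_boundary(self):
        markers = list(ph.RIBOSOMAL_15)
        blocks = self._blocks(["rich"], markers, 8)
        # taxon with exactly 8 markers is included, 7 is excluded
        for m in markers[:8]:
            blocks[m]["eight"] = blocks[m]["rich"]
        for m in markers[:7]:
            blocks[m]["seven"] = blocks[m]["rich"]
        sm = ph.concatenate(blocks, ph.SET15, min_markers=8)
        assert "eight" in sm.taxa
        assert "seven" not in sm.taxa
        assert "seven" in sm.excluded

    def test_unequal_rows_rejected(self):
        blocks = {"rpL2": {"x": "AA", "y": "AAA"}}
        with pytest.raises(ValueError, match="unequal"):
            ph.concatenate(blocks, ph.SET15, min_markers=1)


class TestPairwiseDistances:
    def _sm(self, rows):
        taxa = sorted(rows)
        return ph.Supermatrix(
            taxa, rows, [("b", 0, len(next(iter(rows.values()))))],
            {t: {"b"} for t in taxa},
        )

    def test_identical_and_simple(self):
        sm = self._sm({"a": "AAAA", "b": "AAAA", "c": "AAAT"})
        d, _ = ph.pairwise_distances(sm, min_shared=1)
        assert d[0, 1] == 0.0
        assert d[0, 2] == pytest.approx(0.25)

    def test_pairwise_deletion_oracle(self):
        rng = np.random.default_rng(17)
        alpha = list("ACDEF-")
        rows = {
            f"t{i}": "".join(rng.choice(alpha, size=120, p=[0.18] * 5 + [0.1]))
            for i in range(5)
        }
        sm = self._sm(rows)
        d, _ = ph.pairwise_distances(sm, min_shared=1)
        taxa = sm.taxa
        for i, j in itertools.combinations(range(5), 2):
            a, b = rows[taxa[i]], rows[taxa[j]]
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            expect = sum(x != y for x, y in shared) / len(shared)
            assert d[i, j] == pytest.approx(expect)

    def test_low_overlap_flagged(self):
        rows = {"a": "AC" + "-" * 98, "b": "AC" + "-" * 98, "c": "A" * 100}
        sm = self._sm(rows)
        d, unreliable = ph.pairwise_distances(sm, min_shared=50)
        assert ("a", "b") in unreliable

    def test_zero_overlap_is_error(self):
        rows = {"a": "AC--", "b": "--AC", "c": "ACAC"}
        sm = self._sm(rows)
        with pytest.raises(ValueError, match="share no aligned"):
            ph.pairwise_distances(sm, min_shared=1)


def canon_split(side, taxa):
    """Encode a bipartition the way DistanceTree.splits does: the side
    not containing the alphabetically first taxon."""
    side = frozenset(side)
    return side if min(taxa) not in side else frozenset(set(taxa) - side)


def additive_matrix_5taxa(pairs, lengths):
    """Distance matrix of the unrooted 5-taxon tree with cherries
    ``pairs[0]`` and ``pairs[1]`` and a fifth leaf on the central node."""
    (a, b), (c, d), e = pairs
    x = lengths  # leaf branches a..e then internal m (to ab) and n (to cd)
    leaves = {a: x[0], b: x[1], c: x[2], d: x[3], e: x[4]}
    m, n = x[5], x[6]
    taxa = sorted(leaves)

    def dist(p, q):
        extra = 0.0
        for leaf, side in ((p, 0), (q, 0)):
            if leaf in (a, b):
                extra += m
            elif leaf in (c, d):
                extra += n
        if {p, q} == {a, b}:
            extra = 0.0
        elif {p, q} == {c, d}:
            extra = 0.0
        return leaves[p] + leaves[q] + extra

    D = np.zeros((5, 5))
    for i, p in enumerate(taxa):
        for j, q in enumerate(taxa):
            if i != j:
                D[i, j] = dist(p, q)
    return taxa, D


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = ph.nj_tree(D, ["a", "b", "c"])
        bl = {c.name: l for c, l in tree.root.children}
        assert bl["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert bl["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert bl["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_split_recovered(self):
        # tree ((a:1,b:2):1.5,(c:3,d:4)): split {a,b} | {c,d}
        D = np.array(
            [[0, 3, 5.5, 6.5], [3, 0, 6.5, 7.5], [5.5, 6.5, 0, 7], [6.5, 7.5, 7, 0]]
        )
        tree = ph.nj_tree(D, ["a", "b", "c", "d"])
        assert tree.splits() == {frozenset({"c", "d"})}
        assert np.allclose(tree.path_lengths(), D)

    def test_all_fifteen_5taxon_topologies_exact(self):
        """NJ reconstructs every labeled 5-taxon topology and its path
        lengths exactly from the additive matrix."""
        rng = np.random.default_rng(23)
        taxa5 = ["a", "b", "c", "d", "e"]
        seen = set()
        for pair1 in itertools.combinations(taxa5, 2):
            rest = [t for t in taxa5 if t not in pair1]
            for pair2 in itertools.combinations(rest, 2):
                e = [t for t in rest if t not in pair2][0]
                key = frozenset([frozenset(pair1), frozenset(pair2)])
                if key in seen:
                    continue
                seen.add(key)
                lengths = rng.uniform(0.5, 3.0, size=7)
                taxa, D = additive_matrix_5taxa((pair1, pair2, e), lengths)
                tree = ph.nj_tree(D, taxa)
                expected = {canon_split(pair1, taxa), canon_split(pair2, taxa)}
                assert tree.splits() == expected
                assert np.allclose(tree.path_lengths(), D, atol=1e-9)
        assert len(seen) == 15

    def test_agrees_with_dendropy_on_additive_matrix(self):
        """Independent cross-check: dendropy's NJ finds the same topology."""
        import dendropy

        rng = np.random.default_rng(4)
        taxa, D = additive_matrix_5taxa((("a", "b"), ("c", "d"), "e"),
                                        rng.uniform(0.5, 2.0, 7))
        mine = ph.nj_tree(D, taxa).splits()
        csv = "," + ",".join(taxa) + "\n" + "\n".join(
            t + "," + ",".join(str(D[i, j]) for j in range(5))
            for i, t in enumerate(taxa)
        )
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        dtree = pdm.nj_tree()
        theirs = set()
        all_taxa = set(taxa)
        anchor = min(taxa)
        for edge in dtree.preorder_edge_iter():
            leaves = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
            if 1 < len(leaves) < 4:
                side = leaves if anchor not in leaves else all_taxa - leaves
                theirs.add(frozenset(side))
        assert mine <= theirs

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ph.nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), list("abc"))
        with pytest.raises(ValueError, match="at least 3"):
            ph.nj_tree(np.zeros((2, 2)), list("ab"))


EIGHT_TAXON_TREE = (
    "root",
    [
        (("t1", []), 0.04),
        (
            ("i1", [
                (("t2", []), 0.05),
                (("i2", [(("t3", []), 0.06), (("t4", []), 0.04)]), 0.05),
            ]),
            0.06,
        ),
        (
            ("i3", [
                (("i4", [(("t5", []), 0.05), (("t6", []), 0.07)]), 0.06),
                (("i5", [(("t7", []), 0.04), (("t8", []), 0.05)]), 0.05),
            ]),
            0.07,
        ),
    ],
)
TRUE_SPLITS = {
    frozenset({"t3", "t4"}),
    frozenset({"t2", "t3", "t4"}),
    frozenset({"t5", "t6"}),
    frozenset({"t7", "t8"}),
    frozenset({"t5", "t6", "t7", "t8"}),
}


class TestBootstrapAndRecovery:
    def _supermatrix(self, seed, length=300):
        blocks = {
            m: syn.evolve_alignment(EIGHT_TAXON_TREE, length, seed=seed * 100 + i)
            for i, m in enumerate(ph.RIBOSOMAL_15[:5])
        }
        return ph.concatenate(blocks, ph.SET15, min_markers=1)

    def test_known_tree_recovered_across_seeds(self):
        """Markers simulated down a known 8-taxon tree recover its
        topology in >= 95% of seeds."""
        hits = 0
        for seed in range(20):
            sm = self._supermatrix(seed)
            d, _ = ph.pairwise_distances(sm, min_shared=1)
            tree = ph.nj_tree(d, sm.taxa)
            hits += tree.splits() == TRUE_SPLITS
        assert hits >= 19

    def test_clean_data_full_support(self):
        sm = self._supermatrix(7, length=500)
        tree, support = ph.bootstrap_support(sm, n_replicates=50, seed=2)
        assert tree.splits() == TRUE_SPLITS
        assert all(v >= 0.95 for v in support.values())

    def test_single_replicate_support_binary(self):
        sm = self._supermatrix(3, length=100)
        _, support = ph.bootstrap_support(sm, n_replicates=1, seed=5)
        assert set(support.values()) <= {0.0, 1.0}

    def test_deterministic_support(self):
        sm = self._supermatrix(4, length=150)
        _, s1 = ph.bootstrap_support(sm, n_replicates=20, seed=9)
        _, s2 = ph.bootstrap_support(sm, n_replicates=20, seed=9)
        assert s1 == s2

    def test_invalid_replicates(self):
        sm = self._supermatrix(1, length=50)
        with pytest.raises(ValueError, match="n_replicates"):
            ph.bootstrap_support(sm, n_replicates=0)
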