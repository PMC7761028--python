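"""Alignment, distances, neighbor joining and bootstrap, against oracles."""

import itertools

import numpy as np
import pytest

from wrkymine.phylogeny import (Alignment, DistanceMatrix, Node, Tree,
                                blosum62, bootstrap, nj,
                                pairwise_global_align, pdistance,
                                percent_identity, progressive_msa, upgma)
from wrkymine.seqio import SequenceRecord

from conftest import AA20, random_protein


def brute_force_align_score(a, b, sub, gap_open, gap_extend):
    """Enumerate every global alignment and score it with affine gaps."""
    best = float("-inf")
    n, m = len(a), len(b)

    def rec(i, j, score, last):
        nonlocal best
        if i == n and j == m:
            best = max(best, score)
            return
        if i < n and j < m:
            rec(i + 1, j + 1, score + sub[(a[i], b[j])], "D")
        if i < n:
            cost = gap_extend if last == "U" else gap_open
            rec(i + 1, j, score + cost, "U")
        if j < m:
            cost = gap_extend if last == "L" else gap_open
            rec(i, j + 1, score + cost, "L")

    rec(0, 0, 0.0, None)
    return best


class TestPairwiseAlign:
    def test_identity_score_is_diagonal_sum(self):
        sub = blosum62()
        a, b, score = pairwise_global_align("WRKYGQK", "WRKYGQK")
        assert a == b == "WRKYGQK"
        assert score == sum(sub[(c, c)] for c in "WRKYGQK")
        assert percent_identity(a, b) == 100.0

    def test_single_mismatch(self):
        a, b, _ = pairwise_global_align("WRKYGQK", "WRKYGKK")
        assert a == "WRKYGQK" and b == "WRKYGKK"
        assert percent_identity(a, b) == pytest.approx(100 * 6 / 7)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_global_align("", "ACD")

    @pytest.mark.parametrize("gap_open,gap_extend", [(-10.0, -1.0),
                                                     (-5.0, -2.0)])
    def test_matches_exhaustive_enumeration(self, rng, gap_open, gap_extend):
        """DP score equals brute-force enumeration over all alignments."""
        sub = blosum62()
        for _ in range(8):
            la, lb = rng.integers(2, 7, size=2)
            a = random_protein(rng, la)
            b = random_protein(rng, lb)
            _, _, got = pairwise_global_align(a, b, gap_open=gap_open,
                                              gap_extend=gap_extend)
            want = brute_force_align_score(a, b, sub, gap_open, gap_extend)
            assert got == pytest.approx(want)

    def test_traceback_produces_scoring_alignment(self, rng):
        """The returned alignment re-scores to the reported optimum."""
        sub = blosum62()
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(4, 30)))
            b = random_protein(rng, int(rng.integers(4, 30)))
            aa, bb, score = pairwise_global_align(a, b)
            assert aa.replace("-", "") == a and bb.replace("-", "") == b
            total, gap_a = 0.0, None
            last = None
            for x, y in zip(aa, bb):
                if x != "-" and y != "-":
                    total += sub[(x, y)]
                    last = "D"
                elif y == "-":
                    total += -1.0 if last == "U" else -10.0
                    last = "U"
                else:
                    total += -1.0 if last == "L" else -10.0
                    last = "L"
            assert total == pytest.approx(score)


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "MKLVWRKYGQK", "protein")
                for i in range(2)]
        aln = progressive_msa(recs)
        assert all("-" not in r.residues for r in aln.records)

    def test_internal_deletion_gets_gap(self):
        base = "MKKLVDEWRKYGQKEVKG"
        deleted = base[:8] + base[11:]
        recs = [SequenceRecord("a", base, "protein"),
                SequenceRecord("b", deleted, "protein"),
                SequenceRecord("c", base, "protein")]
        aln = progressive_msa(recs)
        rows = {r.id: r.residues for r in aln.records}
        assert aln.n_columns == len(base)
        assert rows["b"].count("-") == 3
        assert rows["a"] == rows["c"] == base

    def test_planted_conserved_block_aligned(self, rng):
        block = "WRKYGQKEVKGSE"
        recs = []
        for i in range(5):
            left = random_protein(rng, int(rng.integers(5, 25)))
            right = random_protein(rng, int(rng.integers(5, 25)))
            recs.append(SequenceRecord(f"s{i}", left + block + right,
                                       "protein"))
        aln = progressive_msa(recs)
        # the conserved block must appear intact (gap-free) in every row
        assert all(block in r.residues for r in aln.records)

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([SequenceRecord("a", "MKV", "protein")])


class TestPdistance:
    def test_identical_rows_zero(self):
        aln = Alignment([SequenceRecord("a", "MKV", "protein"),
                         SequenceRecord("b", "MKV", "protein")])
        assert pdistance(aln).values[0, 1] == 0.0

    def test_one_in_ten(self):
        aln = Alignment([SequenceRecord("a", "A" * 10, "protein"),
                         SequenceRecord("b", "A" * 9 + "C", "protein")])
        assert pdistance(aln).values[0, 1] == pytest.approx(0.1)

    def test_pairwise_deletion_oracle(self, rng):
        """Matches a direct column-count oracle on random gapped alignments."""
        for _ in range(10):
            n_col = int(rng.integers(10, 40))
            rows = []
            for i in range(4):
                chars = [("-" if rng.random() < 0.15 else
                          AA20[int(rng.integers(0, 4))]) for _ in range(n_col)]
                rows.append(SequenceRecord(f"s{i}", "".join(chars), "protein"))
            try:
                got = pdistance(Alignment(rows))
            except ValueError:
                continue  # a pair without comparable columns
            for i in range(4):
                for j in range(i + 1, 4):
                    a, b = rows[i].residues, rows[j].residues
                    cols = [(x, y) for x, y in zip(a, b)
                            if x != "-" and y != "-"]
                    want = sum(x != y for x, y in cols) / len(cols)
                    assert got.values[i, j] == pytest.approx(want)

    def test_no_comparable_columns_is_error(self):
        aln = Alignment([SequenceRecord("a", "AA--", "protein"),
                         SequenceRecord("b", "--CC", "protein")])
        with pytest.raises(ValueError, match="comparable"):
            pdistance(aln)


def random_additive_tree(rng, labels):
    """A random binary tree with positive branch lengths over `labels`."""
    nodes = [Node(lab, float(rng.uniform(0.5, 3.0))) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(None, float(rng.uniform(0.5, 3.0)),
                      children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Tree(Node(children=nodes))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(list("abc"),
                           np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        tree = nj(D)
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 2.0}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrix_recovered_exactly(self, rng, n_taxa):
        """NJ on an additive matrix returns the generating tree."""
        for _ in range(10):
            labels = [f"t{i}" for i in range(n_taxa)]
            true = random_additive_tree(rng, labels)
            D = true.path_length_matrix()
            got = nj(D)
            assert got.bipartitions() == true.bipartitions()
            np.testing.assert_allclose(got.path_length_matrix().values,
                                       D.values, atol=1e-9)

    def test_matches_skbio_oracle(self, rng):
        """Topology identical to an independent NJ implementation."""
        import skbio

        for _ in range(50):
            n = 5
            m = rng.uniform(0.1, 2.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"t{i}" for i in range(n)]
            ours = nj(DistanceMatrix(labels, m))
            sk = skbio.tree.nj(skbio.DistanceMatrix(m, labels))
            theirs = Tree.from_newick(str(sk).strip())
            assert ours.bipartitions() == theirs.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("abc"),
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_ultrametric_topology_matches_upgma(self, rng):
        """On an ultrametric matrix NJ and UPGMA agree on topology."""
        for _ in range(5):
            labels = [f"t{i}" for i in range(6)]
            # build ultrametric distances from a random clock tree
            t = random_additive_tree(rng, labels)
            # force clock: distance = depth-based (cophenetic of UPGMA on it)
            D = t.path_length_matrix()
            ut = upgma(D)
            U = ut.path_length_matrix()  # cophenetic matrix is ultrametric
            assert nj(U).bipartitions() == upgma(U).bipartitions()


class TestBootstrap:
    def _clade_alignment(self, rng, n_per_clade=4, length=120, n_mut=6):
        base1 = random_protein(rng, length)
        base2 = random_protein(rng, length)

        def mutate(s):
            s = list(s)
            for p in rng.choice(length, n_mut, replace=False):
                s[p] = AA20[int(rng.integers(0, 20))]
            return "".join(s)

        recs = [SequenceRecord(f"x{i}", mutate(base1), "protein")
                for i in range(n_per_clade)]
        recs += [SequenceRecord(f"y{i}", mutate(base2), "protein")
                 for i in range(n_per_clade)]
        return Alignment(recs)

    def test_identical_sequences_full_support(self):
        aln = Alignment([SequenceRecord(f"s{i}", "MKVLWRKY", "protein")
                         for i in range(5)])
        tree = bootstrap(aln, n=20, seed=3)
        supports = [n.support for n in tree.postorder()
                    if not n.is_leaf and n is not tree.root]
        assert supports and all(s == 100 for s in supports)

    def test_planted_clades_high_support(self, rng):
        aln = self._clade_alignment(rng)
        tree = bootstrap(aln, n=100, seed=7)
        sets = tree._leafsets()
        all_leaves = sets[id(tree.root)]
        clade_x = frozenset(l for l in all_leaves if l.startswith("x"))
        supported = {frozenset([sets[id(n)], all_leaves - sets[id(n)]]):
                     n.support for n in tree.postorder()
                     if not n.is_leaf and n is not tree.root}
        key = frozenset([clade_x, all_leaves - clade_x])
        assert key in supported and supported[key] >= 95

    def test_seed_reproducibility(self, rng):
        aln = self._clade_alignment(rng)
        t1 = bootstrap(aln, n=30, seed=11)
        t2 = bootstrap(aln, n=30, seed=11)
        assert t1.to_newick() == t2.to_newick()

    def test_leaf_relabeling_equivariance(self, rng):
        """Supports are invariant under a permutation of leaf labels.

        Distances are made generically distinct (disjoint mutation blocks of
        power-of-two sizes), since exact ties are resolved by label order.
        """
        base = random_protein(rng, 256)
        recs, pos = [], 0
        for i, size in enumerate([1, 2, 4, 8, 16, 32]):
            s = list(base)
            for p in range(pos, pos + size):
                s[p] = "W" if base[p] != "W" else "Y"
            pos += size
            recs.append(SequenceRecord(f"s{i}", "".join(s), "protein"))
        aln = Alignment(recs)
        mapping = {r.id: f"z{i}" for i, r in enumerate(reversed(aln.records))}
        relabeled = Alignment([SequenceRecord(mapping[r.id], r.residues,
                                              "protein")
                               for r in aln.records])
        t1 = bootstrap(aln, n=50, seed=13)
        t2 = bootstrap(relabeled, n=50, seed=13)

        def support_map(tree):
            sets = tree._leafsets()
            all_leaves = sets[id(tree.root)]
            out = {}
            for node in tree.postorder():
                if not node.is_leaf and node is not tree.root:
                    side = sets[id(node)]
                    out[frozenset([side, all_leaves - side])] = node.support
            return out

        m1 = {frozenset(frozenset(mapping[l] for l in side) for side in k): v
              for k, v in support_map(t1).items()}
        assert m1 == support_map(t2)

    def test_invalid_replicate_count(self, rng):
        aln = self._clade_alignment(rng, n_per_clade=2)
        with pytest.raises(ValueError):
            bootstrap(aln, n=0, seed=1)
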