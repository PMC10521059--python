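import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode

from amoebascan.seq_compare import (divergence_matrix, donor_nesting_check,
                                    global_align, nj_tree, ssu_report)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


def brute_force_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Enumerate every global alignment recursively, tracking the score."""
    best = [-float("inf")]

    def rec(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences(self):
        r = global_align("ACGT", "ACGT")
        assert r.score == 4 and r.identity == 1.0 and r.divergence == 0.0

    def test_single_mismatch(self):
        r = global_align("ACGT", "AGGT")
        assert r.score == 2 and r.identity == 0.75 and r.divergence == 0.25

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_gap_columns_recover_inputs(self):
        r = global_align("ACGTACGT", "ACGT")
        assert r.aligned_a.replace("-", "") == "ACGTACGT"
        assert r.aligned_b.replace("-", "") == "ACGT"
        assert len(r.aligned_a) == len(r.aligned_b)
        assert not any(x == y == "-" for x, y in zip(r.aligned_a, r.aligned_b))

    def test_score_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"),
                                   size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(list("ACGT"),
                                   size=int(rng.integers(1, 7))))
            assert global_align(a, b).score == brute_force_score(a, b)

    def test_score_matches_biopython_aligner(self):
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1, -1
        aligner.open_gap_score = aligner.extend_gap_score = -2
        rng = np.random.default_rng(12)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 40))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 40))))
            assert global_align(a, b).score == aligner.score(a, b)

    def test_unit_cost_score_matches_edlib_edit_distance(self):
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(13)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 50))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 50))))
            r = global_align(a, b, match=0.0, mismatch=-1.0, gap=-1.0)
            assert -r.score == edlib.align(a, b, task="distance",
                                           mode="NW")["editDistance"]

    @settings(derandomize=True, max_examples=60)
    @given(DNA, DNA)
    def test_score_symmetric_and_self_identity(self, a, b):
        assert global_align(a, b).score == global_align(b, a).score
        assert global_align(a, a).identity == 1.0

    @settings(derandomize=True, max_examples=40)
    @given(DNA, DNA, st.randoms(use_true_random=False))
    def test_dp_dominates_fuzzed_alignments(self, a, b, rnd):
        # build a random valid alignment and score it with the same scheme
        ai = bi = 0
        cols = []
        while ai < len(a) or bi < len(b):
            moves = []
            if ai < len(a) and bi < len(b):
                moves.append("d")
            if ai < len(a):
                moves.append("u")
            if bi < len(b):
                moves.append("l")
            m = rnd.choice(moves)
            if m == "d":
                cols.append((a[ai], b[bi])); ai += 1; bi += 1
            elif m == "u":
                cols.append((a[ai], "-")); ai += 1
            else:
                cols.append(("-", b[bi])); bi += 1
        score = sum(-2.0 if "-" in (x, y) else (1.0 if x == y else -1.0)
                    for x, y in cols)
        assert global_align(a, b).score >= score

    def test_affine_gaps_via_gap_open(self):
        r = global_align("ACGTACGTAC", "ACAC", gap_open=-5.0, gap=-1.0)
        assert r.aligned_a.replace("-", "") == "ACGTACGTAC"
        assert r.aligned_b.replace("-", "") == "ACAC"


class TestSsuReport:
    def test_identical_copies_pass(self):
        rep = ssu_report({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert rep.max_divergence == 0.0 and rep.passes

    def test_planted_divergent_copy_fails(self):
        base = "ACGT" * 25  # 100 bp
        mutated = list(base)
        for i in range(0, 40, 4):  # 10 substitutions = 10% divergence
            mutated[i] = "G" if base[i] != "G" else "T"
        rep = ssu_report({"a": base, "b": "".join(mutated)})
        assert rep.max_divergence == pytest.approx(0.10)
        assert not rep.passes

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError):
            ssu_report({"a": "ACGT"})

    def test_generator_copies_within_bound(self, default_bundle):
        rep = ssu_report(default_bundle.ssu)
        assert rep.n_copies == 22
        assert rep.passes and rep.max_divergence < 0.03
        assert rep.mean_divergence <= rep.max_divergence

    def test_divergence_matrix_symmetric_zero_diagonal(self):
        dm = divergence_matrix({"a": "ACGTAC", "b": "ACTTAC", "c": "ACGTTT"})
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)


def _additive_matrix(rng, n):
    """Random binary tree over n labels -> (split set, additive distances)."""
    labels = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=label) for label in labels]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
        parent.length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    dm = DistanceMatrix(root.tip_tip_distances(endpoints=labels).data,
                        ids=labels)
    return tree_splits(root), dm


def tree_splits(tree):
    """Non-trivial bipartitions of an unrooted tree as frozensets of pairs."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


class TestNjTree:
    def test_four_taxon_additive_recovery(self):
        # ((A,B),(C,D)) with internal branch 2
        dm = DistanceMatrix(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            ids=list("ABCD"))
        tree = nj_tree(dm)
        assert frozenset({frozenset("AB"), frozenset("CD")}) in \
            tree_splits(tree)

    def test_three_taxa_star(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 3], [3, 3, 0]], ids=list("ABC"))
        tree = nj_tree(dm)
        assert {t.name for t in tree.tips()} == set("ABC")
        assert tree_splits(tree) == set()

    def test_ultrametric_five_taxon_recovery(self):
        rng = np.random.default_rng(21)
        true_splits, dm = _additive_matrix(rng, 5)
        assert tree_splits(nj_tree(dm)) == true_splits

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))

    def test_asymmetric_matrix_rejected(self):
        from skbio.stats.distance import DissimilarityMatrixError
        with pytest.raises((DissimilarityMatrixError, ValueError)):
            DistanceMatrix([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                           ids=list("ABC"))

    def test_negative_branch_lengths_clamped(self):
        dm = DistanceMatrix([[0, 1, 1, 1], [1, 0, 1, 1],
                             [1, 1, 0, 1], [1, 1, 1, 0]], ids=list("ABCD"))
        tree = nj_tree(dm)
        assert all((node.length or 0) >= 0 for node in tree.traverse())


class TestDonorNesting:
    def _tree(self, seqs):
        return nj_tree(divergence_matrix(seqs))

    def test_candidate_identical_to_donor_nests_in_donor(self):
        seqs = {
            "cand": "AAAATTTTCCCCGGGG",
            "don1": "AAAATTTTCCCCGGGG",
            "don2": "AAAATTTTCCCCGGGT",
            "rec1": "TTTTAAAAGGGGCCCC",
            "rec2": "TTTTAAAAGGGGCCCA",
        }
        verdict = donor_nesting_check(self._tree(seqs), "cand",
                                      {"don1", "don2"}, {"rec1", "rec2"})
        assert verdict == "nested_in_donor"

    def test_recipient_like_candidate(self):
        rng = np.random.default_rng(34)
        rec_anc = "".join(rng.choice(list("ACGT"), size=120))
        don_anc = "".join(rng.choice(list("ACGT"), size=120))
        rec1 = _mutate(rng, rec_anc, 3)
        seqs = {"cand": _mutate(rng, rec1, 1), "rec1": rec1,
                "rec2": _mutate(rng, rec_anc, 4),
                "don1": _mutate(rng, don_anc, 3),
                "don2": _mutate(rng, don_anc, 4)}
        verdict = donor_nesting_check(self._tree(seqs), "cand",
                                      {"don1", "don2"}, {"rec1", "rec2"})
        assert verdict == "nested_in_recipient"

    def test_equidistant_candidate_unresolved(self):
        n = 5
        dm = DistanceMatrix(np.ones((n, n)) - np.eye(n),
                            ids=["cand", "don1", "don2", "rec1", "rec2"])
        verdict = donor_nesting_check(nj_tree(dm), "cand",
                                      {"don1", "don2"}, {"rec1", "rec2"})
        assert verdict == "unresolved"

    def test_missing_labels_rejected(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4),
                            ids=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            donor_nesting_check(nj_tree(dm), "zz", {"a", "b"}, {"c", "d"})

    def test_planted_lgt_gene_nests_with_donor_references(self):
        # the transferred gene is a recent derivative of one donor lineage
        rng = np.random.default_rng(33)
        donor_anc = "".join(rng.choice(list("ACGT"), size=120))
        rec_anc = "".join(rng.choice(list("ACGT"), size=120))
        don1 = _mutate(rng, donor_anc, 3)
        seqs = {"cand": _mutate(rng, don1, 1), "don1": don1,
                "don2": _mutate(rng, donor_anc, 4),
                "rec1": _mutate(rng, rec_anc, 3),
                "rec2": _mutate(rng, rec_anc, 4)}
        verdict = donor_nesting_check(self._tree(seqs), "cand",
                                      {"don1", "don2"}, {"rec1", "rec2"})
        assert verdict == "nested_in_donor"


def _mutate(rng, seq, k):
    s = list(seq)
    for p in rng.choice(len(s), size=k, replace=False):
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)
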