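"""Pairwise alignment, divergence matrices and neighbor-joining trees.

Divergence between SSU-rDNA copies is a p-distance on a global
(Needleman-Wunsch) alignment: 1 - matches / aligned columns, with
terminal gap columns excluded and internal gap columns counted as
differences (both policies configurable).  Neighbor joining over a
divergence matrix serves as a deterministic, distance-based stand-in
for likelihood-based phylogenetic corroboration of LGT candidates; the
report carries an explicit disclaimer to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

NJ_DISCLAIMER = ("neighbor-joining corroboration; distance-based stand-in, "
                 "not a maximum-likelihood analysis")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap: float = -2.0, gap_open: float | None = None,
                 count_terminal_gaps: bool = False,
                 internal_gaps_differ: bool = True) -> AlignmentResult:
    """Optimal global alignment under a linear gap penalty.

    Needleman-Wunsch with deterministic traceback tie-breaking
    (diagonal > up > left).  Identity is matches over aligned columns
    under the configured gap-column policy.  Passing ``gap_open``
    switches to affine gaps (open + extend), delegated to Biopython's
    ``PairwiseAligner``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if gap_open is not None:
        aa, bb, score = _affine_align(a, b, match, mismatch, gap_open, gap)
    else:
        aa, bb, score = _nw_align(a, b, match, mismatch, gap)
    identity = _column_identity(aa, bb, count_terminal_gaps,
                                internal_gaps_differ)
    return AlignmentResult(aa, bb, score, identity)


def _nw_align(a: str, b: str, match: float, mismatch: float, gap: float
              ) -> tuple[str, str, float]:
    n, m = len(a), len(b)
    F = np.empty((n + 1, m + 1))
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    sub = np.where(
        np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(b.encode(), dtype=np.uint8)[None, :],
        match, mismatch)
    # Row-vectorized recurrence: with cand[j] = max(diag, up) for j >= 1,
    # row[j] = max_{k<=j} t[k] + gap*(j-k) where t = [row[0], cand...];
    # the left-gap chain collapses to a running maximum of t[k] - gap*k.
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        row_prev = F[i - 1]
        cand = np.maximum(row_prev[:-1] + sub[i - 1], row_prev[1:] + gap)
        t = np.concatenate(([F[i, 0]], cand))
        F[i] = np.maximum.accumulate(t - gap * j_idx) + gap * j_idx
    # traceback, preferring diagonal > up > left on ties
    aa: list[str] = []
    bb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            aa.append(a[i - 1]); bb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            aa.append(a[i - 1]); bb.append("-"); i -= 1
        else:
            aa.append("-"); bb.append(b[j - 1]); j -= 1
    return "".join(reversed(aa)), "".join(reversed(bb)), float(F[n, m])


def _affine_align(a: str, b: str, match: float, mismatch: float,
                  gap_open: float, gap_extend: float
                  ) -> tuple[str, str, float]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = next(iter(aligner.align(a, b)))
    return str(aln[0]), str(aln[1]), float(aln.score)


def _column_identity(aa: str, bb: str, count_terminal_gaps: bool,
                     internal_gaps_differ: bool) -> float:
    cols = list(zip(aa, bb))
    lo, hi = 0, len(cols)
    if not count_terminal_gaps:
        while lo < hi and "-" in cols[lo]:
            lo += 1
        while hi > lo and "-" in cols[hi - 1]:
            hi -= 1
    matches = counted = 0
    for x, y in cols[lo:hi]:
        if "-" in (x, y):
            if internal_gaps_differ:
                counted += 1
            continue
        counted += 1
        matches += x == y
    return matches / counted if counted else 1.0


# ---------------------------------------------------------------------------
# divergence matrices and SSU report

def divergence_matrix(seqs: Mapping[str, str], **align_kwargs
                      ) -> DistanceMatrix:
    """All-pairs alignment divergences as a symmetric DistanceMatrix."""
    labels = list(seqs)
    n = len(labels)
    mat = np.zeros((n, n))
    for (i, la), (j, lb) in combinations(enumerate(labels), 2):
        d = global_align(seqs[la], seqs[lb], **align_kwargs).divergence
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


@dataclass(frozen=True)
class SsuReport:
    n_copies: int
    max_divergence: float
    mean_divergence: float
    passes: bool
    matrix: DistanceMatrix


def ssu_report(copies: Mapping[str, str], max_divergence: float = 0.03
               ) -> SsuReport:
    """Intragenomic SSU-rDNA variation report over provided copies.

    ``passes`` is true when the maximum pairwise divergence stays below
    ``max_divergence`` (default 3%, the conventional species-level
    bound), i.e. the copies are consistent with one genome rather than
    contamination.
    """
    if len(copies) < 2:
        raise ValueError("need at least two SSU copies")
    dm = divergence_matrix(copies)
    off = dm.data[np.triu_indices(dm.shape[0], k=1)]
    return SsuReport(
        n_copies=len(copies),
        max_divergence=float(off.max()),
        mean_divergence=float(off.mean()),
        passes=bool(off.max() < max_divergence),
        matrix=dm,
    )


# ---------------------------------------------------------------------------
# neighbor joining and nesting checks

def nj_tree(dm: DistanceMatrix, allow_negative: bool = False) -> TreeNode:
    """Neighbor-joining tree from a divergence matrix.

    Branch lengths are clamped at zero unless ``allow_negative``; input
    must be a valid symmetric matrix with >= 3 labels (DistanceMatrix
    construction enforces symmetry and a zero diagonal).
    """
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 labels for a tree")
    tree = _skbio_nj(dm)
    if not allow_negative:
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return tree


def _collapse_short_branches(tree: TreeNode, eps: float = 1e-9) -> TreeNode:
    """Copy of ``tree`` with internal branches of length <= eps collapsed
    into polytomies, so unsupported resolutions do not count as clades."""
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse(include_self=False)):
            if node.is_tip() or node.parent is None:
                continue
            if (node.length or 0.0) <= eps:
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True
    return tree


def donor_nesting_check(tree: TreeNode, candidate: str,
                        donor_labels: set[str], recipient_labels: set[str]
                        ) -> str:
    """Classify where an LGT candidate nests in a corroboration tree.

    Internal branches of zero length are first collapsed (a tie in the
    agglomeration is no evidence of grouping).  Over all bipartition
    sides (edges of the unrooted tree) containing the candidate plus at
    least one other leaf, the smallest side is examined: all-donor
    companions -> ``nested_in_donor``, all-recipient ->
    ``nested_in_recipient``, anything else (including ties between
    minimal sides that disagree) -> ``unresolved``.
    """
    tree = _collapse_short_branches(tree)
    leaves = {t.name for t in tree.tips()}
    missing = ({candidate} | donor_labels | recipient_labels) - leaves
    if missing:
        raise ValueError(f"labels missing from tree: {sorted(missing)}")
    if len(donor_labels) < 2 or len(recipient_labels) < 2:
        raise ValueError("need >= 2 donor and >= 2 recipient labels")

    sides: list[frozenset[str]] = []
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips(include_self=True))
        for side in (clade, frozenset(leaves) - clade):
            if candidate in side and len(side) >= 2:
                sides.append(side)
    if not sides:
        return "unresolved"
    smallest = min(len(s) for s in sides)
    verdicts = set()
    for side in {s for s in sides if len(s) == smallest}:
        others = side - {candidate}
        if others <= donor_labels:
            verdicts.add("nested_in_donor")
        elif others <= recipient_labels:
            verdicts.add("nested_in_recipient")
        else:
            verdicts.add("unresolved")
    return verdicts.pop() if len(verdicts) == 1 else "unresolved"
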