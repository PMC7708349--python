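"""Progressive profile-profile alignment over integer-coded alphabets.

Shared by the motif-level and DNA-level aligners.  Sequences are coded as
int16 arrays (gap = -1).  Profiles carry per-column symbol counts; two
profiles are merged with the affine-gap kernel using average-of-pairs
column scores under an identity substitution model.  Columns may carry
anchor-group marks; marked column pairs sharing a group receive a large
bonus, which forces anchored symbols into a common column at the merge
where their profiles meet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._dp import affine_align_ops, pair_score_matrix
from .errors import DomainError

GAP = -1
ANCHOR_BONUS = 1.0e7


@dataclass(frozen=True)
class Scoring:
    """Identity scoring: match > mismatch; gap_open <= gap_extend <= 0.

    A gap run of length k costs ``gap_open + k * gap_extend``.
    """

    match: float
    mismatch: float
    gap_open: float
    gap_extend: float

    def __post_init__(self):
        if not self.match > self.mismatch:
            raise DomainError("match score must exceed mismatch score")
        if not self.gap_open <= self.gap_extend <= 0:
            raise DomainError("require gap_open <= gap_extend <= 0")


def pairwise_codes(a: np.ndarray, b: np.ndarray, scoring: Scoring):
    """Optimal global affine alignment of two coded sequences.

    Returns (score, ops); see :func:`kirmotif._dp.affine_align_ops`.
    """
    S = pair_score_matrix(a, b, scoring.match, scoring.mismatch)
    return affine_align_ops(S, scoring.gap_open, scoring.gap_extend)


def ops_to_rows(a: np.ndarray, b: np.ndarray, ops: np.ndarray):
    """Expand two coded sequences into gapped rows according to ops."""
    ra = np.full(len(ops), GAP, dtype=np.int16)
    rb = np.full(len(ops), GAP, dtype=np.int16)
    i = j = 0
    for k, op in enumerate(ops):
        if op == 0:
            ra[k] = a[i]
            rb[k] = b[j]
            i += 1
            j += 1
        elif op == 1:
            ra[k] = a[i]
            i += 1
        else:
            rb[k] = b[j]
            j += 1
    return ra, rb


class Profile:
    """A block of aligned rows plus per-column anchor marks."""

    def __init__(self, rows: np.ndarray, ids: list[int],
                 marks: list[frozenset] | None = None):
        self.rows = rows  # (nrows, ncols) int16, GAP = -1
        self.ids = ids  # indices into the original input list
        ncols = rows.shape[1]
        self.marks = marks if marks is not None else [frozenset()] * ncols

    @classmethod
    def leaf(cls, codes: np.ndarray, idx: int,
             anchor_marks: dict[int, frozenset] | None = None) -> "Profile":
        rows = codes.reshape(1, -1).astype(np.int16)
        marks = [frozenset()] * rows.shape[1]
        if anchor_marks:
            for col, groups in anchor_marks.items():
                marks[col] = groups
        return cls(rows, [idx], marks)

    def counts(self, nsym: int) -> tuple[np.ndarray, np.ndarray]:
        ncols = self.rows.shape[1]
        C = np.zeros((ncols, nsym), dtype=np.float64)
        for r in self.rows:
            ok = r >= 0
            np.add.at(C, (np.nonzero(ok)[0], r[ok]), 1.0)
        return C, C.sum(axis=1)


def merge_profiles(p1: Profile, p2: Profile, scoring: Scoring, nsym: int) -> Profile:
    C1, nz1 = p1.counts(nsym)
    C2, nz2 = p2.counts(nsym)
    same = C1 @ C2.T
    tot = np.outer(nz1, nz2)
    denom = p1.rows.shape[0] * p2.rows.shape[0]
    S = (scoring.match * same + scoring.mismatch * (tot - same)) / denom
    if any(p1.marks) and any(p2.marks):
        for i, m1 in enumerate(p1.marks):
            if not m1:
                continue
            for j, m2 in enumerate(p2.marks):
                if m1 & m2:
                    S[i, j] += ANCHOR_BONUS * len(m1 & m2)
    _, ops = affine_align_ops(S, scoring.gap_open, scoring.gap_extend)
    ncols = len(ops)
    n1, n2 = p1.rows.shape[0], p2.rows.shape[0]
    rows = np.full((n1 + n2, ncols), GAP, dtype=np.int16)
    marks = [frozenset()] * ncols
    i = j = 0
    for k, op in enumerate(ops):
        if op == 0:
            rows[:n1, k] = p1.rows[:, i]
            rows[n1:, k] = p2.rows[:, j]
            marks[k] = p1.marks[i] | p2.marks[j]
            i += 1
            j += 1
        elif op == 1:
            rows[:n1, k] = p1.rows[:, i]
            marks[k] = p1.marks[i]
            i += 1
        else:
            rows[n1:, k] = p2.rows[:, j]
            marks[k] = p2.marks[j]
            j += 1
    return Profile(rows, p1.ids + p2.ids, marks)


def pairwise_distance_matrix(coded: list[np.ndarray], scoring: Scoring) -> np.ndarray:
    """Normalized alignment distance: 1 - identical columns / alignment length."""
    n = len(coded)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ops = pairwise_codes(coded[i], coded[j], scoring)
            ra, rb = ops_to_rows(coded[i], coded[j], ops)
            ident = np.sum((ra == rb) & (ra >= 0))
            D[i, j] = D[j, i] = 1.0 - ident / max(1, len(ops))
    return D


def progressive_align(coded: list[np.ndarray], scoring: Scoring, nsym: int,
                      anchor_marks: dict[int, dict[int, frozenset]] | None = None
                      ) -> np.ndarray:
    """UPGMA-guided progressive alignment; returns (n, ncols) gapped rows in
    input order.  ``anchor_marks`` maps input index -> {column -> group set}.
    """
    n = len(coded)
    if n == 1:
        return coded[0].reshape(1, -1).astype(np.int16)
    leaves = [Profile.leaf(coded[i], i, (anchor_marks or {}).get(i))
              for i in range(n)]
    if n == 2:
        final = merge_profiles(leaves[0], leaves[1], scoring, nsym)
    else:
        D = pairwise_distance_matrix(coded, scoring)
        Z = linkage(squareform(D, checks=False), method="average")
        clusters: dict[int, Profile] = {i: leaves[i] for i in range(n)}
        nxt = n
        for a, b, _, _ in Z:
            pa, pb = clusters.pop(int(a)), clusters.pop(int(b))
            # deterministic orientation: lower smallest-input-index first
            if min(pa.ids) > min(pb.ids):
                pa, pb = pb, pa
            clusters[nxt] = merge_profiles(pa, pb, scoring, nsym)
            nxt += 1
        final = clusters[nxt - 1]
    order = np.argsort(final.ids)
    return final.rows[order]
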