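"""Multiple sequence alignment over the motif alphabet, and the motif tree.

Standard DNA/protein aligners cannot consume the probe-pair alphabet, so
this module provides a progressive aligner that is generic over any finite
symbol set: optimal affine-gap pairwise alignment, a UPGMA guide tree built
from normalized pairwise alignment distances, and average-of-pairs
profile-profile merges.  Explicit anchor constraints — groups of (row,
symbol index) that must share an alignment column — are the replayable
substitute for interactive manual curation of ambiguous regions.

The module also derives a column-difference distance matrix from a motif
MSA and builds a neighbor-joining tree from it (Newick output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._profile import Scoring, ops_to_rows, pairwise_codes, progressive_align
from .errors import AnchorError, DomainError
from .motif_encode import MotifString

GAP_CHAR = "-"


@dataclass(frozen=True)
class SymbolScoring(Scoring):
    """Scoring for the motif alphabet.

    The alphabet has no substitution structure, so an identity model is
    used.  Defaults make a single-symbol indel (gene presence/absence)
    cheaper than a mismatch between unrelated motifs.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class AnchorConstraint:
    """One group of (seq_id, symbol_index) pairs forced into one column."""

    members: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class MotifMSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise DomainError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP_CHAR, "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    def to_text(self) -> str:
        w = max((len(i) for i in self.ids), default=0)
        return "\n".join(f"{rid:<{w}}  {row}" for rid, row in zip(self.ids, self.rows))


def _codebook(strings: Sequence[str]) -> dict[str, int]:
    symbols = sorted({c for s in strings for c in s})
    return {c: i for i, c in enumerate(symbols)}

def _code(s: str, book: dict[str, int]) -> np.ndarray:
    return np.array([book[c] for c in s], dtype=np.int16)


def pairwise_align(a: str, b: str, scoring: SymbolScoring | None = None
                   ) -> tuple[tuple[str, str], float]:
    """Optimal global affine-gap alignment of two motif strings.

    Returns ((gapped_a, gapped_b), score).  Ties are broken deterministically
    (diagonal, then up, then left).
    """
    scoring = scoring or SymbolScoring()
    for s in (a, b):
        if GAP_CHAR in s:
            raise DomainError("input motif strings must not contain '-'")
    book = _codebook([a, b])
    inv = {v: k for k, v in book.items()}
    ca, cb = _code(a, book), _code(b, book)
    score, ops = pairwise_codes(ca, cb, scoring)
    ra, rb = ops_to_rows(ca, cb, ops)
    to_s = lambda r: "".join(GAP_CHAR if v < 0 else inv[v] for v in r)
    return (to_s(ra), to_s(rb)), float(score)


def _validate_anchors(motifs: Sequence[MotifString],
                      anchors: Sequence[AnchorConstraint]) -> None:
    lengths = {m.seq_id: len(m.symbols) for m in motifs}
    per_row: dict[str, list[int]] = {}
    for g, grp in enumerate(anchors):
        if len(grp.members) < 2:
            raise AnchorError(f"anchor group {g} needs at least two members")
        for sid, idx in grp.members:
            if sid not in lengths:
                raise AnchorError(f"anchor group {g} names unknown sequence {sid!r}")
            if not 0 <= idx < lengths[sid]:
                raise AnchorError(
                    f"anchor group {g}: index {idx} out of range for {sid}")
            per_row.setdefault(sid, []).append(idx)
    for sid, idxs in per_row.items():
        if any(b <= a for a, b in zip(idxs, idxs[1:])):
            raise AnchorError(
                f"anchored indices for {sid} must be strictly increasing "
                "across successive groups")


def progressive_msa(motifs: Sequence[MotifString],
                    scoring: SymbolScoring | None = None,
                    anchors: Sequence[AnchorConstraint] | None = None) -> MotifMSA:
    """Progressive MSA of motif strings (UPGMA guide, affine gaps).

    Every row degaps back to its input string; anchored symbol groups end in
    shared columns (verified, :class:`AnchorError` on violation).
    """
    scoring = scoring or SymbolScoring()
    motifs = list(motifs)
    if len(motifs) < 2:
        raise DomainError("progressive_msa needs at least 2 motif strings")
    ids = [m.seq_id for m in motifs]
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate seq ids")
    if anchors:
        _validate_anchors(motifs, anchors)
    book = _codebook([m.symbols for m in motifs])
    inv = {v: k for k, v in book.items()}
    coded = [_code(m.symbols, book) for m in motifs]
    marks: dict[int, dict[int, frozenset]] = {}
    if anchors:
        for g, grp in enumerate(anchors):
            for sid, idx in grp.members:
                i = ids.index(sid)
                col = marks.setdefault(i, {})
                col[idx] = col.get(idx, frozenset()) | {g}
    rows = progressive_align(coded, scoring, nsym=len(book),
                             anchor_marks=marks or None)
    out = MotifMSA(ids=ids, rows=["".join(GAP_CHAR if v < 0 else inv[v] for v in r)
                                  for r in rows])
    for i, m in enumerate(motifs):
        if out.degapped(i) != m.symbols:
            raise AnchorError(f"row {m.seq_id} does not round-trip")  # pragma: no cover
    if anchors:
        _verify_anchor_columns(out, anchors)
    return out


def _verify_anchor_columns(msa: MotifMSA, anchors: Sequence[AnchorConstraint]) -> None:
    colmap = []
    for row in msa.rows:
        cols, k = {}, 0
        for c, ch in enumerate(row):
            if ch != GAP_CHAR:
                cols[k] = c
                k += 1
        colmap.append(cols)
    for g, grp in enumerate(anchors):
        cols = {colmap[msa.ids.index(sid)][idx] for sid, idx in grp.members}
        if len(cols) != 1:
            raise AnchorError(f"anchor group {g} was not resolved into one column")


def motif_distance_matrix(msa: MotifMSA) -> tuple[list[str], np.ndarray]:
    """Column-difference distances: gap-vs-gap columns are skipped, symbol-
    vs-gap counts as a difference.  Pairs with no co-scorable columns get
    distance 1."""
    n = len(msa.rows)
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == GAP_CHAR
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scorable = ~(gap[i] & gap[j])
            m = int(scorable.sum())
            if m == 0:
                D[i, j] = D[j, i] = 1.0
                continue
            diff = int(np.sum(arr[i][scorable] != arr[j][scorable]))
            D[i, j] = D[j, i] = diff / m
    return list(msa.ids), D


def neighbor_joining(D: np.ndarray, ids: Sequence[str]) -> str:
    """Neighbor joining with deterministic tie-breaking; returns Newick.

    Joins are chosen by minimal Q, ties resolved by the lexicographically
    smallest sorted label pair.  Negative branch lengths are clamped to 0
    with the deficit moved to the sister branch.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DomainError("distance matrix must be square")
    if n != len(ids):
        raise DomainError("ids do not match matrix size")
    if n < 2:
        raise DomainError("need at least 2 taxa")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0):
        raise DomainError("distance matrix must be symmetric with zero diagonal")

    labels = [str(x) for x in ids]
    newick = list(labels)
    D = D.copy()
    active = list(range(n))

    def _fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(active) > 2:
        m = len(active)
        r = np.array([sum(D[i, k] for k in active if k != i) for i in active])
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[ai] - r[aj]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        node = f"({newick[i]}:{_fmt(li)},{newick[j]}:{_fmt(lj)})"
        newdist = {k: 0.5 * (D[i, k] + D[j, k] - dij) for k in active if k not in (i, j)}
        # reuse slot i for the new node
        for k, v in newdist.items():
            D[i, k] = D[k, i] = max(v, 0.0)
        newick[i] = node
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j = active
    d = D[i, j]
    return f"({newick[i]}:{_fmt(d / 2)},{newick[j]}:{_fmt(d / 2)});"


def write_phylip(path, ids: Sequence[str], D: np.ndarray) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for rid, row in zip(ids, D):
            name = str(rid)[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_anchors_tsv(path) -> list[AnchorConstraint]:
    """Headered TSV ``group_id, seq_id, symbol_index`` (0-based)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    groups: dict = {}
    for r in df.itertuples():
        groups.setdefault(r.group_id, AnchorConstraint()).members.append(
            (str(r.seq_id), int(r.symbol_index)))
    return [groups[k] for k in sorted(groups)]
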