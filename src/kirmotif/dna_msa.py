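"""Per-locus DNA alignment and conforming concatenation.

Following the motif-level annotation, the DNA of each motif-defined locus is
extracted from every haplotype carrying it, each locus set is aligned
separately (progressive, UPGMA guide, affine gaps), and the per-locus blocks
are laid left-to-right in canonical locus order into one full-haplotype
alignment.  Haplotypes lacking a locus get all-gap rows across that block,
so the gap-block pattern of the final alignment mirrors locus
presence/absence.  An aligned block produced by an external aligner can be
dropped in for any locus as long as it degaps to the same member sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._profile import Scoring, progressive_align
from .errors import DomainError, IntegrityError
from .locus_model import Segmentation, tiled_intervals

_DNA = "ACGTN"
_DNA_CODE = {c: i for i, c in enumerate(_DNA)}
GAP_CHAR = "-"


@dataclass(frozen=True)
class DnaScoring(Scoring):
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass
class LocusSequenceSet:
    locus_label: str
    rank: int
    members: list[tuple[str, str]]  # (seq_id, DNA substring)


@dataclass
class BlockMSA:
    locus_label: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise DomainError("block rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class FullHaplotypeMSA:
    ids: list[str]
    rows: list[str]
    boundaries: list[tuple[str, int, int]]  # locus_label, col_start, col_end

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP_CHAR, "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    def write_boundaries_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus_label\tcol_start\tcol_end\n")
            for label, a, b in self.boundaries:
                fh.write(f"{label}\t{a}\t{b}\n")


def extract_locus_sets(haplotypes: Mapping[str, str],
                       annotations: Mapping[str, Segmentation]
                       ) -> list[LocusSequenceSet]:
    """One sequence set per locus present in any haplotype, rank order.

    Locus DNA intervals tile each haplotype (shared anchors close the left
    locus; unmatched residues are absorbed leftwards), so concatenating a
    haplotype's extracted substrings in order reproduces it exactly.
    """
    sets: dict[str, LocusSequenceSet] = {}
    ranks: dict[str, int] = {}
    for sid, seq in haplotypes.items():
        seg = annotations[sid]
        for s in seg.segments:
            ranks.setdefault(s.locus_label, s.rank)
        for label, start, end in tiled_intervals(seg, len(seq)):
            if not 0 <= start <= end <= len(seq):
                raise IntegrityError(
                    f"interval {start}-{end} out of bounds for {sid}/{label}")
            sub = seq[start:end]
            if not sub:
                continue
            sets.setdefault(label, LocusSequenceSet(label, ranks[label], [])
                            ).members.append((sid, sub))
    return sorted(sets.values(), key=lambda s: s.rank)


def align_locus(lset: LocusSequenceSet, scoring: DnaScoring | None = None,
                prealigned: Sequence[str] | None = None) -> BlockMSA:
    """Align one locus set (progressive) or adopt an externally aligned block.

    ``prealigned`` rows must be in member order and degap to the member
    sequences exactly.
    """
    scoring = scoring or DnaScoring()
    if not lset.members:
        raise DomainError(f"locus {lset.locus_label} has no members")
    ids = [sid for sid, _ in lset.members]
    if prealigned is not None:
        block = BlockMSA(lset.locus_label, ids, [r.upper() for r in prealigned])
        for (sid, seq), row in zip(lset.members, block.rows):
            if row.replace(GAP_CHAR, "") != seq.upper():
                raise IntegrityError(
                    f"prealigned row for {sid} does not degap to its sequence")
        return block
    coded = []
    for sid, seq in lset.members:
        try:
            coded.append(np.array([_DNA_CODE[c] for c in seq.upper()], dtype=np.int16))
        except KeyError as exc:
            raise DomainError(f"non-DNA character in {sid}: {exc}") from exc
    rows = progressive_align(coded, scoring, nsym=len(_DNA))
    out = ["".join(GAP_CHAR if v < 0 else _DNA[v] for v in r) for r in rows]
    block = BlockMSA(lset.locus_label, ids, out)
    for (sid, seq), row in zip(lset.members, block.rows):
        if row.replace(GAP_CHAR, "") != seq.upper():  # pragma: no cover
            raise IntegrityError(f"block row for {sid} lost bases")
    return block


def concatenate_blocks(blocks: Sequence[BlockMSA], all_ids: Sequence[str],
                       order: Sequence[str] | None = None) -> FullHaplotypeMSA:
    """Lay blocks left-to-right (canonical order), pad absentees with gaps."""
    labels = [b.locus_label for b in blocks]
    if len(set(labels)) != len(labels):
        raise DomainError("duplicate locus label among blocks")
    if order is not None:
        by_label = {b.locus_label: b for b in blocks}
        unknown = set(labels) - set(order)
        if unknown:
            raise DomainError(f"blocks not in the given order: {sorted(unknown)}")
        blocks = [by_label[l] for l in order if l in by_label]
    parts = {sid: [] for sid in all_ids}
    boundaries = []
    col = 0
    for b in blocks:
        w = b.width
        rows = dict(zip(b.ids, b.rows))
        for sid in all_ids:
            parts[sid].append(rows.get(sid, GAP_CHAR * w))
        boundaries.append((b.locus_label, col, col + w))
        col += w
    msa = FullHaplotypeMSA(ids=list(all_ids),
                           rows=["".join(parts[sid]) for sid in all_ids],
                           boundaries=boundaries)
    if msa.width != sum(b.width for b in blocks):  # pragma: no cover
        raise IntegrityError("width additivity violated")
    return msa


def verify_full_msa(msa: FullHaplotypeMSA,
                    locus_ordered: Mapping[str, str]) -> None:
    """Hard check of the two binding invariants: width additivity and the
    per-row degap round trip against each haplotype's locus-ordered DNA."""
    if msa.boundaries and msa.width != msa.boundaries[-1][2]:
        raise IntegrityError("boundary table does not cover the alignment")
    for i, sid in enumerate(msa.ids):
        if msa.degapped(i) != locus_ordered[sid].upper():
            raise IntegrityError(f"degap round trip failed for {sid}")
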