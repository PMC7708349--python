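"""Placement of anchor probes on haplotype-length DNA.

A haplotype is scaffolded by finding every placement of each short probe
(all-hits semantics) whose full-length, end-to-end alignment has unit-cost
edit distance at most ``max_cost``, on either strand.  Overlapping placements
then compete: among hits overlapping by more than a configured fraction of
the shorter hit, only the lowest-cost one survives, leaving an ordered,
non-overlapping scaffold of anchors.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._dp import semiglobal_end_costs
from .errors import DomainError, RegistryError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MAX_COST = 8
DEFAULT_OVERLAP_FRACTION = 0.5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, role: str) -> np.ndarray:
    """Code DNA as uint8.  'N' in subject and probe get distinct codes so an
    N never matches anything, including another N."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise DomainError(f"non-DNA character {seq[pos]!r} at position {pos}")
    arr[arr == ord("N")] = 0 if role == "subject" else 1
    return arr


@dataclass(frozen=True)
class ProbeHit:
    """One placement of one probe on one sequence."""

    probe_id: int
    start: int
    end: int
    strand: str  # '+' or '-'
    cost: int

    def overlap(self, other: "ProbeHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ProbeSet:
    """An ordered collection of anchor probes with unique integer ids."""

    def __init__(self, entries: Sequence[tuple[int, str]]):
        ids = [pid for pid, _ in entries]
        if len(set(ids)) != len(ids):
            raise RegistryError("probe ids must be unique")
        for pid, seq in entries:
            if pid <= 0:
                raise RegistryError(f"probe id {pid} is not a positive integer")
            if not seq:
                raise RegistryError(f"probe {pid} has an empty sequence")
            if set(seq.upper()) - set("ACGTN"):
                raise RegistryError(f"probe {pid} contains non-DNA characters")
        self.entries: list[tuple[int, str]] = [(pid, seq.upper()) for pid, seq in entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sequence(self, probe_id: int) -> str:
        for pid, seq in self.entries:
            if pid == probe_id:
                return seq
        raise KeyError(probe_id)

    @classmethod
    def from_fasta(cls, path) -> "ProbeSet":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                pid = int(rec.id)
            except ValueError as exc:
                raise RegistryError(f"probe record id {rec.id!r} is not an integer") from exc
            entries.append((pid, str(rec.seq)))
        if not entries:
            raise RegistryError(f"no probe records in {path}")
        return cls(entries)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for pid, seq in self.entries:
                fh.write(f">{pid}\n{seq}\n")


def _best_start(text_codes: np.ndarray, probe_codes: np.ndarray, end: int,
                cost: int, max_cost: int) -> int:
    """Recover the start of a hit ending at ``end`` with known cost by
    scanning the reversed window with the reversed probe."""
    m = probe_codes.shape[0]
    lo = max(0, end - (m + max_cost))
    window = text_codes[lo:end][::-1].copy()
    rc = semiglobal_end_costs(window, probe_codes[::-1].copy())
    best_j, best_key = None, None
    for j in range(window.shape[0] + 1):
        if rc[j] == cost:
            key = (abs(j - m), j)
            if best_key is None or key < best_key:
                best_key, best_j = key, j
    if best_j is None:  # pragma: no cover - defensive
        raise RuntimeError("start recovery failed")
    return end - best_j


def _scan_one_strand(text_codes: np.ndarray, probe_codes: np.ndarray,
                     probe_id: int, strand: str, max_cost: int) -> list[ProbeHit]:
    m = probe_codes.shape[0]
    costs = semiglobal_end_costs(text_codes, probe_codes)
    qual = np.nonzero(costs <= max_cost)[0]
    qual = qual[qual > 0]
    if qual.size == 0:
        return []
    # Cluster qualifying end offsets: nearby ends describe the same placement
    # shifted by edits; keep the minimum-cost end per cluster (earliest on tie).
    gap = max(1, m // 2)
    hits: list[ProbeHit] = []
    cluster = [int(qual[0])]
    for j in qual[1:]:
        if int(j) - cluster[-1] > gap:
            hits.append(_cluster_hit(text_codes, probe_codes, probe_id, strand,
                                     cluster, costs, max_cost))
            cluster = [int(j)]
        else:
            cluster.append(int(j))
    hits.append(_cluster_hit(text_codes, probe_codes, probe_id, strand,
                             cluster, costs, max_cost))
    return hits


def _cluster_hit(text_codes, probe_codes, probe_id, strand, cluster, costs, max_cost):
    best_end = min(cluster, key=lambda j: (costs[j], j))
    cost = int(costs[best_end])
    start = _best_start(text_codes, probe_codes, best_end, cost, max_cost)
    return ProbeHit(probe_id, start, best_end, strand, cost)


def find_probe_hits(sequence: str, probes: ProbeSet,
                    max_cost: int = DEFAULT_MAX_COST) -> list[ProbeHit]:
    """All placements of every probe with edit cost <= max_cost, both strands.

    Returns hits sorted by start, then end, then probe id.  A probe longer
    than the sequence simply yields no hits; an empty sequence is an error.
    """
    if not sequence:
        raise DomainError("empty sequence")
    if max_cost < 0:
        raise DomainError("max_cost must be >= 0")
    text = _encode(sequence, "subject")
    hits: list[ProbeHit] = []
    for pid, pseq in probes:
        if len(pseq) > len(sequence):
            continue
        fwd = _encode(pseq, "probe")
        rev = _encode(reverse_complement(pseq), "probe")
        hits.extend(_scan_one_strand(text, fwd, pid, "+", max_cost))
        hits.extend(_scan_one_strand(text, rev, pid, "-", max_cost))
    hits.sort(key=lambda h: (h.start, h.end, h.probe_id, h.strand))
    return hits


def order_hits(hits: Iterable[ProbeHit],
               overlap_fraction: float = DEFAULT_OVERLAP_FRACTION) -> list[ProbeHit]:
    """Greedy lowest-cost pruning of conflicting hits, then sort by start.

    Two hits conflict when their overlap exceeds ``overlap_fraction`` of the
    shorter hit's length.  Hits are admitted in order of (cost, probe_id,
    start); an admitted hit excludes all later conflicting ones.
    """
    ranked = sorted(hits, key=lambda h: (h.cost, h.probe_id, h.start, h.end, h.strand))
    kept: list[ProbeHit] = []
    for h in ranked:
        ok = True
        for k in kept:
            shorter = min(h.end - h.start, k.end - k.start)
            if shorter > 0 and h.overlap(k) > overlap_fraction * shorter:
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.probe_id))
    return kept


def majority_strand(hits: Sequence[ProbeHit]) -> str:
    """'+' unless strictly more hits lie on the minus strand."""
    minus = sum(1 for h in hits if h.strand == "-")
    return "-" if minus > len(hits) - minus else "+"


def write_hits_tsv(path, seq_id: str, hits: Sequence[ProbeHit]) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tprobe_id\tstart\tend\tstrand\tcost\n")
        for h in hits:
            fh.write(f"{seq_id}\t{h.probe_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.cost}\n")
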