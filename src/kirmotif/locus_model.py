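"""Locus segmentation, gene calls, and haplotype structure naming.

A haplotype motif string is cut into loci by greedy left-to-right matching
of locus patterns in their canonical 5'->3' rank order, every locus being
optional.  Patterns are small regular expressions over the motif alphabet
(literals, character classes like ``[FA]``, and postfix ``+ * ?``); a locus
may have alternative pattern rows ("variants", e.g. the 3DL1-proximal
variant of the 3DL2 motif carried by 3DL1/3DL2 fusion alleles).  At each
position the longest available match wins, ties going to the lowest rank;
unmatched symbols are reported, never dropped.  A pattern that is truncated
by the end of the string (an incomplete 3' haplotype) yields a terminal
segment flagged partial.

Gene families with a shared motif (MHCIJ at 2DL1/2DS1/2DS2, FIRL at the two
2DL5 loci, FZ*GHCIJKL at 2DL2L3/2DS3S5/2DS3S4S5) are disambiguated purely
by rank context.  The count of the repeat symbol 'Z' inside a 2DS3S5 or
2DS3S4S5 segment hints the allele: one Z points to 2DS3, two or three to
2DS5, anything else is 2DS4-compatible.  A 3DL2 match through the fusion
variant is resolved by 2DS4 linkage: haplotypes carrying a 2DS4-compatible
segment cannot carry the fusion.
"""

from __future__ import annotations

import importlib.resources as _res
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, RegistryError
from .motif_encode import MotifString

INTERGENIC_FAMILY = "intergenic"
Z_LOCI = ("2DS3S5", "2DS3S4S5")
FUSION_LOCUS = "3DL2"
FUSION_PROXIMAL = "3DL1S1"
FUSION_LINKAGE = "2DS3S4S5"
FUSION_CALL = "3DL1/3DL2-fusion"
NOVEL = "novel"

PRESENT, ABSENT, PARTIAL = "present", "absent", "partial"


# ---------------------------------------------------------------------------
# pattern machinery
# ---------------------------------------------------------------------------

def _tokenize(pattern: str) -> list[tuple[frozenset, int, int | None]]:
    """Parse a motif pattern into (charset, min, max) tokens."""
    tokens: list[tuple[frozenset, int, int | None]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise RegistryError(f"unterminated class in pattern {pattern!r}")
            charset = frozenset(pattern[i + 1:j])
            i = j + 1
        elif ch in "+*?]":
            raise RegistryError(f"misplaced {ch!r} in pattern {pattern!r}")
        else:
            charset = frozenset(ch)
            i += 1
        lo, hi = 1, 1
        if i < len(pattern) and pattern[i] in "+*?":
            q = pattern[i]
            lo, hi = (1, None) if q == "+" else (0, None) if q == "*" else (0, 1)
            i += 1
        tokens.append((charset, lo, hi))
    if not tokens:
        raise RegistryError("empty pattern")
    return tokens


def _match_longest(tokens, s: str, pos: int) -> int:
    """Length of the longest full match of tokens at s[pos:], or -1."""
    best = -1

    def rec(ti: int, p: int):
        nonlocal best
        if ti == len(tokens):
            best = max(best, p - pos)
            return
        charset, lo, hi = tokens[ti]
        k = 0
        while True:
            if k >= lo:
                rec(ti + 1, p + k)
            if hi is not None and k >= hi:
                break
            if p + k >= len(s) or s[p + k] not in charset:
                break
            k += 1

    rec(0, pos)
    return best


def _match_partial_to_end(tokens, s: str, pos: int) -> bool:
    """True if s[pos:] is a proper prefix of some string the pattern accepts
    (the string runs out before the pattern is satisfied)."""
    n = len(s)

    def rec(ti: int, p: int) -> bool:
        if p == n:
            # at least one mandatory token still unmet -> genuinely partial
            return any(lo > 0 for _, lo, _ in tokens[ti:]) or ti < len(tokens)
        if ti == len(tokens):
            return False
        charset, lo, hi = tokens[ti]
        k = 0
        while True:
            if k >= lo and rec(ti + 1, p + k):
                return True
            if hi is not None and k >= hi:
                return False
            if p + k >= n:
                return rec(ti, n) if k >= lo else (p + k == n)
            if s[p + k] not in charset:
                return False
            k += 1

    return rec(0, pos) and _match_longest(tokens, s, pos) < n - pos


# ---------------------------------------------------------------------------
# registries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneMotifPattern:
    locus_label: str
    rank: int
    pattern: str
    gene_family: str
    variant: str = ""

    def tokens(self):
        return _tokenize(self.pattern)


def load_pattern_registry(path=None) -> list[GeneMotifPattern]:
    """Load the locus pattern registry (canonical one if no path given)."""
    if path is None:
        path = _res.files("kirmotif.data") / "gene_patterns.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    registry = [GeneMotifPattern(str(r.locus_label), int(r.rank), str(r.pattern),
                                 str(r.gene_family),
                                 "" if str(r.variant) in (".", "nan") else str(r.variant))
                for r in df.itertuples()]
    validate_pattern_registry(registry)
    return registry


def validate_pattern_registry(registry: Sequence[GeneMotifPattern]) -> None:
    if not registry:
        raise RegistryError("pattern registry is empty")
    by_rank: dict[int, str] = {}
    for p in registry:
        p.tokens()  # syntax check
        if p.rank in by_rank and by_rank[p.rank] != p.locus_label:
            raise RegistryError(
                f"rank {p.rank} assigned to both {by_rank[p.rank]} and {p.locus_label}")
        by_rank[p.rank] = p.locus_label
    labels = {}
    for p in registry:
        if p.locus_label in labels and labels[p.locus_label] != p.rank:
            raise RegistryError(f"locus {p.locus_label} has two ranks")
        labels[p.locus_label] = p.rank


def genic_loci(registry: Sequence[GeneMotifPattern]) -> list[str]:
    """Genic locus labels in rank order (intergenic blocks excluded)."""
    seen = {}
    for p in sorted(registry, key=lambda p: p.rank):
        if p.gene_family != INTERGENIC_FAMILY:
            seen.setdefault(p.locus_label, p.rank)
    return sorted(seen, key=seen.get)


def gene_motif_classes(registry: Sequence[GeneMotifPattern]) -> set[str]:
    return {p.gene_family for p in registry if p.gene_family != INTERGENIC_FAMILY}


@dataclass(frozen=True)
class StructureDefinition:
    name: str
    states: dict  # locus_label -> present/absent/partial

    def vector(self, loci: Sequence[str]) -> tuple:
        return tuple(self.states.get(l, ABSENT) for l in loci)


def load_structure_definitions(path=None) -> list[StructureDefinition]:
    if path is None:
        path = _res.files("kirmotif.data") / "structures.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    states: dict[str, dict] = {}
    for r in df.itertuples():
        states.setdefault(str(r.structure_name), {})[str(r.locus_label)] = str(r.state)
    defs = [StructureDefinition(name, s) for name, s in states.items()]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):  # pragma: no cover
        raise RegistryError("duplicate structure names")
    return defs


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class LocusSegment:
    locus_label: str
    rank: int
    motif: str
    sym_start: int
    sym_end: int
    z_count: int
    gene_call: str
    variant: str = ""
    partial: bool = False
    genomic: tuple[int, int] | None = None


@dataclass
class Segmentation:
    """Ordered locus segments plus explicitly reported unmatched runs."""

    motif: MotifString
    segments: list[LocusSegment] = field(default_factory=list)
    unmatched: list[tuple[int, int]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def segment(self, locus_label: str) -> LocusSegment | None:
        for s in self.segments:
            if s.locus_label == locus_label:
                return s
        return None

    def check_partition(self) -> None:
        covered = sorted([(s.sym_start, s.sym_end) for s in self.segments]
                         + list(self.unmatched))
        pos = 0
        for a, b in covered:
            if a != pos:
                raise DomainError("segments + unmatched do not tile the motif")
            pos = b
        if pos != len(self.motif.symbols):
            raise DomainError("segments + unmatched do not tile the motif")


def segment_loci(motif: MotifString | str, registry: Sequence[GeneMotifPattern],
                 repeat_symbols: Iterable[str] = ("Z",),
                 allow_partial_terminal: bool = True) -> Segmentation:
    """Greedy in-order segmentation of a motif string into loci.

    Matching walks 5'->3'; at each position every locus whose rank exceeds
    the last matched rank is tried (all its pattern variants) and the
    longest match wins, ties to the lowest rank.  Unmatched symbols are
    recorded and skipped one at a time.  At the string end a pattern
    truncated after >= 2 symbols yields a ``partial`` terminal segment.
    """
    if isinstance(motif, str):
        motif = MotifString(seq_id="", symbols=motif)
    if not registry:
        raise DomainError("pattern registry is empty")
    reg = sorted(registry, key=lambda p: (p.rank, p.variant))
    toks = {id(p): p.tokens() for p in reg}
    repeat = set(repeat_symbols)
    s = motif.symbols
    seg = Segmentation(motif=motif)
    pos, min_rank = 0, 0
    run_start = None
    while pos < len(s):
        best = None  # (length, rank, pattern)
        for p in reg:
            if p.rank <= min_rank:
                continue
            L = _match_longest(toks[id(p)], s, pos)
            if L > 0:
                key = (-L, p.rank, p.variant)
                if best is None or key < best[0]:
                    best = (key, L, p)
        if best is None and allow_partial_terminal:
            for p in reg:
                if p.rank <= min_rank:
                    continue
                if len(s) - pos >= 2 and _match_partial_to_end(toks[id(p)], s, pos):
                    sub = s[pos:]
                    if run_start is not None:
                        seg.unmatched.append((run_start, pos))
                        run_start = None
                    seg.segments.append(LocusSegment(
                        locus_label=p.locus_label, rank=p.rank, motif=sub,
                        sym_start=pos, sym_end=len(s),
                        z_count=sum(1 for c in sub if c in repeat),
                        gene_call=p.gene_family, variant=p.variant, partial=True))
                    pos = len(s)
                    break
            else:
                if run_start is None:
                    run_start = pos
                pos += 1
            continue
        if best is None:
            if run_start is None:
                run_start = pos
            pos += 1
            continue
        _, L, p = best
        if run_start is not None:
            seg.unmatched.append((run_start, pos))
            run_start = None
        sub = s[pos:pos + L]
        seg.segments.append(LocusSegment(
            locus_label=p.locus_label, rank=p.rank, motif=sub,
            sym_start=pos, sym_end=pos + L,
            z_count=sum(1 for c in sub if c in repeat),
            gene_call=p.gene_family, variant=p.variant))
        min_rank = p.rank
        pos += L
    if run_start is not None:
        seg.unmatched.append((run_start, len(s)))
    _attach_genomic(seg)
    return seg


def _attach_genomic(seg: Segmentation) -> None:
    """Raw genomic span of each segment from its symbols' spans."""
    spans = seg.motif.spans
    if not spans:
        return
    for sg in seg.segments:
        sg.genomic = (spans[sg.sym_start][0], spans[sg.sym_end - 1][1])


def tiled_intervals(seg: Segmentation, seq_len: int) -> list[tuple[str, int, int]]:
    """Cut the whole sequence into per-locus DNA intervals.

    The shared anchor between adjacent loci closes the left locus: locus k's
    interval starts at the end of its opening anchor (position 0 for the
    first locus) and runs to the start of the next locus, so the intervals
    tile [0, seq_len) and no base is dropped — unmatched motif residues are
    absorbed into the preceding locus.
    """
    anchors = seg.motif.anchors
    if anchors is None:
        raise DomainError("motif carries no anchor intervals")
    out = []
    segs = seg.segments
    for k, sg in enumerate(segs):
        start = 0 if k == 0 else anchors[sg.sym_start][1]
        end = seq_len if k == len(segs) - 1 else anchors[segs[k + 1].sym_start][1]
        if not 0 <= start <= end <= seq_len:
            raise DomainError(f"locus {sg.locus_label} interval out of bounds")
        out.append((sg.locus_label, start, end))
    return out


# ---------------------------------------------------------------------------
# gene calls and structure naming
# ---------------------------------------------------------------------------

def z_allele_hint(segment: LocusSegment) -> str:
    """Allele hint from the Z-repeat count of a 2DS3S5/2DS3S4S5 segment."""
    if segment.locus_label not in Z_LOCI:
        raise DomainError(
            f"z_allele_hint applies to {Z_LOCI}, not {segment.locus_label}")
    if segment.z_count == 1:
        return "2DS3"
    if segment.z_count in (2, 3):
        return "2DS5"
    return "indeterminate"


@dataclass
class PresenceVector:
    loci: list[str]
    states: dict
    anomalies: list[str] = field(default_factory=list)

    def __getitem__(self, locus: str) -> str:
        return self.states[locus]

    def __setitem__(self, locus: str, state: str) -> None:
        self.states[locus] = state

    def vector(self) -> tuple:
        return tuple(self.states[l] for l in self.loci)


def presence_vector(seg: Segmentation,
                    registry: Sequence[GeneMotifPattern]) -> PresenceVector:
    loci = genic_loci(registry)
    states = {l: ABSENT for l in loci}
    anomalies: list[str] = []
    for sg in seg.segments:
        if sg.locus_label not in states:
            continue
        if states[sg.locus_label] != ABSENT:
            anomalies.append(f"duplicate segment at locus {sg.locus_label}")
            continue
        states[sg.locus_label] = PARTIAL if sg.partial else PRESENT
    return PresenceVector(loci=loci, states=states, anomalies=anomalies)


@dataclass
class FusionCall:
    call: str | None
    warning: str | None = None


def resolve_fusion(vector: PresenceVector, seg: Segmentation) -> FusionCall:
    """Resolve the 3DL1/3DL2 fusion ambiguity by 2DS4 linkage.

    A 3DL2 segment matched through the 3DL1-proximal variant (or with a
    merely partial 3DL1S1 segment upstream) is fusion-compatible.  The
    fusion lacks 2DS4, so a 2DS4-compatible segment at the 2DS3S4S5 locus
    forces the plain 3DL2 call; otherwise the fusion is called and the 3DL2
    cell is flagged partial.
    """
    tgt = seg.segment(FUSION_LOCUS)
    if tgt is None:
        return FusionCall(call=None, warning=f"no {FUSION_LOCUS} segment matched")
    proximal_state = vector.states.get(FUSION_PROXIMAL, ABSENT)
    fusion_compatible = tgt.variant == "3DL1-proximal" or proximal_state == PARTIAL
    if not fusion_compatible:
        tgt.gene_call = FUSION_LOCUS
        return FusionCall(call=FUSION_LOCUS)
    linkage = seg.segment(FUSION_LINKAGE)
    s4_compatible = linkage is not None and z_allele_hint(linkage) == "indeterminate"
    if s4_compatible:
        tgt.gene_call = FUSION_LOCUS
        return FusionCall(call=FUSION_LOCUS)
    tgt.gene_call = FUSION_CALL
    vector[FUSION_LOCUS] = PARTIAL
    return FusionCall(call=FUSION_CALL)


def name_structure(vector: PresenceVector,
                   definitions: Sequence[StructureDefinition]
                   ) -> tuple[str, list[tuple[str, int]]]:
    """Exact vector match -> structure name; otherwise ('novel', nearest).

    The nearest list carries (name, Hamming distance) for the closest
    definitions (ties all listed, lexicographic order).
    """
    if not definitions:
        raise DomainError("no structure definitions loaded")
    loci = vector.loci
    vecs = {}
    for d in definitions:
        v = d.vector(loci)
        if v in vecs:
            raise RegistryError(
                f"structures {vecs[v]} and {d.name} have identical vectors")
        vecs[v] = d.name
    target = vector.vector()
    if target in vecs:
        return vecs[target], []
    dists = sorted((sum(a != b for a, b in zip(target, d.vector(loci))), d.name)
                   for d in definitions)
    best = dists[0][0]
    nearest = sorted((name, dist) for dist, name in dists if dist == best)
    return NOVEL, nearest


def write_annotation_tsv(path, seq_id: str, seg: Segmentation,
                         structure_name: str) -> None:
    """Per-haplotype annotation report (coordinates 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tlocus_label\tstart\tend\tmotif\tz_count\tgene_call\n")
        for sg in seg.segments:
            g = sg.genomic or ("", "")
            fh.write(f"{seq_id}\t{sg.locus_label}\t{g[0]}\t{g[1]}\t{sg.motif}\t"
                     f"{sg.z_count}\t{sg.gene_call}\n")
        fh.write(f"# structure\t{seq_id}\t{structure_name}\n")
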