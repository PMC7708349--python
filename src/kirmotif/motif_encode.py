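"""Probe-pair motif encoding.

Each ordered pair of consecutive anchor placements on a haplotype is looked
up in a :class:`PairAlphabet` and rendered as one printable symbol, so a
haplotype becomes a short string over the pair alphabet (its "motif").  A
pair of identical probe ids flagged as a repeat pair (canonically (1,1),
symbol 'Z') emits one symbol per consecutive occurrence: a run of n probe-1
anchors yields n-1 'Z's.

Every symbol carries its genomic span: from the start of its left anchor to
the end of its right anchor, 0-based half-open.  Consecutive symbols share
the middle anchor, so spans tile the scaffold without inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import CapacityError, DomainError, RegistryError, UnknownPairError
from .probe_align import ProbeHit

#: Symbols handed out, in order, when novel pairs are observed.  '-' and '.'
#: are excluded by construction (alignment gap characters).
DEFAULT_RESERVE = (
    "BDE"
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789"
    "!#$%&*+/:;<=>?@^_|~"
)


class PairAlphabet:
    """Registry mapping ordered probe-id pairs to single printable symbols."""

    def __init__(self, mapping: dict[tuple[int, int], str],
                 repeat_pairs: Iterable[tuple[int, int]] = ((1, 1),),
                 reserve: str | None = None):
        self.mapping: dict[tuple[int, int], str] = {}
        for pair, sym in mapping.items():
            self._check_symbol(sym)
            self.mapping[(int(pair[0]), int(pair[1]))] = sym
        symbols = list(self.mapping.values())
        if len(set(symbols)) != len(symbols):
            raise RegistryError("pair->symbol mapping must be injective")
        self.repeat_pairs = {tuple(p) for p in repeat_pairs}
        for p in self.repeat_pairs:
            if p[0] != p[1]:
                raise RegistryError(f"repeat pair {p} must have identical probe ids")
        used = set(symbols)
        pool = reserve if reserve is not None else DEFAULT_RESERVE
        self.reserve: list[str] = [s for s in pool if s not in used]

    @staticmethod
    def _check_symbol(sym: str) -> None:
        if len(sym) != 1 or sym in "-." or sym.isspace() or not sym.isprintable():
            raise RegistryError(f"invalid motif symbol {sym!r}")

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in self.mapping

    def symbol(self, pair: tuple[int, int]) -> str:
        return self.mapping[tuple(pair)]

    @property
    def repeat_symbols(self) -> set[str]:
        return {self.mapping[p] for p in self.repeat_pairs if p in self.mapping}

    def pair_of(self, symbol: str) -> tuple[int, int]:
        for pair, sym in self.mapping.items():
            if sym == symbol:
                return pair
        raise KeyError(symbol)

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "PairAlphabet":
        df = pd.read_csv(path, sep="\t", comment="#")
        mapping = {(int(r.probe_from), int(r.probe_to)): str(r.symbol)
                   for r in df.itertuples()}
        repeats = [(int(r.probe_from), int(r.probe_to))
                   for r in df.itertuples() if int(getattr(r, "repeat", 0))]
        return cls(mapping, repeat_pairs=repeats)

    def to_tsv(self, path) -> None:
        rows = [{"probe_from": a, "probe_to": b, "symbol": s,
                 "repeat": int((a, b) in self.repeat_pairs)}
                for (a, b), s in sorted(self.mapping.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def extend_alphabet(observed_pairs: Sequence[tuple[int, int]],
                    alphabet: PairAlphabet) -> PairAlphabet:
    """Assign reserve symbols to novel pairs, first-observed order; idempotent."""
    mapping = dict(alphabet.mapping)
    reserve = list(alphabet.reserve)
    for pair in observed_pairs:
        pair = (int(pair[0]), int(pair[1]))
        if pair in mapping:
            continue
        if not reserve:
            raise CapacityError(f"reserve symbol pool exhausted at pair {pair}")
        mapping[pair] = reserve.pop(0)
    return PairAlphabet(mapping, repeat_pairs=alphabet.repeat_pairs,
                        reserve="".join(reserve))


@dataclass
class MotifString:
    """A haplotype rendered over the pair alphabet, with per-symbol spans.

    ``anchors`` optionally retains the underlying ordered hit intervals
    (len(anchors) == len(symbols) + 1) so locus boundaries can be cut at
    anchor edges later in the pipeline.
    """

    seq_id: str
    symbols: str
    spans: list[tuple[int, int]] = field(default_factory=list)
    anchors: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if self.spans and len(self.spans) != len(self.symbols):
            raise DomainError("one span per symbol required")

    def __len__(self) -> int:
        return len(self.symbols)


def encode_motif(hits: Sequence[ProbeHit], alphabet: PairAlphabet,
                 seq_id: str = "", extend: bool = False) -> MotifString:
    """Encode an ordered, non-overlapping hit scaffold as a motif string.

    One symbol per consecutive hit pair; a single hit (or none) encodes the
    empty motif.  With ``extend=False`` an unseen pair raises
    :class:`UnknownPairError`; with ``extend=True`` the alphabet is extended
    in place semantics-free (a new alphabet is not returned here — call
    :func:`extend_alphabet` first for registry control).
    """
    hits = list(hits)
    for a, b in zip(hits, hits[1:]):
        if b.start < a.start:
            raise DomainError("hits must be ordered by start")
    symbols: list[str] = []
    spans: list[tuple[int, int]] = []
    if extend:
        alphabet = extend_alphabet(
            [(a.probe_id, b.probe_id) for a, b in zip(hits, hits[1:])], alphabet)
    for a, b in zip(hits, hits[1:]):
        pair = (a.probe_id, b.probe_id)
        if pair not in alphabet:
            raise UnknownPairError(pair, (a.start, b.end))
        symbols.append(alphabet.symbol(pair))
        spans.append((a.start, b.end))
    return MotifString(seq_id=seq_id, symbols="".join(symbols), spans=spans,
                       anchors=[(h.start, h.end) for h in hits])


def symbol_span(motif: MotifString, index: int) -> tuple[int, int]:
    """Genomic half-open interval of symbol ``index``."""
    if not 0 <= index < len(motif.symbols):
        raise IndexError(f"symbol index {index} out of range for motif of "
                         f"length {len(motif.symbols)}")
    if not motif.spans:
        raise DomainError("motif carries no span information")
    return motif.spans[index]


def write_motifs_fasta(path, motifs: Sequence[MotifString]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.seq_id}\n{m.symbols}\n")


def write_spans_tsv(path, motifs: Sequence[MotifString]) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tsymbol_index\tsymbol\tstart\tend\n")
        for m in motifs:
            for i, ((s, e), sym) in enumerate(zip(m.spans, m.symbols)):
                fh.write(f"{m.seq_id}\t{i}\t{sym}\t{s}\t{e}\n")
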