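"""Synthetic haplotype worlds with planted structures and truth labels.

The generator emulates exactly the features the annotation method consumes:
an ordered scaffold of anchor probes whose consecutive pairs spell a motif
string, grouped into locus cassettes that are concatenated in canonical
5'->3' order for each haplotype structure.  Inter-anchor filler is random
DNA; it does not model KIR paralog homology, repeat elements or
recombination.  A single master seed determines everything; per-haplotype
seeds are derived by stable hashing of (master seed, sequence id).

Default shapes mirror the canonical world: 18 probes of 120 bp and a mean
inter-anchor spacing of 2.4 kb.  Both are configurable, and the test suite
runs the same generator at reduced probe length and spacing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .errors import DomainError, IntegrityError
from .locus_model import (PARTIAL, GeneMotifPattern, StructureDefinition,
                          genic_loci, load_pattern_registry,
                          load_structure_definitions)
from .motif_encode import PairAlphabet
from .probe_align import ProbeSet, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Base cassette motif per locus in the canonical world.  Z-carrying loci
#: are templated with {z} and filled per structure (allele choice).
CANONICAL_CASSETTES = {
    "3DL3": "MHCIJKL",
    "2DS2": "MHCIJKL",
    "2DL2L3": "FGHCIJKL",
    "2DL5cen": "AIRL",
    "2DS3S5": "F{z}GHCIJKL",
    "2DP1": "MHCIRL",
    "2DL1": "MHCIJKL",
    "3DP1": "SC",
    "3DP1-2DL4": "TUVWX",
    "2DL4": "YKL",
    "3DL1S1": "SCNOJKL",
    "2DL5tel": "AIRL",
    "2DS3S4S5": "F{z}GHCIJKL",
    "2DS1": "MHCIJKL",
    "3DL2": "FPCNOJQ",
}
FUSION_CASSETTE = ("3DL2", "SCNOJQ")

#: Z-repeat counts per region variant: one Z marks a 2DS3-like allele, two
#: or three a 2DS5-like one, other counts are 2DS4-compatible.
CANONICAL_Z_COUNTS = {
    ("cB01", "2DS3S5"): 1,
    ("cB04", "2DS3S5"): 2,
    ("cB05", "2DS3S5"): 3,
    ("tA01", "2DS3S4S5"): 0,
    ("tB01", "2DS3S4S5"): 2,
    ("tB03", "2DS3S4S5"): 4,
}


def derive_seed(master_seed: int, *parts) -> int:
    """Stable 31-bit seed from the master seed and an object id."""
    h = hashlib.sha256(":".join([str(master_seed), *map(str, parts)]).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=length, p=p)]).decode()


def generate_probe_set(n: int = 18, length: int = 120,
                       min_pairwise_distance: int = 30, seed: int = 0,
                       max_retries: int = 50) -> ProbeSet:
    """Random probes with all pairwise edit distances >= the floor, in both
    orientations.  Deterministic under the seed."""
    if n < 1 or length < 1:
        raise DomainError("need n >= 1 probes of positive length")
    rng = np.random.default_rng(seed)
    probes: list[str] = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            cand = _random_dna(rng, length)
            others = probes + [reverse_complement(p) for p in probes]
            if all(edlib.align(cand, o, task="distance")["editDistance"]
                   >= min_pairwise_distance for o in others):
                probes.append(cand)
                break
        else:
            raise DomainError(
                "could not generate probes satisfying the distance floor")
    return ProbeSet([(i + 1, p) for i, p in enumerate(probes)])


@dataclass
class CassetteLibrary:
    """Locus cassettes + filler model realizing planted structures as DNA."""

    probes: ProbeSet
    alphabet: PairAlphabet
    registry: list[GeneMotifPattern]
    definitions: list[StructureDefinition]
    cassettes: dict = field(default_factory=lambda: dict(CANONICAL_CASSETTES))
    z_counts: dict = field(default_factory=lambda: dict(CANONICAL_Z_COUNTS))
    spacing: int = 2400
    gc: float = 0.5

    def definition(self, name: str) -> StructureDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise DomainError(f"unknown structure {name!r}")

    def motif_chunks(self, structure: StructureDefinition | str
                     ) -> list[tuple[str, str]]:
        """(locus_label, motif chunk) for every locus of the structure, in
        canonical rank order, with the intergenic block inserted between
        3DP1 and 2DL4 and the fusion cassette standing in for a partial
        3DL2."""
        d = self.definition(structure) if isinstance(structure, str) else structure
        cen, _, tel = d.name.partition("~")
        order = sorted({p.locus_label: p.rank for p in self.registry}.items(),
                       key=lambda kv: kv[1])
        genic = set(genic_loci(self.registry))
        chunks = []
        for label, _rank in order:
            if label not in genic:  # intergenic: present iff both flanks are
                if (d.states.get("3DP1", "absent") != "absent"
                        and d.states.get("2DL4", "absent") != "absent"):
                    chunks.append((label, self.cassettes[label]))
                continue
            state = d.states.get(label, "absent")
            if state == "absent":
                continue
            if label not in self.cassettes:
                raise DomainError(f"no cassette for locus {label}")
            if label == FUSION_CASSETTE[0] and state == PARTIAL:
                chunks.append((label, FUSION_CASSETTE[1]))
                continue
            motif = self.cassettes[label]
            if "{z}" in motif:
                region = cen if label == "2DS3S5" else tel
                z = self.z_counts.get((region, label), 1)
                motif = motif.replace("{z}", "Z" * z)
            chunks.append((label, motif))
        return chunks

    def walk(self, motif: str) -> list[int]:
        """Probe-id walk spelled by a motif string; errors if inconsistent."""
        if not motif:
            return []
        pairs = [self.alphabet.pair_of(c) for c in motif]
        ids = [pairs[0][0]]
        for (a, b), (c, _) in zip(pairs, pairs[1:]):
            if b != c:
                raise IntegrityError(
                    f"motif {motif!r} is not a consistent probe walk")
        for _, b in pairs:
            ids.append(b)
        return ids


def canonical_library(seed: int = 0, probe_length: int = 120, n_probes: int = 18,
                      spacing: int = 2400,
                      min_pairwise_distance: int | None = None) -> CassetteLibrary:
    """The shipped world: canonical registries + a seeded random probe set."""
    if min_pairwise_distance is None:
        min_pairwise_distance = max(2, probe_length // 4)
    probes = generate_probe_set(n=n_probes, length=probe_length,
                                min_pairwise_distance=min_pairwise_distance,
                                seed=derive_seed(seed, "probes"))
    from importlib.resources import files

    alphabet = PairAlphabet.from_tsv(files("kirmotif.data") / "pair_alphabet.tsv")
    return CassetteLibrary(probes=probes, alphabet=alphabet,
                           registry=load_pattern_registry(),
                           definitions=load_structure_definitions(),
                           spacing=spacing)


@dataclass
class SimulationTruth:
    seq_id: str
    structure_name: str
    motif: str
    locus_symbols: list[tuple[str, int, int]]  # locus, sym_start, sym_end
    locus_intervals: list[tuple[str, int, int]]  # locus, genomic start, end
    anchors: list[tuple[int, int]]
    n_mutations: int
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list)


def _mutate(rng: np.random.Generator, text: str, snv_rate: float,
            indel_rate: float) -> tuple[str, int]:
    if snv_rate == 0 and indel_rate == 0:
        return text, 0
    out = []
    n_mut = 0
    for ch in text:
        r = rng.random()
        if r < indel_rate / 2:  # deletion
            n_mut += 1
            continue
        if r < indel_rate:  # insertion before the base
            out.append(bytes(_BASES[rng.integers(4):][:1]).decode())
            n_mut += 1
        if rng.random() < snv_rate:
            alt = ch
            while alt == ch:
                alt = "ACGT"[rng.integers(4)]
            out.append(alt)
            n_mut += 1
        else:
            out.append(ch)
    return "".join(out), n_mut


def generate_haplotype(structure: StructureDefinition | str,
                       library: CassetteLibrary, snv_rate: float = 0.0,
                       indel_rate: float = 0.0, seed: int = 0,
                       anchor_safe: bool = True, seq_id: str | None = None
                       ) -> tuple[str, SimulationTruth]:
    """One haplotype realizing a planted structure, plus complete truth.

    Cassettes are concatenated in canonical locus order; each motif symbol
    becomes (left anchor, filler, right anchor) with anchors shared between
    consecutive symbols.  With ``anchor_safe`` mutations only touch filler.
    """
    for rate in (snv_rate, indel_rate):
        if not 0 <= rate <= 0.05:
            raise DomainError("mutation rates must lie in [0, 0.05]")
    d = library.definition(structure) if isinstance(structure, str) else structure
    sid = seq_id or d.name
    rng = np.random.default_rng(seed)
    chunks = library.motif_chunks(d)
    motif = "".join(m for _, m in chunks)
    walk = library.walk(motif)

    parts: list[tuple[str, str]] = []  # (kind, text)
    lo, hi = max(20, library.spacing // 2), library.spacing + library.spacing // 2
    for k, pid in enumerate(walk):
        if k > 0:
            parts.append(("filler", _random_dna(rng, int(rng.integers(lo, hi + 1)),
                                                library.gc)))
        parts.append((f"probe:{pid}", library.probes.sequence(pid)))
    parts.append(("filler", _random_dna(rng, int(rng.integers(lo, hi + 1)),
                                        library.gc)))

    n_mut = 0
    final: list[str] = []
    anchors: list[tuple[int, int]] = []
    pos = 0
    for kind, text in parts:
        if kind == "filler" or not anchor_safe:
            text, k = _mutate(rng, text, snv_rate, indel_rate)
            n_mut += k
        if kind.startswith("probe:"):
            anchors.append((pos, pos + len(text)))
        final.append(text)
        pos += len(text)
    seq = "".join(final)

    locus_symbols = []
    s = 0
    for label, m in chunks:
        locus_symbols.append((label, s, s + len(m)))
        s += len(m)
    if s != len(motif):  # pragma: no cover
        raise IntegrityError("cassette symbol accounting error")
    # boundary convention: a locus opens at the end of its opening anchor
    # (the shared anchor closes the left locus); first opens at 0
    locus_intervals = []
    for k, (label, a, b) in enumerate(locus_symbols):
        g0 = 0 if k == 0 else anchors[a][1]
        if k == len(locus_symbols) - 1:
            g1 = len(seq)
        else:
            g1 = anchors[locus_symbols[k + 1][1]][1]
        locus_intervals.append((label, g0, g1))

    truth = SimulationTruth(
        seq_id=sid, structure_name=d.name, motif=motif,
        locus_symbols=locus_symbols, locus_intervals=locus_intervals,
        anchors=anchors, n_mutations=n_mut, seed=seed,
        params={"snv_rate": snv_rate, "indel_rate": indel_rate,
                "anchor_safe": anchor_safe, "spacing": library.spacing})
    return seq, truth


def generate_panel(structures: Sequence[str | tuple[str, int]],
                   library: CassetteLibrary, snv_rate: float = 0.0,
                   indel_rate: float = 0.0, seed: int = 0,
                   anchor_safe: bool = True
                   ) -> tuple[list[tuple[str, str]], list[SimulationTruth]]:
    """A multi-haplotype panel; entries are names or (name, multiplicity)."""
    expanded: list[str] = []
    for entry in structures:
        if isinstance(entry, tuple):
            name, k = entry
            expanded.extend([name] * int(k))
        else:
            expanded.append(entry)
    if not expanded:
        raise DomainError("empty structure list")
    records, truths = [], []
    for i, name in enumerate(expanded):
        sid = f"{name}.{i}"
        seq, truth = generate_haplotype(
            name, library, snv_rate=snv_rate, indel_rate=indel_rate,
            seed=derive_seed(seed, "hap", sid), anchor_safe=anchor_safe,
            seq_id=sid)
        records.append((sid, seq))
        truths.append(truth)
    return records, truths


def write_panel(fasta_path, truth_path, records, truths) -> None:
    """Multi-FASTA plus a JSON-lines truth file (always written together)."""
    with open(fasta_path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(truth_path, "w") as fh:
        for t in truths:
            fh.write(t.to_json() + "\n")
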