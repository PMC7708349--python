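"""End-to-end glue: FASTA records -> annotation -> motif MSA -> DNA MSA."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import SeqIO

from .dna_msa import (BlockMSA, DnaScoring, FullHaplotypeMSA, align_locus,
                      concatenate_blocks, extract_locus_sets, verify_full_msa)
from .errors import DomainError
from .locus_model import (FusionCall, GeneMotifPattern, PresenceVector,
                          Segmentation, StructureDefinition,
                          load_pattern_registry, load_structure_definitions,
                          name_structure, presence_vector, resolve_fusion,
                          segment_loci, tiled_intervals)
from .motif_encode import MotifString, PairAlphabet, encode_motif
from .motif_msa import (AnchorConstraint, MotifMSA, SymbolScoring,
                        motif_distance_matrix, neighbor_joining,
                        progressive_msa)
from .probe_align import (ProbeSet, find_probe_hits, majority_strand,
                          order_hits, reverse_complement)


@dataclass
class AnnotationResult:
    seq_id: str
    sequence: str  # possibly reverse-complemented to the plus orientation
    reoriented: bool
    hits: list
    motif: MotifString
    segmentation: Segmentation
    vector: PresenceVector
    fusion: FusionCall
    structure_name: str
    nearest: list = field(default_factory=list)


def annotate_sequence(seq_id: str, sequence: str, probes: ProbeSet,
                      alphabet: PairAlphabet,
                      registry: Sequence[GeneMotifPattern],
                      definitions: Sequence[StructureDefinition],
                      max_cost: int = 8, extend: bool = False
                      ) -> AnnotationResult:
    """Annotate one haplotype: anchors -> motif -> loci -> structure name.

    A haplotype whose surviving anchor hits are majority-minus is
    reverse-complemented and re-annotated in the plus orientation.
    """
    hits = order_hits(find_probe_hits(sequence, probes, max_cost=max_cost))
    reoriented = False
    if hits and majority_strand(hits) == "-":
        sequence = reverse_complement(sequence)
        hits = order_hits(find_probe_hits(sequence, probes, max_cost=max_cost))
        reoriented = True
    motif = encode_motif(hits, alphabet, seq_id=seq_id, extend=extend)
    seg = segment_loci(motif, registry,
                       repeat_symbols=alphabet.repeat_symbols or ("Z",))
    vec = presence_vector(seg, registry)
    fusion = resolve_fusion(vec, seg)
    name, nearest = name_structure(vec, definitions)
    return AnnotationResult(seq_id=seq_id, sequence=sequence,
                            reoriented=reoriented, hits=hits, motif=motif,
                            segmentation=seg, vector=vec, fusion=fusion,
                            structure_name=name, nearest=nearest)


def annotate_records(records: Sequence[tuple[str, str]], probes: ProbeSet,
                     alphabet: PairAlphabet,
                     registry: Sequence[GeneMotifPattern] | None = None,
                     definitions: Sequence[StructureDefinition] | None = None,
                     max_cost: int = 8, extend: bool = False
                     ) -> dict[str, AnnotationResult]:
    if not records:
        raise DomainError("no records")
    registry = registry if registry is not None else load_pattern_registry()
    definitions = (definitions if definitions is not None
                   else load_structure_definitions())
    return {sid: annotate_sequence(sid, seq, probes, alphabet, registry,
                                   definitions, max_cost=max_cost, extend=extend)
            for sid, seq in records}


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def build_motif_msa(results: Mapping[str, AnnotationResult],
                    scoring: SymbolScoring | None = None,
                    anchors: Sequence[AnchorConstraint] | None = None) -> MotifMSA:
    return progressive_msa([r.motif for r in results.values()],
                           scoring=scoring, anchors=anchors)


def motif_tree(msa: MotifMSA) -> str:
    ids, D = motif_distance_matrix(msa)
    return neighbor_joining(D, ids)


def build_dna_msa(results: Mapping[str, AnnotationResult],
                  registry: Sequence[GeneMotifPattern] | None = None,
                  scoring: DnaScoring | None = None,
                  prealigned: Mapping[str, Sequence[str]] | None = None
                  ) -> tuple[list[BlockMSA], FullHaplotypeMSA]:
    """Per-locus blocks + the conforming concatenation, invariants verified."""
    registry = registry if registry is not None else load_pattern_registry()
    haplotypes = {sid: r.sequence for sid, r in results.items()}
    annotations = {sid: r.segmentation for sid, r in results.items()}
    sets = extract_locus_sets(haplotypes, annotations)
    blocks = [align_locus(s, scoring=scoring,
                          prealigned=(prealigned or {}).get(s.locus_label))
              for s in sets]
    full = concatenate_blocks(blocks, list(results))
    locus_ordered = {
        sid: "".join(haplotypes[sid][a:b] for _, a, b in
                     tiled_intervals(annotations[sid], len(haplotypes[sid])))
        for sid in results}
    verify_full_msa(full, locus_ordered)
    return blocks, full
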