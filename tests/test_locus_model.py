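"""Locus segmentation, Z-count allele hints, fusion resolution, naming."""

import pytest

from helpers import segmentations_exhaustive
from kirmotif import (EXAMPLE_KP420440_MOTIF, PresenceVector,
                      StructureDefinition, gene_motif_classes, genic_loci,
                      name_structure, presence_vector, resolve_fusion,
                      segment_loci, z_allele_hint)
from kirmotif.errors import DomainError, RegistryError
from kirmotif.locus_model import ABSENT, PARTIAL, PRESENT, LocusSegment


def test_fz_run_is_one_segment_with_z_count(registry):
    seg = segment_loci("FZGHCIJKL", registry)
    assert len(seg.segments) == 1
    s = seg.segments[0]
    assert s.gene_call == "FZGHCIJKL" and s.z_count == 1
    assert s.locus_label in ("2DL2L3", "2DS3S5", "2DS3S4S5")


def test_empty_motif_empty_segmentation(registry):
    seg = segment_loci("", registry)
    assert seg.segments == [] and seg.unmatched == []


def test_empty_registry_rejected():
    with pytest.raises(DomainError):
        segment_loci("ABC", [])


def test_example_haplotype_segmentation_matches_exhaustive_oracle(registry):
    seg = segment_loci(EXAMPLE_KP420440_MOTIF, registry)
    seg.check_partition()
    got = [(s.sym_start, s.sym_end, s.rank, s.locus_label) for s in seg.segments]
    cov, best = segmentations_exhaustive(EXAMPLE_KP420440_MOTIF, registry)
    assert sum(e - s for s, e, _, _ in got) == cov  # greedy achieves max coverage
    # preferred tiling: max coverage, lexicographically smallest rank walk
    preferred = min(best, key=lambda segs: [(s[0], s[2]) for s in segs])
    assert got == preferred
    # the example tiles completely into 14 of the 15 canonical loci
    assert cov == len(EXAMPLE_KP420440_MOTIF)
    assert [s.locus_label for s in seg.segments] == [
        "3DL3", "2DL2L3", "2DL5cen", "2DS3S5", "2DP1", "2DL1", "3DP1",
        "3DP1-2DL4", "2DL4", "3DL1S1", "2DL5tel", "2DS3S4S5", "2DS1", "3DL2"]


def test_unmatched_symbols_reported_not_dropped(registry):
    seg = segment_loci("MHCIJKLQQQFPCNOJQ".replace("QQQ", "KKK"), registry)
    seg.check_partition()
    assert seg.unmatched, "junk symbols must be reported"
    total = sum(e - s for s, e in seg.unmatched) + \
        sum(s.sym_end - s.sym_start for s in seg.segments)
    assert total == len("MHCIJKLKKKFPCNOJQ")


def test_partial_terminal_segment_flagged(registry):
    # haplotype truncated inside the final locus
    seg = segment_loci(EXAMPLE_KP420440_MOTIF[:-4], registry)
    last = seg.segments[-1]
    assert last.partial and last.locus_label == "3DL2"


def test_z_count_conservation(registry):
    motif = "MHCIJKLFZZGHCIJKLAIRLFZGHCIJKL"
    seg = segment_loci(motif, registry)
    assert sum(s.z_count for s in seg.segments) == motif.count("Z")


@pytest.mark.parametrize("z,expected", [(1, "2DS3"), (2, "2DS5"), (3, "2DS5"),
                                        (0, "indeterminate"),
                                        (5, "indeterminate")])
def test_z_allele_hint(z, expected):
    seg = LocusSegment("2DS3S4S5", 13, "F" + "Z" * z + "GHCIJKL", 0, 9 + z,
                       z_count=z, gene_call="FZGHCIJKL")
    assert z_allele_hint(seg) == expected


def test_z_allele_hint_rejects_non_z_locus():
    seg = LocusSegment("2DL4", 10, "YKL", 0, 3, z_count=0, gene_call="2DL4")
    with pytest.raises(DomainError):
        z_allele_hint(seg)


def test_registry_has_14_genic_loci_in_9_motif_classes(registry):
    assert len(genic_loci(registry)) == 14
    assert len(gene_motif_classes(registry)) == 9


def test_presence_vector_full_and_empty(lib, registry):
    chunks = lib.motif_chunks("cB01~tB01")
    seg = segment_loci("".join(m for _, m in chunks), registry)
    vec = presence_vector(seg, registry)
    assert all(v == PRESENT for v in vec.states.values())
    empty = presence_vector(segment_loci("", registry), registry)
    assert all(v == ABSENT for v in empty.states.values())


def test_fusion_called_without_2ds4_and_not_with_it(lib, registry):
    # fusion-compatible motif, no 2DS4-compatible segment -> fusion
    seg = segment_loci("YKLSCNOJQ", registry)
    vec = presence_vector(seg, registry)
    fc = resolve_fusion(vec, seg)
    assert fc.call == "3DL1/3DL2-fusion"
    assert vec["3DL2"] == PARTIAL
    # same motif but with a 2DS4-compatible (zero-Z) segment -> plain 3DL2
    seg2 = segment_loci("YKLFGHCIJKLSCNOJQ", registry)
    # FGHCIJKL after 2DL4 is the telomeric 2DS3S4S5 locus with z=0
    vec2 = presence_vector(seg2, registry)
    fc2 = resolve_fusion(vec2, seg2)
    assert fc2.call == "3DL2"
    assert vec2["3DL2"] == PRESENT


def test_fusion_no_3dl2_segment_warns(registry):
    seg = segment_loci("YKL", registry)
    vec = presence_vector(seg, registry)
    fc = resolve_fusion(vec, seg)
    assert fc.call is None and fc.warning


def test_plain_3dl2_untouched_when_3dl1s1_present(lib, registry):
    chunks = lib.motif_chunks("cA01~tA01")
    seg = segment_loci("".join(m for _, m in chunks), registry)
    vec = presence_vector(seg, registry)
    fc = resolve_fusion(vec, seg)
    assert fc.call == "3DL2" and vec["3DL2"] == PRESENT


def test_name_structure_exact_and_novel(definitions, registry, lib):
    chunks = lib.motif_chunks("cA01~tA01")
    seg = segment_loci("".join(m for _, m in chunks), registry)
    vec = presence_vector(seg, registry)
    resolve_fusion(vec, seg)
    name, nearest = name_structure(vec, definitions)
    assert name == "cA01~tA01" and nearest == []

    empty = presence_vector(segment_loci("", registry), registry)
    name, nearest = name_structure(empty, definitions)
    assert name == "novel"
    assert nearest and all(isinstance(d, int) for _, d in nearest)
    assert nearest == sorted(nearest)


def test_all_shipped_structure_vectors_distinct(definitions, registry):
    loci = genic_loci(registry)
    vecs = {d.vector(loci) for d in definitions}
    assert len(vecs) == len(definitions) == 13


def test_duplicate_definitions_rejected(definitions, registry, lib):
    dup = definitions + [StructureDefinition("copy", definitions[0].states)]
    vec = PresenceVector(loci=genic_loci(registry),
                         states={l: ABSENT for l in genic_loci(registry)})
    with pytest.raises(RegistryError):
        name_structure(vec, dup)
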