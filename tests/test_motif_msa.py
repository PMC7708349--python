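"""Generic-alphabet alignment: pairwise optima, progressive MSA, NJ tree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendropy
from helpers import affine_score_oracle, enumerate_alignments_score
from kirmotif import (AnchorConstraint, MotifString, SymbolScoring,
                      motif_distance_matrix, neighbor_joining, pairwise_align,
                      progressive_msa)
from kirmotif.errors import AnchorError, DomainError
from kirmotif.motif_msa import MotifMSA


def M(sid, s):
    return MotifString(seq_id=sid, symbols=s)


# ---------------------------------------------------------------------------
# pairwise
# ---------------------------------------------------------------------------

def test_identity_alignment_score():
    scoring = SymbolScoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
    (ra, rb), score = pairwise_align("CIJ", "CIJ", scoring)
    assert (ra, rb) == ("CIJ", "CIJ") and score == 3


def test_empty_vs_two_symbols_forced_gaps():
    scoring = SymbolScoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
    (ra, rb), score = pairwise_align("", "AB", scoring)
    assert (ra, rb) == ("--", "AB")
    assert score == scoring.gap_open + 2 * scoring.gap_extend


def test_cijkl_cirl_matches_enumeration():
    scoring = SymbolScoring()
    _, score = pairwise_align("CIJKL", "CIRL", scoring)
    exp = enumerate_alignments_score("CIJKL", "CIRL", scoring.match,
                                     scoring.mismatch, scoring.gap_open,
                                     scoring.gap_extend)
    assert score == pytest.approx(exp)


def test_gap_in_input_rejected():
    with pytest.raises(DomainError):
        pairwise_align("A-B", "AB")


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.text(alphabet="ABCD", max_size=8), st.text(alphabet="ABCD", max_size=8))
def test_pairwise_score_equals_recursive_oracle(a, b):
    scoring = SymbolScoring()
    _, score = pairwise_align(a, b, scoring)
    exp = affine_score_oracle(a, b, scoring.match, scoring.mismatch,
                              scoring.gap_open, scoring.gap_extend)
    if a == "" and b == "":
        exp = 0.0
    assert score == pytest.approx(exp)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.text(alphabet="AB", min_size=1, max_size=5),
       st.text(alphabet="AB", min_size=1, max_size=5))
def test_pairwise_score_equals_full_enumeration(a, b):
    scoring = SymbolScoring()
    _, score = pairwise_align(a, b, scoring)
    exp = enumerate_alignments_score(a, b, scoring.match, scoring.mismatch,
                                     scoring.gap_open, scoring.gap_extend)
    assert score == pytest.approx(exp)


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def test_three_identical_rows_align_gapless():
    msa = progressive_msa([M("a", "CIJKL"), M("b", "CIJKL"), M("c", "CIJKL")])
    assert msa.rows == ["CIJKL"] * 3


def test_three_way_alignment_single_gap_column():
    msa = progressive_msa([M("a", "CIJKL"), M("b", "CIJKL"), M("c", "CIRL")])
    assert msa.rows[0] == msa.rows[1] == "CIJKL"
    assert msa.n_columns == 5
    assert msa.rows[2].count("-") == 1
    assert msa.degapped(2) == "CIRL"


def test_degap_round_trip_and_width_bounds(lib):
    strings = ["MHCIJKL", "MHCIJKLFGHCIJKL", "MHCIRL", "SCNOJKL", "MHCIJKL"]
    motifs = [M(f"s{i}", s) for i, s in enumerate(strings)]
    msa = progressive_msa(motifs)
    for i, s in enumerate(strings):
        assert msa.degapped(i) == s
    assert max(map(len, strings)) <= msa.n_columns <= sum(map(len, strings))


def test_anchor_constraint_joins_final_symbols():
    a, b = M("a", "KKQ"), M("b", "LLLQ")
    msa = progressive_msa(
        [a, b], anchors=[AnchorConstraint(members=[("a", 2), ("b", 3)])])
    col_a = max(i for i, c in enumerate(msa.rows[0]) if c != "-")
    col_b = max(i for i, c in enumerate(msa.rows[1]) if c != "-")
    assert col_a == col_b
    assert msa.rows[0][col_a] == "Q" and msa.rows[1][col_b] == "Q"


def test_infeasible_anchor_ordering_rejected_before_alignment():
    a, b = M("a", "ABCD"), M("b", "ABCD")
    anchors = [AnchorConstraint(members=[("a", 3), ("b", 0)]),
               AnchorConstraint(members=[("a", 1), ("b", 2)])]
    with pytest.raises(AnchorError):
        progressive_msa([a, b], anchors=anchors)


def test_msa_needs_two_rows():
    with pytest.raises(DomainError):
        progressive_msa([M("a", "ABC")])


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

def test_distance_identical_rows_zero():
    msa = MotifMSA(ids=["a", "b"], rows=["AB-", "AB-"])
    _, D = motif_distance_matrix(msa)
    assert D[0, 1] == 0


def test_distance_hand_enumeration():
    # columns: (A,A) same, (B,-) diff, (-,C) diff -> 2/3
    msa = MotifMSA(ids=["a", "b"], rows=["AB-", "A-C"])
    _, D = motif_distance_matrix(msa)
    assert D[0, 1] == pytest.approx(2 / 3)


def test_distance_matrix_symmetry_random():
    rng = np.random.default_rng(5)
    rows = ["".join(rng.choice(list("ABC-"), 12)) for _ in range(6)]
    msa = MotifMSA(ids=[f"r{i}" for i in range(6)], rows=rows)
    _, D = motif_distance_matrix(msa)
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
    assert (D >= 0).all() and (D <= 1).all()


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _patristic(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


def test_nj_two_taxa_branches_sum_to_distance():
    nwk = neighbor_joining(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
    dist = _patristic(nwk)
    assert dist("a", "b") == pytest.approx(0.4)


def additive_matrix(tree_newick, labels):
    t = dendropy.Tree.get(data=tree_newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return D


def test_nj_recovers_additive_four_taxon_metric():
    source = "((a:1,b:2):1.5,(c:0.5,d:3):1);"
    labels = ["a", "b", "c", "d"]
    D = additive_matrix(source, labels)
    nwk = neighbor_joining(D, labels)
    dist = _patristic(nwk)
    for i in range(4):
        for j in range(i + 1, 4):
            assert dist(labels[i], labels[j]) == pytest.approx(D[i, j], abs=1e-9)


def test_nj_recovers_additive_five_taxon_topology_and_paths():
    source = "(((a:1,b:0.5):0.7,c:2):0.4,(d:1.2,e:0.3):0.9);"
    labels = ["a", "b", "c", "d", "e"]
    D = additive_matrix(source, labels)
    nwk = neighbor_joining(D, labels)
    dist = _patristic(nwk)
    for i in range(5):
        for j in range(i + 1, 5):
            assert dist(labels[i], labels[j]) == pytest.approx(D[i, j], abs=1e-9)
    # the recovered topology equals the source topology
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=source, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_nj_crosscheck_with_skbio():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(17)
    pts = rng.random((6, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = [f"t{i}" for i in range(6)]
    ours = neighbor_joining(D, labels)
    theirs = skbio_nj(DistanceMatrix(D, ids=labels))
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=str(theirs), schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_nj_duplicate_taxa_zero_length_pair():
    D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
    nwk = neighbor_joining(D, ["a", "a2", "b"])
    dist = _patristic(nwk)
    assert dist("a", "a2") == pytest.approx(0, abs=1e-12)


def test_nj_rejects_asymmetric_input():
    with pytest.raises(DomainError):
        neighbor_joining(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])
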