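# Methods

## Anchor placement

Probes are placed by unit-cost edit distance (substitution = 1, each gap
position = 1), end-to-end over the full probe, on both strands, with
all-hits semantics: a semi-global dynamic program produces the best cost
for every possible end position, qualifying ends (cost ≤ `max_cost`) are
clustered — ends within half a probe length of one another describe the
same placement shifted by edits — and each cluster reports its
minimum-cost placement (earliest end on ties). The start is recovered by
the reverse dynamic program on a bounded window. `max_cost` defaults to 8
per 120 bp probe and scales conceptually with probe length (the test
world's 40 bp probes use 5); the value is deliberately loose because the
probes are designed to be mutually distant anchors, not discriminative
primers. `N` in either sequence always counts as a mismatch.

Overlapping placements then compete: hits are admitted in order of
(cost, probe id, start) and an admitted hit excludes any later hit whose
overlap exceeds half the shorter hit's length. If the surviving hits are
majority-minus the haplotype is reverse-complemented and re-annotated, so
downstream coordinates always refer to the plus orientation. All machine
coordinates are 0-based half-open; only console summaries are 1-based.

## Pair alphabet

The registry maps ordered probe-id pairs to single printable symbols
(everything except `-`, `.` and whitespace is admissible). Only four
mappings are fixed by convention — (4,3)→`C`, (3,12)→`I`, (12,10)→`J` and
the repeat pair (1,1)→`Z` — so the shipped alphabet is a data file: the 19
further assignments complete a consistent "probe walk" for the canonical
cassette world and can be replaced wholesale. Novel pairs observed in new
probe sets draw symbols deterministically from a reserve pool in
first-observed order. Repeat pairs need no special machinery at encoding
time (every consecutive pair emits one symbol, so a run of *n* probe-1
anchors emits *n−1* `Z`s); the flag only marks which symbol the Z-count
allele hints read.

Every symbol spans from the start of its left anchor to the end of its
right anchor; consecutive symbols share the middle anchor. This sharing is
what later lets locus boundaries be cut at anchor edges.

## Motif alignment

The motif alphabet has no substitution structure, so scoring is identity
based: match +2, mismatch −3, gap open −4, gap extend −1 (a gap run of
length *k* costs `open + k·extend`). The penalties make a single-symbol
indel — a gene presence/absence difference — cheaper than aligning
unrelated motifs. Pairwise alignment is exact Gotoh with deterministic
tie-breaking (diagonal, then gap in the second sequence, then gap in the
first); the test suite checks its optima against an independently written
recursive oracle and, on short strings, against full enumeration of all
alignments.

The progressive stage builds a UPGMA guide tree from normalized pairwise
alignment distances (1 − identical columns / alignment length) and merges
profiles leaf-to-root with average-of-pairs column scores over symbol
frequencies; column pairs involving a gap contribute zero and gap
penalties are applied per profile column. Any reasonable guide would do —
determinism is the binding requirement, and all choices here (scipy
average linkage, lower-input-index-first merge orientation) are
deterministic.

Anchor constraints replace interactive curation: a constraint file lists
groups of (sequence, symbol index) that must share one alignment column.
Feasibility (strictly increasing anchored indices per row across groups)
is checked before any alignment; during profile merges, column pairs whose
anchor-mark sets intersect receive a large bonus, which forces the match
at the merge where the marked profiles meet, and the final alignment is
verified to honor every group.

The motif distance matrix counts the proportion of differing columns per
row pair, treating symbol-vs-gap as a difference and skipping gap-vs-gap
columns; pairs with no co-scorable columns get distance 1. Neighbor
joining is implemented in-package because its determinism rules are part
of the contract: minimal-Q joins with ties broken by the lexicographically
smallest label pair, and negative branch lengths clamped to zero with the
deficit moved to the sister branch (tests cross-check topologies against
scikit-bio's implementation).

## Locus model

Loci are matched greedily left to right in canonical 5'→3' rank order,
each locus optional and usable once. Patterns are small regular
expressions over the motif alphabet (literals, character classes, postfix
`+ * ?`); at each position the longest available match wins, ties going to
the lowest rank, and unmatched symbols are reported rather than dropped.
A locus may carry alternative pattern rows — the shipped registry uses one
for the 3DL1-proximal variant of the 3DL2 motif carried by 3DL1/3DL2
fusion alleles. A pattern truncated by the end of the string after at
least two symbols yields a terminal segment flagged `partial`
(incomplete-3'-end haplotypes), not an error.

Because the shared-motif families (MHCIJ…, FIRL, FZ\*GHCIJKL) occur at
several loci, identity of a segment is positional: rank context relative
to already-matched flanking loci. Where the printed family description
leaves a choice — the MHCIJ core versus the full MHCIJKL with its flank —
the registry writes the full literal, since every observed occurrence
carries the `KL` flank; both the patterns and the structure definitions
are replaceable TSV data files, not code.

Fusion resolution: a 3DL2 segment matched through the 3DL1-proximal
variant (or accompanied by a merely partial 3DL1S1) is fusion-compatible;
it is called `3DL1/3DL2-fusion` only when the 2DS3S4S5 locus carries no
2DS4-compatible segment (Z-count outside 1–3), because haplotypes with
2DS4 cannot carry the fusion. A fusion call flags the 3DL2 cell `partial`
in the presence vector, mirroring how fusion cells are drawn in structure
schematics.

Structure naming is exact vector matching over the 14 genic loci
(present/absent/partial); on no match the result is `novel` together with
the nearest definitions by Hamming distance, never a wrong confident name.
The 13 shipped structure definitions are authored to be mutually distinct
and self-consistent with the pattern registry and the cassette library; at
locus resolution some real-world region variants are indistinguishable, so
these vectors are a canonical approximation, not a transcription of any
external table.

Boundary convention: the anchor shared by two adjacent loci closes the
left locus. DNA extraction therefore cuts at the end of each locus's
opening anchor, the first locus extends to position 0 and the last to the
sequence end, and unmatched motif residues are absorbed into the preceding
locus — so the per-locus intervals tile every haplotype exactly and no
base is ever dropped.

## DNA alignment and concatenation

Each locus set is aligned with the same progressive machinery over the
DNA alphabet (match +2, mismatch −3, gap open −6, gap extend −1; generic
values, not a claim about any published parameterization); a
single-member set is its own block. An externally produced aligned block
can be substituted for any locus and is validated by degapping. Blocks are
concatenated in canonical rank order with all-gap rows for haplotypes
lacking a locus; the intergenic 3DP1–2DL4 block is a first-class block.
Two invariants are verified as hard failures, not warnings: total width
equals the sum of block widths, and every row degaps to its haplotype's
locus-ordered sequence (which, under the tiling convention above, is the
full haplotype).

## Synthetic worlds

The generator emulates exactly what the method consumes: per-locus
cassettes of anchor walks joined through a shared junction probe, with
random-DNA filler between anchors. Defaults mirror the canonical shape —
18 probes of 120 bp with a minimum pairwise edit distance of a quarter of
the probe length in both orientations, and mean inter-anchor spacing of
2.4 kb (drawn uniformly between 0.5× and 1.5× the mean). Z-carrying loci
get per-structure repeat counts (2DS3-like 1, 2DS5-like 2–3, 2DS4-like 0
or 4). Mutations are per-base SNVs and single-base indels at rates up to
5 %; in `anchor_safe` mode they touch only filler. One master seed
determines everything; per-haplotype seeds derive from a stable hash of
(master seed, sequence id), and truth files (structure name, motif string,
locus intervals, anchors) are always written beside the FASTA.

What the synthetic world does **not** model: KIR paralog homology between
filler regions, repeat elements, recombination, or allele-level sequence
variation. Passing round-trip tests therefore demonstrates the
correctness of the scaffolding, encoding, segmentation, naming and
alignment machinery — not robustness to paralogous probe cross-mapping on
real data, where the probes' empirical specificity does that work.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at probe length
40 bp, spacing 120 bp and `max_cost` 5 — chosen so a full run takes well
under a minute of alignment time per panel on one CPU while preserving
every structural feature (anchor sharing, Z runs, locus tiling). The
acceptance script's problem sizes are recorded in its JSON output under
`n`.

Known limitations:

* Greedy longest-match segmentation is exact for the shipped registry
  (verified against an exhaustive-search oracle on the published example
  motif) but is not a global optimizer for arbitrary user registries with
  heavily overlapping patterns.
* The motif distance treats symbol-vs-gap as a difference, so
  deletion-rich structures (e.g. the fusion telomere tA02, which lacks
  three loci) sit basally in the tree rather than inside their haplotype
  family; family-separation guarantees hold for panels of structurally
  complete haplotypes.
* The DNA aligner is quadratic per merge; it is intended for motif-defined
  locus blocks (kilobases), not whole haplotypes. For large real loci the
  external-aligner hook is the pragmatic route.
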