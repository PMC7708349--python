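# Canonical locus patterns over the motif alphabet, in 5'->3' rank order.
# 14 genic loci + the 3DP1-2DL4 intergenic block; 9 distinct gene-motif
# families cover the genic loci.  The MHCIJ family (2DL1/2DS1/2DS2) carries
# its KL flank as written context and is disambiguated from 3DL3 and from
# its sister loci purely by rank.  The 3DL1-proximal variant of 3DL2 is the
# motif of 3DL1/3DL2 fusion alleles (proximal 3DL1, distal 3DL2); it is
# resolved against plain 3DL2 by 2DS4 linkage downstream.
locus_label	rank	pattern	gene_family	variant
3DL3	1	MHCIJKL	3DL3	.
2DS2	2	MHCIJKL	MHCIJ	.
2DL2L3	3	FZ*GHCIJKL	FZGHCIJKL	.
2DL5cen	4	[FA]IRL	FIRL	.
2DS3S5	5	FZ+GHCIJKL	FZGHCIJKL	.
2DP1	6	MHCIRL	2DP1	.
2DL1	7	MHCIJKL	MHCIJ	.
3DP1	8	SC	3DP1	.
3DP1-2DL4	9	TUVWX	intergenic	.
2DL4	10	YKL	2DL4	.
3DL1S1	11	SCNOJKL	3DL1S1	.
2DL5tel	12	[FA]IRL	FIRL	.
2DS3S4S5	13	FZ*GHCIJKL	FZGHCIJKL	.
2DS1	14	MHCIJKL	MHCIJ	.
3DL2	15	FPCNOJQ	3DL2	.
3DL2	15	SCNOJQ	3DL2	3DL1-proximal
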