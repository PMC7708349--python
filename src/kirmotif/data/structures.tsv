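# Canonical haplotype structure definitions: informal centromeric~telomeric
# names with per-locus presence states over the 14 genic loci.  Loci not
# listed for a structure are absent.  "partial" marks fusion cells (the
# tA02 telomere carries the 3DL1/3DL2 fusion in place of 3DL1S1 + 2DS4 +
# 3DL2).  Vectors are authored to be mutually distinct and consistent with
# the shipped pattern registry and cassette library.
structure_name	locus_label	state
cA01~tA01	3DL3	present
cA01~tA01	2DL2L3	present
cA01~tA01	2DP1	present
cA01~tA01	2DL1	present
cA01~tA01	3DP1	present
cA01~tA01	2DL4	present
cA01~tA01	3DL1S1	present
cA01~tA01	2DS3S4S5	present
cA01~tA01	3DL2	present
cA01~tA02	3DL3	present
cA01~tA02	2DL2L3	present
cA01~tA02	2DP1	present
cA01~tA02	2DL1	present
cA01~tA02	3DP1	present
cA01~tA02	2DL4	present
cA01~tA02	3DL2	partial
cA01~tB01	3DL3	present
cA01~tB01	2DL2L3	present
cA01~tB01	2DP1	present
cA01~tB01	2DL1	present
cA01~tB01	3DP1	present
cA01~tB01	2DL4	present
cA01~tB01	3DL1S1	present
cA01~tB01	2DL5tel	present
cA01~tB01	2DS3S4S5	present
cA01~tB01	2DS1	present
cA01~tB01	3DL2	present
cA02~tA03	3DL3	present
cA02~tA03	2DL2L3	present
cA02~tA03	2DP1	present
cA02~tA03	3DP1	present
cA02~tA03	2DL4	present
cA02~tA03	3DL2	present
cA03~tB02	3DL3	present
cA03~tB02	2DL2L3	present
cA03~tB02	2DL5cen	present
cA03~tB02	2DP1	present
cA03~tB02	2DL1	present
cA03~tB02	3DP1	present
cA03~tB02	2DL4	present
cA03~tB02	3DL1S1	present
cA03~tB02	2DL5tel	present
cA03~tB02	2DS1	present
cA03~tB02	3DL2	present
cB01~tA01	3DL3	present
cB01~tA01	2DS2	present
cB01~tA01	2DL2L3	present
cB01~tA01	2DL5cen	present
cB01~tA01	2DS3S5	present
cB01~tA01	2DP1	present
cB01~tA01	2DL1	present
cB01~tA01	3DP1	present
cB01~tA01	2DL4	present
cB01~tA01	3DL1S1	present
cB01~tA01	2DS3S4S5	present
cB01~tA01	3DL2	present
cB01~tB01	3DL3	present
cB01~tB01	2DS2	present
cB01~tB01	2DL2L3	present
cB01~tB01	2DL5cen	present
cB01~tB01	2DS3S5	present
cB01~tB01	2DP1	present
cB01~tB01	2DL1	present
cB01~tB01	3DP1	present
cB01~tB01	2DL4	present
cB01~tB01	3DL1S1	present
cB01~tB01	2DL5tel	present
cB01~tB01	2DS3S4S5	present
cB01~tB01	2DS1	present
cB01~tB01	3DL2	present
cB02~tA01	3DL3	present
cB02~tA01	2DS2	present
cB02~tA01	2DL2L3	present
cB02~tA01	2DP1	present
cB02~tA01	2DL1	present
cB02~tA01	3DP1	present
cB02~tA01	2DL4	present
cB02~tA01	3DL1S1	present
cB02~tA01	2DS3S4S5	present
cB02~tA01	3DL2	present
cB02~tB01	3DL3	present
cB02~tB01	2DS2	present
cB02~tB01	2DL2L3	present
cB02~tB01	2DP1	present
cB02~tB01	2DL1	present
cB02~tB01	3DP1	present
cB02~tB01	2DL4	present
cB02~tB01	3DL1S1	present
cB02~tB01	2DL5tel	present
cB02~tB01	2DS3S4S5	present
cB02~tB01	2DS1	present
cB02~tB01	3DL2	present
cB03~tA01	3DL3	present
cB03~tA01	2DS2	present
cB03~tA01	2DL2L3	present
cB03~tA01	3DP1	present
cB03~tA01	2DL4	present
cB03~tA01	3DL1S1	present
cB03~tA01	2DS3S4S5	present
cB03~tA01	3DL2	present
cB04~tB03	3DL3	present
cB04~tB03	2DS2	present
cB04~tB03	2DL2L3	present
cB04~tB03	2DL5cen	present
cB04~tB03	2DS3S5	present
cB04~tB03	3DP1	present
cB04~tB03	2DL4	present
cB04~tB03	2DL5tel	present
cB04~tB03	2DS3S4S5	present
cB04~tB03	2DS1	present
cB04~tB03	3DL2	present
cB05~tA01	3DL3	present
cB05~tA01	2DS2	present
cB05~tA01	2DL5cen	present
cB05~tA01	2DS3S5	present
cB05~tA01	2DP1	present
cB05~tA01	2DL1	present
cB05~tA01	3DP1	present
cB05~tA01	2DL4	present
cB05~tA01	3DL1S1	present
cB05~tA01	2DS3S4S5	present
cB05~tA01	3DL2	present
cB05~tB01	3DL3	present
cB05~tB01	2DS2	present
cB05~tB01	2DL5cen	present
cB05~tB01	2DS3S5	present
cB05~tB01	2DP1	present
cB05~tB01	2DL1	present
cB05~tB01	3DP1	present
cB05~tB01	2DL4	present
cB05~tB01	3DL1S1	present
cB05~tB01	2DL5tel	present
cB05~tB01	2DS3S4S5	present
cB05~tB01	2DS1	present
cB05~tB01	3DL2	present
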