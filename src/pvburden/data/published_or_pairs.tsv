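# Published gene-specific odds ratios (95% CI) for pathogenic-variant carrier
# status across cancer types, no-family-history design, from a nationwide
# Japanese biobank case-control study of the two hereditary breast/ovarian
# cancer genes.  Only cancers with estimates for both genes are listed.
# printed_i2: the I^2 (%) column as published, for cross-reference.
cancer	gene	or	lo	hi	printed_i2
breast_female	BRCA1	16.1	7.1	36.7	0.0
breast_female	BRCA2	10.9	7.0	17.1	0.0
colorectal	BRCA1	1.9	0.8	4.5	28.9
colorectal	BRCA2	1.0	0.5	1.9	28.9
gastric	BRCA1	5.2	2.6	10.5	0
gastric	BRCA2	4.7	3.1	7.1	0
lung	BRCA1	3.7	1.6	8.8	48.6
lung	BRCA2	1.7	0.9	3.3	48.6
lymphoma	BRCA1	7.7	2.6	22.4	76.0
lymphoma	BRCA2	1.2	0.3	5.0	76.0
ovarian	BRCA1	75.6	31.6	180.6	90.9
ovarian	BRCA2	11.3	5.6	23.0	90.9
pancreatic	BRCA1	12.6	3.7	42.8	0
pancreatic	BRCA2	10.7	5.1	22.6	0
prostate	BRCA1	1.1	0.3	3.4	77.4
prostate	BRCA2	4.0	2.5	6.5	77.4
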