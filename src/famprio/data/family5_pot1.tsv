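chrom	pos	ref	alt	qual	filter_pass	gene	consequence	maf_1kg	maf_exac_nontcga	cadd_phred	gerp	phastcons	phylop	SIFT	Polyphen2_HDIV	Polyphen2_HVAR	LRT	MutationTaster	MutationAssessor	FATHMM	MetaSVM	MetaLR	PROVEAN	gt_I-1	gt_II-1	gt_II-2	gt_II-3	gt_II-4	gt_II-5	gt_II-6	gt_II-7	gt_II-8	dp_I-1	dp_II-1	dp_II-2	dp_II-3	dp_II-4	dp_II-5	dp_II-6	dp_II-7	dp_II-8
7	124503601	C	A	200.0	1	POT1	missense	.	.	24.0	5.2	0.98	7.5	D	D	D	D	D	D	D	D	T	T	0	0	1	1	0	1	1	0	1	31	28	35	30	27	33	29	30	32
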