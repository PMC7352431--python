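FAM5	I-1	0	0	2	1	carrier	1
FAM5	I-2	0	0	1	0	unknown	0
FAM5	II-1	I-2	I-1	0	1	control	1
FAM5	II-2	I-2	I-1	0	2	case	1
FAM5	II-3	I-2	I-1	0	2	case	1
FAM5	II-4	I-2	I-1	0	1	carrier	1
FAM5	II-5	I-2	I-1	0	2	case	1
FAM5	II-6	I-2	I-1	0	1	carrier	1
FAM5	II-7	I-2	I-1	0	1	control	1
FAM5	II-8	I-2	I-1	0	2	case	1
FAM5	II-9	I-2	I-1	0	2	case	0
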