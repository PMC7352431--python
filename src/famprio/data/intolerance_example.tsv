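gene	esp6500_pct	exac_pct	local_pct	pli	mis_z	note
POT1	12.0	9.5	14.0	0.92	2.10	synthetic illustrative values
EPYC	78.0	81.0	.	0.00	-0.40	synthetic illustrative values
SPOCK1	35.0	40.0	38.0	0.45	0.90	synthetic illustrative values
MYBPC1	55.0	49.0	60.0	0.02	0.10	synthetic illustrative values
ACSS3	62.0	58.0	.	0.01	-0.20	synthetic illustrative values
NRP1	20.0	18.0	25.0	0.85	1.50	synthetic illustrative values
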