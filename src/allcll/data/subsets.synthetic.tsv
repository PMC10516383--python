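# SYNTHETIC stereotyped-subset definitions for testing only.
# These motifs are NOT the published CLL subset definitions; supply a
# canonical definitions TSV for real analyses.
# version: synthetic-test-0.1
subset_id	v_genes	cdr3_length_aa	motif	max_mismatches
CLL#1	IGHV1-2,IGHV1-3,IGHV5-a	13	AR[DE]..GY.YW.DA	2
CLL#2	IGHV3-21	9	[AG]RD.NG.DI	1
CLL#8	IGHV4-34	19	ARG..TGS[WY]GW..F..YDW	3
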