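class	name	family	cdr1_aa	cdr2_aa	sequence	anchor_offset
V	TRBV1	TRBV1	MGHRA	VFLMVW	TGTGCCAGC
V	TRBV2	TRBV2	SGHNS	SNEGSK	TGTGCCAGT
V	TRBV3-1	TRBV3	SGDLS	YYNGEE	TGCGCCTCA
D	TRBD1				GGGACA
D	TRBD2				GGGACT
J	TRBJ1-1				GCTTTCTTT	3
J	TRBJ1-2				TACACCTTC	6
J	TRBJ2-1				GAGCAGTTCTTC	9
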