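class	name	family	cdr1_aa	cdr2_aa	sequence	anchor_offset
V	TRBV4-1	TRBV4	MGHRA	YFSYWV	TGTGCCAGCAGCCAA
V	TRBV4-2	TRBV4	MGHDK	YFVYWT	TGTGCCAGCAGCCAC
V	TRBV5-1	TRBV5	SGHRS	YFSETQ	TGCGCCAGCAGCTTG
V	TRBV6-5	TRBV6	MNHEY	SVGAGI	TGTGCCAGCAGTTAC
V	TRBV7-2	TRBV7	SGHNS	FNEGSQ	TGTGCCAGCAGCTTA
V	TRBV7-9	TRBV7	SGDLS	YNGEEQ	TGTGCCAGCAGTTTA
V	TRBV9	TRBV9	SGDLS	YYNGEE	TGTGCCAGCAGCGTA
V	TRBV10-3	TRBV10	ENHRY	SYGVKD	TGTGCCATCAGC
V	TRBV12-3	TRBV12	SGHAT	FQYNNK	TGTGCCAGCAGT
V	TRBV19	TRBV19	LNHDA	SQIVND	TGTGCCAGTTCT
V	TRBV20-1	TRBV20	DFQATT	SNEGSK	TGTAGCGCA
V	TRBV28	TRBV28	MDHEN	SYDVKM	TGTGCCAGCAGTCTC
V	TRBV29-1	TRBV29	MNHEY	SVGEGT	TGCAGTGTAGAG
D	TRBD1				GGGACAGGGGGC	
D	TRBD2				GGGACTAGCGGGGGG	
J	TRBJ1-1				AACACTGAAGCTTTCTTT	15
J	TRBJ1-2				AACTATGGCTACACCTTC	15
J	TRBJ2-1				AATGAGCAGTTCTTC	12
J	TRBJ2-3				ACAGATACGCAGTATTTT	15
J	TRBJ2-5				CAAGAGACCCAGTACTTC	15
J	TRBJ2-7				TCCTACGAGCAGTACTTC	15
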