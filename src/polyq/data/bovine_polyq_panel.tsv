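gene	tract	purity	alleles	p_taurus_vs_indicus	p_beef_vs_dairy	control
ABCF1	Q1	G1A1G9A1	3	NS	NS	0
C10ORF26	Q1	G8	1	-	-	0
CACNA1A	Q1	G6	3	<0.05	<0.01	0
CREBBP	Q1	G5A1G3A1G5	4	<0.001	NS	0
EXDL2	Q1	G9A1	3	<0.0001	NS	0
FAM155A	Q1	G10	6	<0.0001	NS	0
FAM48A	Q1	G1A1G6	3	<0.0001	NS	0
FXC1	Q1	G10A1	18	<0.0001	<0.001	0
HTT	Q1	G15	9	<0.0001	<0.01	0
LRCH4	Q1	G7	3	<0.0001	NS	0
MED12	Q1	G6A1G2A1G1A1G13A1G1N4G5	5	<0.01	NS	0
MED15	Q1	G6NG1NG3N3G10NG1NG2N3G3NG1N3G5NG4	3	<0.001	NS	0
MEF2A	Q1	G5	1	-	-	0
MLL3	Q1	G5A1	4	<0.0001	NS	0
NCOR1	Q1	G10	2	<0.0001	NS	0
RUNX2	Q1	G3A2G3A1G5A1G3A1G2	1	-	-	0
ST6GALNAC5	Q1	G7	3	<0.0001	NS	0
TBP	Q1	G5A1G13	4	<0.0001	NS	0
THAP11	Q1	G5A1G4A1G1A1G5	5	<0.05	NS	0
AR	Q1	G3A1G4	1	-	-	1
AR	Q2	G3A1G4	1	-	-	1
NFYA	Q1	G3	1	-	-	1
NFYA	Q2	G2	1	-	-	1
ODAM	Q1	A1G4	1	-	-	1
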