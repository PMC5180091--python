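symbol	role	cds_length_aa	percentile_in_genome
KMT2D	TSG	5537	99.9
KMT2C	TSG	4911	99.8
FAT1	TSG	4588	99.7
CSMD1	TSG	3565	99.5
BRCA2	TSG	3418	99.4
ATM	TSG	3056	99.2
APC	TSG	2843	99.1
NF1	TSG	2839	99.1
SETD2	TSG	2564	98.8
NOTCH1	TSG	2555	98.8
CIC	TSG	2514	98.7
ATRX	TSG	2492	98.7
NOTCH2	TSG	2471	98.6
CREBBP	TSG	2442	98.6
NCOR1	TSG	2440	98.6
EP300	TSG	2414	98.5
ARID1A	TSG	2285	98.3
ARID1B	TSG	2236	98.2
MED12	OG	2177	98.1
TET2	TSG	2023	97.7
BRCA1	TSG	1884	97.2
ARID2	TSG	1835	97.0
TSC2	TSG	1807	96.9
BCOR	TSG	1755	96.6
PBRM1	TSG	1689	96.2
SMARCA4	TSG	1681	96.2
DNMT1	OG	1678	96.2
ALK	OG	1620	95.9
SETBP1	OG	1596	95.8
KDM5C	TSG	1560	95.6
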