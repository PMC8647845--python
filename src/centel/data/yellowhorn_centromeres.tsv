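# Published centromere regions and karyotype summary for the yellowhorn
# (Xanthoceras sorbifolium) "JGXP" chromosome-level assembly (15 chromosomes,
# 470 Mb). Columns: chromosome, Hi-C predicted centromere point (bp),
# centromeric region start/end (bp, 1-based inclusive, 100-kb resolution),
# region size (Mb), arm ratio r (long arm / short arm), karyotype term
# (m metacentric, sm submetacentric, st subtelocentric).
# The Chr15 end coordinate is 6,200,000 (a typographical digit grouping in the
# printed source is resolved by the printed 2.5 Mb size).
chrom	point_bp	start	end	size_mb	arm_ratio	term
Chr01	11336700	10700001	12100000	1.4	2.36	sm
Chr02	18486900	17600001	19200000	1.6	1.02	m
Chr03	14643700	13500001	15200000	1.7	1.40	m
Chr04	13374100	12500001	13900000	1.4	1.55	m
Chr05	17994100	16700001	18600000	1.9	1.24	m
Chr06	20311600	19900001	20900000	1.0	1.70	m
Chr07	17351700	17300001	18000000	0.7	1.29	m
Chr08	13037700	11800001	14000000	2.2	1.28	m
Chr09	12381000	11600001	13300000	1.7	1.34	m
Chr10	16802400	16200001	17700000	1.5	1.48	m
Chr11	11513900	11000001	11900000	0.9	1.39	m
Chr12	20460700	19500001	22000000	2.5	3.22	st
Chr13	20418300	20100001	21000000	0.9	3.26	st
Chr14	11055000	10500001	11600000	1.1	1.30	m
Chr15	5226800	3700001	6200000	2.5	2.67	sm
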