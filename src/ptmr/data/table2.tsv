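gene	chrom	plasma_z	plasma_p_fdr	plasma_pph4	blood_z	blood_p_fdr	blood_pph4	breast_z	breast_p_fdr	breast_pph4	score	power
PGD	1	-9.152	7.39E-17	0.994							2	Weak
TLR1	4	6.225	3.18E-07	1							2	Weak
FBLN5	14	5.226	7.60E-05	0	0.460	0.6460	0				1	Weak
PEX14	1	4.839	0.0004	0.989	6.843	1.09E-10	0.195	5.341	8.14E-07	0.79	5	Strong
LAYN	11	4.499	0.0018	0.936							2	Weak
SNUPN	15	-4.413	0.0022	0.952	-5.285	8.82E-07	0.939	-5.256	8.14E-07	0.372	5	Strong
GSTM4	1	-4.273	0.0036	0.618	-3.451	0.0011	0.001	-3.736	0.0004	0.175	3	Moderate
MST1	3	4.194	0.0045	0.904	-2.547	0.0139	0.148	-3.266	0.0015	0.584	4	Moderate (inconsistent)
CSK	15	-4.147	0.0049	0.779	-3.979	0.0002	0.843	-4.613	1.46E-05	0.863	6	Strong
NTN4	12	3.938	0.0108	0							1	Weak
PAPPA	9	-3.692	0.0255	0.137							1	Weak
CTSF	11	3.681	0.0255	0.777	2.895	0.0059	0.944	4.394	0.0000	0.939	6	Strong
PARK7	1	-3.648	0.0269	0.978	-4.644	1.20E-05	0.965	-2.391	0.0185	0.014	5	Strong
NCF1	7	3.601	0.0296	0.002	4.419	2.78E-05	0.958				3	Moderate
COL6A3	2	-3.585	0.0296	0.026							1	Weak
RSPO3	6	-3.541	0.0319	0.272							1	Weak
HEBP1	12	3.533	0.0319	0.058	2.358	0.0215	0.015				2	Weak
NRP1	10	-3.508	0.0328	0.038							1	Weak
ABO	9	-3.442	0.0369	0.298	-4.953	3.41E-06	0.169	2.127	0.0334	0.994	4	Moderate
PRDX1	1	3.436	0.0369	0.004	1.993	0.0498	0.005	3.392	0.0011	0.03	3	Moderate
EMILIN3	20	3.410	0.0369	0.072							1	Weak
ANXA4	2	3.404	0.0369	0.681	2.820	0.0067	0.008				2	Weak
POSTN	13	3.401	0.0369	0.01							1	Weak
LDHA	11	-3.352	0.0424	0.404	-3.307	0.0016	0.416	-3.625	0.0005	0.291	3	Moderate
UROD	1	3.302	0.0487	0.254				2.834	0.0056	0.113	2	Weak
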