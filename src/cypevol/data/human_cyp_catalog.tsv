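# Human cytochrome P450 gene catalog (Hosa).
# 57 functional genes (35 detoxification/D-type, 22 biosynthesis/B-type),
# 17 pseudogenes with an identified originating functional gene, and 2
# unattributed CYP3A-cluster pseudogenes.  Family counts (functional):
# CYP1=3, CYP2=16, CYP3=4, CYP4=12.  Cluster sizes: 2-19q=12, 2C-10q=4,
# 3A-7q=6, 4-1p=6, 4F-19p=7.  Cluster membership and pseudogene parents
# are approximate where the primary literature does not itemize them.
# Note: an alternative tabulation lists only 15 functional CYP2 genes (34
# D-type); this catalog follows the 16-gene (35 D-type) count and includes
# CYP2A13.
name	species	family	subfamily	clan	cyp_type	status	cluster	parent_gene
CYP1A1	Hosa	1	1A	2	D	functional
CYP1A2	Hosa	1	1A	2	D	functional
CYP1B1	Hosa	1	1B	2	D	functional
CYP2A6	Hosa	2	2A	2	D	functional	2-19q
CYP2A7	Hosa	2	2A	2	D	functional	2-19q
CYP2A13	Hosa	2	2A	2	D	functional	2-19q
CYP2B6	Hosa	2	2B	2	D	functional	2-19q
CYP2C8	Hosa	2	2C	2	D	functional	2C-10q
CYP2C9	Hosa	2	2C	2	D	functional	2C-10q
CYP2C18	Hosa	2	2C	2	D	functional	2C-10q
CYP2C19	Hosa	2	2C	2	D	functional	2C-10q
CYP2D6	Hosa	2	2D	2	D	functional
CYP2E1	Hosa	2	2E	2	D	functional
CYP2F1	Hosa	2	2F	2	D	functional	2-19q
CYP2J2	Hosa	2	2J	2	D	functional
CYP2R1	Hosa	2	2R	2	D	functional
CYP2S1	Hosa	2	2S	2	D	functional	2-19q
CYP2U1	Hosa	2	2U	2	D	functional
CYP2W1	Hosa	2	2W	2	D	functional
CYP3A4	Hosa	3	3A	3	D	functional	3A-7q
CYP3A5	Hosa	3	3A	3	D	functional	3A-7q
CYP3A7	Hosa	3	3A	3	D	functional	3A-7q
CYP3A43	Hosa	3	3A	3	D	functional	3A-7q
CYP4A11	Hosa	4	4A	4	D	functional	4-1p
CYP4A20	Hosa	4	4A	4	D	functional	4-1p
CYP4A22	Hosa	4	4A	4	D	functional	4-1p
CYP4B1	Hosa	4	4B	4	D	functional	4-1p
CYP4F2	Hosa	4	4F	4	D	functional	4F-19p
CYP4F3	Hosa	4	4F	4	D	functional	4F-19p
CYP4F8	Hosa	4	4F	4	D	functional	4F-19p
CYP4F11	Hosa	4	4F	4	D	functional	4F-19p
CYP4F12	Hosa	4	4F	4	D	functional
CYP4F22	Hosa	4	4F	4	D	functional
CYP4V2	Hosa	4	4V	4	D	functional
CYP4X1	Hosa	4	4X	4	D	functional	4-1p
CYP5A1	Hosa	5	5A	3	B	functional
CYP7A1	Hosa	7	7A	7	B	functional
CYP7B1	Hosa	7	7B	7	B	functional
CYP8A1	Hosa	8	8A	7	B	functional
CYP8B1	Hosa	8	8B	7	B	functional
CYP11A1	Hosa	11	11A	mito	B	functional
CYP11B1	Hosa	11	11B	mito	B	functional
CYP11B2	Hosa	11	11B	mito	B	functional
CYP17A1	Hosa	17	17A	2	B	functional
CYP19A1	Hosa	19	19A	19	B	functional
CYP20A1	Hosa	20	20A	20	B	functional
CYP21A2	Hosa	21	21A	2	B	functional
CYP24A1	Hosa	24	24A	mito	B	functional
CYP26A1	Hosa	26	26A	26	B	functional
CYP26B1	Hosa	26	26B	26	B	functional
CYP26C1	Hosa	26	26C	26	B	functional
CYP27A1	Hosa	27	27A	mito	B	functional
CYP27B1	Hosa	27	27B	mito	B	functional
CYP27C1	Hosa	27	27C	mito	B	functional
CYP39A1	Hosa	39	39A	7	B	functional
CYP46A1	Hosa	46	46A	46	B	functional
CYP51A1	Hosa	51	51A	51	B	functional
CYP21A1P	Hosa	21	21A	2	B	pseudogene		CYP21A2
CYP51P1	Hosa	51	51A	51	B	pseudogene		CYP51A1
CYP51P2	Hosa	51	51A	51	B	pseudogene		CYP51A1
CYP1D1P	Hosa	1	1D	2	D	pseudogene		CYP1D1
CYP2A7P1	Hosa	2	2A	2	D	pseudogene	2-19q	CYP2A7
CYP2B7P1	Hosa	2	2B	2	D	pseudogene	2-19q	CYP2B6
CYP2D7P1	Hosa	2	2D	2	D	pseudogene		CYP2D6
CYP2D8P1	Hosa	2	2D	2	D	pseudogene		CYP2D6
CYP2F1P	Hosa	2	2F	2	D	pseudogene		CYP2F1
CYP2G1P	Hosa	2	2G	2	D	pseudogene	2-19q	CYP2G1
CYP2G2P	Hosa	2	2G	2	D	pseudogene	2-19q	CYP2G2
CYP2T2P	Hosa	2	2T	2	D	pseudogene	2-19q	CYP2T2
CYP2T3P	Hosa	2	2T	2	D	pseudogene	2-19q	CYP2T3
CYP4F9P	Hosa	4	4F	4	D	pseudogene	4F-19p	CYP4F9
CYP4F23P	Hosa	4	4F	4	D	pseudogene	4F-19p	CYP4F23
CYP4F24P	Hosa	4	4F	4	D	pseudogene	4F-19p	CYP4F24
CYP4Z2P	Hosa	4	4Z	4	D	pseudogene	4-1p	CYP4Z1
CYP3A5P1	Hosa	3	3A	3	D	pseudogene	3A-7q
CYP3A5P2	Hosa	3	3A	3	D	pseudogene	3A-7q
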