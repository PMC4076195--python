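# Biosynthesis-type (B-type) gene birth/death events on the 15-species
# vertebrate chronogram: 19 gains, 16 losses, 5 pseudogenizations.
# `branch` names the branch by the leaf set of its child clade (sorted,
# '+'-joined).  Placements follow the published lineage narrative where it
# is explicit (teleost and amniote lineage-specific duplications/deletions,
# primate CYP11B2 duplication, hominoid CYP51 pseudogene emergences);
# remaining placements are approximate fill-ins consistent with ortholog
# presence/absence and are marked approx=1.
branch	type	group	cyp_type	approx
Dare	gain	CYP8B2	B	0
Dare	gain	CYP8B3	B	0
Dare	gain	CYP17A1	B	0
Dare	gain	CYP27A1	B	0
Dare	gain	CYP46A1	B	0
Dare	gain	CYP21A2	B	1
Orla	gain	CYP46A1	B	0
Orla	gain	CYP19A1	B	1
Dare+Orla	gain	CYP19A1	B	0
Xetr	gain	CYP8B1	B	0
Xetr	gain	CYP27A1	B	0
Xetr	gain	CYP46A1	B	0
Xetr	gain	CYP24A1	B	1
Anca	gain	CYP24A1	B	0
Modo	gain	CYP8B1	B	0
Bota	gain	CYP17A1	B	1
Caja+Hosa+Mamu+Patr	gain	CYP11B2	B	0
Hosa+Patr	gain	CYP51P1	B	0
Hosa+Patr	gain	CYP51P2	B	0
Orla	loss	CYP7B1	B	0
Orla	loss	CYP11B1	B	0
Orla	loss	CYP39A1	B	0
Xetr	loss	CYP11B1	B	0
Anca	loss	CYP11A1	B	0
Anca	loss	CYP21A2	B	0
Anca	loss	CYP26A1	B	0
Anca	loss	CYP8A1	B	1
Gaga	loss	CYP27B1	B	0
Gaga	loss	CYP8A1	B	1
Gaga	loss	CYP24A1	B	1
Tagu	loss	CYP11B1	B	0
Tagu	loss	CYP21A2	B	0
Tagu	loss	CYP27A1	B	0
Modo	loss	CYP17A1	B	0
Modo	loss	CYP26B1	B	0
Hosa	pseudogenization	CYP21A1P	B	0
Hosa	pseudogenization	CYP51P1	B	0
Hosa	pseudogenization	CYP51P2	B	0
Patr	pseudogenization	CYP21A-ps	B	1
Mamu	pseudogenization	CYP51-ps	B	1
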