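reaction_id	pathway	reversible	equation
G1	G	0	GLC + ATP -> G6P + ADP
G2	G	1	G6P <-> F6P
G3	G	0	F6P + ATP -> FBP + ADP
G4	G	1	FBP <-> DHAP + G3P
G5	G	1	DHAP <-> G3P
G6	G	1	G3P + NAD + PI <-> BPG + NADH
G7	G	1	BPG + ADP <-> 3PG + ATP
G8	G	1	3PG <-> 2PG
G9	G	1	2PG <-> PEP
G10	G	0	PEP + ADP -> PYR + ATP
PYP	PYP	0	PYR + HSCOA + NAD -> ACCOA + NADH + CO2
TCA1	TCA	0	ACCOA + OAA -> CIT + HSCOA
TCA2	TCA	1	CIT <-> ACON
TCA3	TCA	1	ACON <-> ICIT
TCA4	TCA	1	ICIT + NAD <-> AKG + CO2 + NADH
TCA5	TCA	0	AKG + NAD + HSCOA -> SUCCOA + CO2 + NADH
TCA6	TCA	1	SUCCOA + ADP + PI <-> SUC + ATP + HSCOA
TCA7	TCA	1	SUC + FAD <-> FUM + FADH2
TCA8	TCA	1	FUM <-> MAL
TCA9	TCA	1	MAL + NAD <-> OAA + NADH
TCA10	TCA	1	OAA + GLU <-> ASP + AKG
PPP1	PPP	0	G6P + NADP -> 6PGL + NADPH
PPP2	PPP	0	6PGL -> 6PG
PPP3	PPP	0	6PG + NADP -> RU5P + CO2 + NADPH
PPP4	PPP	1	RU5P <-> R5P
PPP5	PPP	1	RU5P <-> X5P
PPP6	PPP	1	R5P + X5P <-> S7P + G3P
PPP7	PPP	1	S7P + G3P <-> E4P + F6P
PPP8	PPP	1	X5P + E4P <-> F6P + G3P
ETC1	ETC	0	NADH + Q + 4 HIN -> NAD + QH2 + 4 HOUT
ETC2	ETC	0	FADH2 + Q -> FAD + QH2
ETC3	ETC	0	QH2 + 2 CYTOX + 2 HIN -> Q + 2 CYTRED + 4 HOUT
ETC4	ETC	0	2 CYTRED + 0.5 O2 + 4 HIN -> 2 CYTOX + 2 HOUT
ETC5	ETC	0	ADP + PI + 3 HOUT -> ATP + 3 HIN
AP1	AP	0	PYR + CO2 + ATP -> OAA + ADP + PI
AP2	AP	1	PYR + GLU <-> ALA + AKG
LDH	LDH	1	PYR + NADH <-> LAC + NAD
GDH	GDH	0	GLN + NAD -> AKG + NH3 + NADH
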