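metabolite_id	name	role	measurable	etc_member
GLC	glucose	external	0	0
G6P	glucose-6-phosphate	internal	1	0
F6P	fructose-6-phosphate	internal	1	0
FBP	fructose-1,6-bisphosphate	internal	1	0
DHAP	dihydroxyacetone phosphate	internal	1	0
G3P	glyceraldehyde-3-phosphate	internal	1	0
BPG	1,3-bisphosphoglycerate	internal	0	0
3PG	3-phosphoglycerate	internal	1	0
2PG	2-phosphoglycerate	internal	1	0
PEP	phosphoenolpyruvate	internal	1	0
PYR	pyruvate	internal	1	0
LAC	lactate	external	1	0
6PGL	6-phosphogluconolactone	internal	0	0
6PG	6-phosphogluconate	internal	1	0
RU5P	ribulose-5-phosphate	internal	1	0
R5P	ribose-5-phosphate	internal	1	0
X5P	xylulose-5-phosphate	internal	1	0
S7P	sedoheptulose-7-phosphate	internal	1	0
E4P	erythrose-4-phosphate	internal	1	0
ACCOA	acetyl-CoA	internal	1	0
HSCOA	coenzyme A	external	1	0
CIT	citrate	internal	1	0
ACON	cis-aconitate	internal	1	0
ICIT	isocitrate	internal	1	0
AKG	alpha-ketoglutarate	internal	1	0
SUCCOA	succinyl-CoA	internal	1	0
SUC	succinate	internal	1	0
FUM	fumarate	internal	1	0
MAL	L-malate	internal	1	0
OAA	oxaloacetate	internal	1	0
ASP	aspartate	external	1	0
GLU	glutamate	external	1	0
GLN	glutamine	external	1	0
ALA	alanine	external	1	0
NAD	NAD+	internal	1	0
NADH	NADH	internal	1	0
NADP	NADP+	external	1	0
NADPH	NADPH	external	1	0
ATP	ATP	external	1	0
ADP	ADP	external	1	0
PI	inorganic phosphate	external	1	0
Q	ubiquinone (oxidized)	internal	0	1
QH2	ubiquinol (reduced)	internal	0	1
FAD	FAD (complex II flavin, oxidized)	internal	0	1
FADH2	FADH2 (complex II flavin, reduced)	internal	0	1
CYTOX	cytochrome c (oxidized)	internal	0	1
CYTRED	cytochrome c (reduced)	internal	0	1
HIN	matrix-side proton	internal	0	1
HOUT	intermembrane-space proton	internal	0	1
O2	molecular oxygen	external	0	0
CO2	carbon dioxide	external	0	0
NH3	ammonia	external	0	0
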