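raw_name	semi_unique_name	constituents	n_waters	molecular_weight	compound_class	category
NaCl	sodium chloride	Na+:1;Cl-:1	0	58.44	defined	
KCl	potassium chloride	K+:1;Cl-:1	0	74.55	defined	
CaCl2 x 2 H2O	calcium chloride	Ca2+:1;Cl-:2	2	147.01	defined	
CaCl2	calcium chloride	Ca2+:1;Cl-:2	0	110.98	defined	
MgCl2 x 6 H2O	magnesium chloride	Mg2+:1;Cl-:2	6	203.3	defined	
MgSO4 x 7 H2O	magnesium sulfate	Mg2+:1;SO4^2-:1	7	246.47	defined	
NH4Cl	ammonium chloride	NH4+:1;Cl-:1	0	53.49	defined	
(NH4)2SO4	ammonium sulfate	NH4+:2;SO4^2-:1	0	132.14	defined	
K2HPO4	dipotassium phosphate	K+:2;HPO4^2-:1	0	174.18	defined	
KH2PO4	monopotassium phosphate	K+:1;H2PO4-:1	0	136.09	defined	
NaHCO3	sodium bicarbonate	Na+:1;HCO3-:1	0	84.01	defined	
Na2S x 9 H2O	sodium sulfide	Na+:2;S2-:1	9	240.18	defined	
FeSO4 x 7 H2O	ferrous sulfate	Fe2+:1;SO4^2-:1	7	278.01	defined	
FeCl3 x 6 H2O	ferric chloride	Fe3+:1;Cl-:3	6	270.3	defined	
ZnSO4 x 7 H2O	zinc sulfate	Zn2+:1;SO4^2-:1	7	287.56	defined	
MnCl2 x 4 H2O	manganese chloride	Mn2+:1;Cl-:2	4	197.91	defined	
CoCl2 x 6 H2O	cobalt chloride	Co2+:1;Cl-:2	6	237.93	defined	
CuSO4 x 5 H2O	copper sulfate	Cu2+:1;SO4^2-:1	5	249.69	defined	
Na2MoO4 x 2 H2O	sodium molybdate	Na+:2;MoO4^2-:1	2	241.95	defined	
glucose	glucose	glucose:1	0	180.16	defined	
sucrose	sucrose	sucrose:1	0	342.3	defined	
lactose	lactose	lactose:1	0	342.3	defined	
xylose	xylose	xylose:1	0	150.13	defined	
glycerol	glycerol	glycerol:1	0	92.09	defined	
sodium acetate	sodium acetate	Na+:1;acetate:1	0	82.03	defined	
thiamine HCl	thiamine	thiamine:1	0	337.27	defined	
biotin	biotin	biotin:1	0	244.31	defined	
1,4-Naphthoquinone	1,4-Naphthoquinone	1,4-Naphthoquinone:1	0	158.15	other	
metabolite X	metabolite X	metabolite X:1	0	100.0	other	
peptone	peptone				complex	complex-meat
tryptone	tryptone				complex	complex-meat
meat extract	meat extract				complex	complex-meat
yeast extract	yeast extract				complex	complex-yeast
casamino acids	casamino acids				complex	complex-meat
malt extract	malt extract				complex	complex-plant
soytone	soytone				complex	complex-plant
xylan	xylan				complex	polysaccharide
starch	starch				complex	polysaccharide
sea salts	sea salts				complex	sea-salts
agar	agar				complex	agar
rumen fluid	rumen fluid				complex	complex-animal
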