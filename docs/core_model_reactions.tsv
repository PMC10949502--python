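id	name	equation	lb	ub	gene	subsystem	flags
EX_glc__D_e	D-glucose exchange	glc__D_e <=> 	-4.67	0		exchange	exchange
EX_o2_e	O2 exchange	o2_e <=> 	-1000	1000		exchange	exchange
EX_co2_e	CO2 exchange	co2_e -> 	0	1000		exchange	exchange
EX_nh4_e	NH4 exchange	nh4_e <=> 	-1000	1000		exchange	exchange
EX_pi_e	phosphate exchange	pi_e <=> 	-1000	1000		exchange	exchange
EX_h2o_e	water exchange	h2o_e <=> 	-1000	1000		exchange	exchange
EX_ac_e	acetate exchange	ac_e -> 	0	1000		exchange	exchange
EX_lac__L_e	L-lactate exchange	lac__L_e -> 	0	1000		exchange	exchange
EX_ala__L_e	L-alanine exchange	ala__L_e -> 	0	1000		exchange	exchange
EX_val__L_e	L-valine exchange	val__L_e -> 	0	1000		exchange	exchange
EX_leu__L_e	L-leucine exchange	leu__L_e -> 	0	1000		exchange	exchange
O2t	O2 diffusion	o2_e <=> o2	-1000	1000		transport	
CO2t	CO2 diffusion	co2 <=> co2_e	-1000	1000		transport	
NH4t	ammonium transport	nh4_e <=> nh4	-1000	1000		transport	
PIt	phosphate transport	pi_e <=> pi	-1000	1000		transport	
H2Ot	water diffusion	h2o <=> h2o_e	-1000	1000		transport	
ACt	acetate transport	ac <=> ac_e	-1000	1000		transport	
LACt	L-lactate export	lac__L -> lac__L_e	0	1000		transport	
ALAt	L-alanine export	ala__L -> ala__L_e	0	1000		transport	
VALt	L-valine export	val__L -> val__L_e	0	1000		transport	
LEUt	L-leucine export	leu__L -> leu__L_e	0	1000		transport	
PTS	glucose PTS uptake	glc__D_e + pep -> g6p + pyr	0	1000	ptsG	glycolysis	
GLCperm	PTS-independent glucose permease (IolT; PMF cost out of scope)	glc__D_e -> glc__D	0	1000	iolT1	glycolysis	
PPGK	polyphosphate glucokinase (poly-P pool out of scope)	glc__D + pi -> g6p	0	1000	ppgK	glycolysis	
PGI	glucose-6-phosphate isomerase	g6p <=> f6p	-1000	1000	pgi	glycolysis	
PFK	phosphofructokinase	atp + f6p -> adp + fdp	0	1000	pfkA	glycolysis	
FBP	fructose-1,6-bisphosphatase	fdp + h2o -> f6p + pi	0	1000	fbp	gluconeogenesis	
FBA	fructose-bisphosphate aldolase	fdp <=> dhap + g3p	-1000	1000	fba	glycolysis	
TPI	triose-phosphate isomerase	dhap <=> g3p	-1000	1000	tpi	glycolysis	
GAPD	glyceraldehyde-3-phosphate dehydrogenase	g3p + nad + pi <=> 13dpg + nadh	-1000	1000	gap	glycolysis	
PGK	phosphoglycerate kinase	13dpg + adp <=> 3pg + atp	-1000	1000	pgk	glycolysis	
PGM	phosphoglycerate mutase	3pg <=> 2pg	-1000	1000	pgm	glycolysis	
ENO	enolase	2pg <=> h2o + pep	-1000	1000	eno	glycolysis	
PYK	pyruvate kinase	adp + pep -> atp + pyr	0	1000	pyk	glycolysis	
G6PDH	glucose-6-phosphate dehydrogenase (lumped with lactonase)	g6p + nadp -> 6pgc + nadph	0	1000	zwf	PPP	
GND	6-phosphogluconate dehydrogenase	6pgc + nadp -> co2 + nadph + ru5p__D	0	1000	gnd	PPP	
RPE	ribulose-5-phosphate epimerase	ru5p__D <=> xu5p__D	-1000	1000	rpe	PPP	
RPI	ribose-5-phosphate isomerase	ru5p__D <=> r5p	-1000	1000	rpi	PPP	
TKT1	transketolase 1	r5p + xu5p__D <=> g3p + s7p	-1000	1000	tkt	PPP	
TALA	transaldolase	g3p + s7p <=> e4p + f6p	-1000	1000	tal	PPP	
TKT2	transketolase 2	e4p + xu5p__D <=> f6p + g3p	-1000	1000	tkt	PPP	
PDH	pyruvate dehydrogenase complex	coa + nad + pyr -> accoa + co2 + nadh	0	1000	aceE	PDH	
CS	citrate synthase	accoa + h2o + oaa -> cit + coa	0	1000	gltA	TCA	
ACONT	aconitase	cit <=> icit	-1000	1000	acn	TCA	
ICDHx	isocitrate dehydrogenase (NADP)	icit + nadp -> akg + co2 + nadph	0	1000	icd	TCA	
AKGDH	2-oxoglutarate dehydrogenase	akg + coa + nad -> co2 + nadh + succoa	0	1000	odhA	TCA	
SUCOAS	succinyl-CoA synthetase	adp + pi + succoa <=> atp + coa + succ	-1000	1000	sucCD	TCA	
SUCD	succinate dehydrogenase (FAD lumped into NAD pool)	nad + succ -> fum + nadh	0	1000	sdh	TCA	
FUM	fumarase	fum + h2o <=> mal__L	-1000	1000	fum	TCA	
MDH	malate dehydrogenase	mal__L + nad <=> nadh + oaa	-1000	1000	mdh	TCA	
ICL	isocitrate lyase	icit -> glx + succ	0	0	aceA	glyoxylate	
MALS	malate synthase	accoa + glx + h2o -> coa + mal__L	0	0	aceB	glyoxylate	
PC	pyruvate carboxylase	atp + co2 + pyr -> adp + oaa + pi	0	1000	pyc	anaplerosis	
PPC	PEP carboxylase	co2 + pep -> oaa + pi	0	1000	ppc	anaplerosis	
PCK	PEP carboxykinase	atp + oaa -> adp + co2 + pep	0	1000	pck	anaplerosis	
ME	malic enzyme (NADP)	mal__L + nadp -> co2 + nadph + pyr	0	1000	malE	anaplerosis	
LDH	lactate dehydrogenase	nadh + pyr <=> lac__L + nad	-1000	1000	ldh	fermentation	
GDH	glutamate dehydrogenase (NADPH)	akg + nadph + nh4 <=> glu__L + h2o + nadp	-1000	1000	gdh	nitrogen	
ALATA	alanine transaminase	glu__L + pyr <=> akg + ala__L	-1000	1000	alaT	fermentation	
ALAD	alanine dehydrogenase (NADH)	nadh + nh4 + pyr <=> ala__L + h2o + nad	-1000	1000	alaD	fermentation	
ACLS	acetolactate synthase	2 pyr -> alac__S + co2	0	1000	ilvBN	BCAA	
KARA	ketol-acid reductoisomerase	alac__S + nadph -> 23dhmb + nadp	0	1000	ilvC	BCAA	
DHAD	dihydroxy-acid dehydratase	23dhmb -> 3mob + h2o	0	1000	ilvD	BCAA	
VALTA	valine transaminase	3mob + glu__L <=> akg + val__L	-1000	1000	ilvE	BCAA	
IPPS	2-isopropylmalate synthase	3mob + accoa + h2o -> 3c3hmp + coa	0	1000	leuA	BCAA	
IPMD	isopropylmalate isomerase/dehydrogenase (lumped leuCD+leuB)	3c3hmp + nad -> 4mop + co2 + nadh	0	1000	leuB	BCAA	
LEUTA	leucine transaminase	4mop + glu__L <=> akg + leu__L	-1000	1000	ilvE	BCAA	
ACK	acetate kinase	ac + atp <=> actp + adp	-1000	1000	ackA	acetate	
PTA	phosphotransacetylase	accoa + pi <=> actp + coa	-1000	1000	pta	acetate	
NADHOX	lumped respiratory chain (P/O = 2)	2 adp + nadh + 0.5 o2 + 2 pi -> 2 atp + h2o + nad	0	1000		energy	
ATPM	non-growth ATP maintenance	atp + h2o -> adp + pi	2	1000		energy	pseudo
DM_accoa	acetyl-CoA demand (yield probe)	accoa -> coa	0	0		demand	pseudo
DM_mal__L	malate demand (yield probe)	mal__L -> 	0	0		demand	pseudo
BIOMASS	lumped biomass formation (growth-rate proxy)	3.7 accoa + 1.1 akg + 40 atp + 0.4 e4p + 16 nadph + 10 nh4 + 1.8 oaa + 2.8 pyr + 0.9 r5p -> 40 adp + 3.7 coa + 16 nadp + 40 pi	0	1000		biomass	pseudo
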