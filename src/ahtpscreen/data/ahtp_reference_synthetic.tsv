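peptide_id	sequence	activity_um	source
AHTP001	IKW	0.21	synthetic fixture: chicken muscle hydrolysate style
AHTP002	LRP	0.27	synthetic fixture: dried bonito style
AHTP003	LKP	0.32	synthetic fixture: dried bonito style
AHTP004	MKP	0.5	synthetic fixture: casein hydrolysate style
AHTP005	LRW	0.54	synthetic fixture: lactoferrin fragment style
AHTP006	IW	0.7	synthetic fixture: salmon muscle style
AHTP007	KGYGGVSLPEW	0.83	synthetic fixture: whole whey proteins style
AHTP008	VW	1.4	synthetic fixture: sake lees style
AHTP009	KW	1.6	synthetic fixture: fish protein style
AHTP010	IKP	1.7	synthetic fixture: dried bonito style
AHTP011	LQP	1.9	synthetic fixture: maize alpha-zein style
AHTP012	VAP	2.0	synthetic fixture: casein fragment style
AHTP013	VRP	2.2	synthetic fixture: maize alpha-zein style
AHTP014	IVGRPRHQG	2.4	synthetic fixture: alpha-s1 casein style
AHTP015	GPL	2.6	synthetic fixture: bovine skin gelatin style
AHTP016	LAP	3.5	synthetic fixture: chicken muscle style
AHTP017	IY	3.7	synthetic fixture: wheat germ style
AHTP018	FY	3.8	synthetic fixture: sardine muscle style
AHTP019	YAEERYPIL	4.7	synthetic fixture: ovalbumin fragment style
AHTP020	GPV	4.8	synthetic fixture: bovine skin gelatin style
AHTP021	DLP	5.0	synthetic fixture: soy glycinin style
AHTP022	IPP	5.0	synthetic fixture: fermented milk beta-casein style
AHTP023	LHLPLP	5.7	synthetic fixture: beta-casein fragment style
AHTP024	IYP	6.1	synthetic fixture: whey fragment style
AHTP025	RADHPFL	6.2	synthetic fixture: ovalbumin fragment style
AHTP026	VY	7.1	synthetic fixture: sardine muscle style
AHTP027	AVP	8.0	synthetic fixture: casein fragment style
AHTP028	VPP	9.0	synthetic fixture: fermented milk beta-casein style
AHTP029	AW	10.0	synthetic fixture: enzymatic whey style
AHTP030	RY	10.5	synthetic fixture: soy protein style
AHTP031	IRP	11.0	synthetic fixture: fish muscle style
AHTP032	GKP	12.0	synthetic fixture: porcine myosin style
AHTP033	AIP	13.0	synthetic fixture: egg white style
AHTP034	AVPYPQR	15.0	synthetic fixture: beta-casein fragment style
AHTP035	TTMPLW	16.0	synthetic fixture: alpha-s1 casein style
AHTP036	VLP	18.0	synthetic fixture: fish frame hydrolysate style
AHTP037	YKVPQL	22.0	synthetic fixture: alpha-s1 casein style
AHTP038	LW	23.6	synthetic fixture: enzymatic whey style
AHTP039	LGP	25.0	synthetic fixture: fish skin collagen style
AHTP040	FQP	27.0	synthetic fixture: soybean style
AHTP041	GLP	30.0	synthetic fixture: fish skin collagen style
AHTP042	LNP	33.0	synthetic fixture: dried bonito style
AHTP043	HLP	36.0	synthetic fixture: rice protein style
AHTP044	VSV	40.0	synthetic fixture: soy glycinin style
AHTP045	ALPMHIR	42.6	synthetic fixture: beta-lactoglobulin fragment style
AHTP046	IVP	48.0	synthetic fixture: sesame protein style
AHTP047	LLP	57.0	synthetic fixture: maize alpha-zein style
AHTP048	LVL	62.0	synthetic fixture: royal jelly style
AHTP049	ASL	70.0	synthetic fixture: pork muscle style
AHTP050	FFVAPFPEVFGK	77.0	synthetic fixture: alpha-s1 casein style
AHTP051	RVPSL	105.0	synthetic fixture: egg white ovalbumin style
AHTP052	IPA	141.0	synthetic fixture: beta-lactoglobulin style
AHTP053	YPK	220.0	synthetic fixture: casein fragment style
AHTP054	VYP	288.0	synthetic fixture: whey fragment style
AHTP055	GAV	340.0	synthetic fixture: gelatin fragment style
AHTP056	IRA	410.0	synthetic fixture: pea protein style
AHTP057	YGLF		synthetic fixture: alpha-lactorphin style, activity unverified
AHTP058	LVYPFP		synthetic fixture: beta-casein style, activity unverified
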