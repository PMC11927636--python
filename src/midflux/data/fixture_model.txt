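# Curated toy network: glycolysis, oxidative PPP with a lumped non-oxidative
# return, de novo serine -> glycine + CH2-THF -> methionine-cycle methyl ->
# SAM, pyruvate -> lactate / PDH, citrate synthesis with oxidation vs efflux,
# and unlabeled medium inflows (serine, alanine, beta-oxidation acetyl units,
# oxaloacetate pool). Textbook carbon transitions; lowercase letters shared
# between sides define the atom map.

@MET GLC carbons=6 kind=substrate measured=0
@MET SERX carbons=3 kind=substrate measured=0
@MET ALA carbons=3 kind=substrate measured=0
@MET ACEX carbons=2 kind=substrate measured=0
@MET OAA carbons=4 kind=substrate measured=0
@MET G6P carbons=6 kind=balanced measured=0
@MET GAP carbons=3 kind=balanced measured=0
@MET P5P carbons=5 kind=balanced measured=1
@MET PG3 carbons=3 kind=balanced measured=1
@MET SER carbons=3 kind=balanced measured=1
@MET GLY carbons=2 kind=balanced measured=1
@MET MLTHF carbons=1 kind=balanced measured=0
@MET MET carbons=1 kind=balanced measured=0
@MET PYR carbons=3 kind=balanced measured=1
@MET ACCOA carbons=2 kind=balanced measured=0
@MET CIT carbons=6 kind=balanced measured=1
@MET LAC carbons=3 kind=sink measured=1
@MET SAM carbons=1 kind=sink measured=1
@MET CO2 carbons=1 kind=sink measured=0
@MET E2C carbons=2 kind=sink measured=0
@MET GLYX carbons=2 kind=sink measured=0
@MET TCAOUT carbons=6 kind=sink measured=0
@MET CITX carbons=6 kind=sink measured=0

# glucose uptake and upper glycolysis (PFK/aldolase/TPI lumped; the DHAP
# half enters GAP with inverted carbon order)
v_upt: GLC(abcdef) -> G6P(abcdef) ; lb=0 ; ub=20
v_ald: G6P(abcdef) -> GAP(cba) + GAP(def) ; lb=0 ; ub=30

# oxidative pentose phosphate pathway (C1 released as CO2) and a lumped
# non-oxidative return of pentose carbons to glycolysis
v_ppp: G6P(abcdef) -> CO2(a) + P5P(bcdef) ; lb=0 ; ub=30
v_tkt: P5P(abcde) -> E2C(ab) + GAP(cde) ; lb=0 ; ub=30

# lower glycolysis
v_gapdh: GAP(abc) -> PG3(abc) ; lb=0 ; ub=60
v_pk: PG3(abc) -> PYR(abc) ; lb=0 ; ub=60

# de novo serine pathway (PHGDH/PSAT1/PSPH lumped) plus medium serine uptake
v_phgdh: PG3(abc) -> SER(abc) ; lb=0 ; ub=30
v_serup: SERX(abc) -> SER(abc) ; lb=0 ; ub=30

# serine hydroxymethyltransferase: glycine + one-carbon unit (CH2-THF)
v_shmt: SER(abc) -> GLY(ab) + MLTHF(c) ; lb=0 ; ub=30
v_glyout: GLY(ab) -> GLYX(ab) ; lb=0 ; ub=30

# methionine cycle: one-carbon unit onto homocysteine (methionine synthase),
# then SAM synthesis; only the methyl carbon is tracked
v_ms: MLTHF(a) -> MET(a) ; lb=0 ; ub=30
v_mat: MET(a) -> SAM(a) ; lb=0 ; ub=30

# pyruvate node: medium alanine inflow, lactate excretion, PDH decarboxylation
v_alaup: ALA(abc) -> PYR(abc) ; lb=0 ; ub=30
v_ldh: PYR(abc) -> LAC(abc) ; lb=0 ; ub=60
v_pdh: PYR(abc) -> CO2(a) + ACCOA(bc) ; lb=0 ; ub=60

# acetyl-CoA from beta-oxidation of medium fatty acid (unlabeled acetyl units)
v_fao: ACEX(ab) -> ACCOA(ab) ; lb=0 ; ub=30

# citrate synthase; citrate either oxidized in the cycle or exported
v_cs: ACCOA(ab) + OAA(cdef) -> CIT(abcdef) ; lb=0 ; ub=60
v_cit_ox: CIT(abcdef) -> TCAOUT(abcdef) ; lb=0 ; ub=60
v_cit_exp: CIT(abcdef) -> CITX(abcdef) ; lb=0 ; ub=60
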