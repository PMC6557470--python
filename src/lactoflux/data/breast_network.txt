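# Central-carbon network for proliferating breast epithelial / breast cancer
# cell lines: glycolysis, pentose phosphate pathway, TCA cycle, anaplerosis,
# glutaminolysis, lactate exchange, compartmented citrate / acetyl-CoA, and
# biomass drains.  One reaction per line: "<id>\t<substrates> <arrow> <products>";
# "<->" marks a reversible reaction; atom maps are lowercase letters, one per
# carbon, locally scoped to the reaction; "x|y" lists equally weighted map
# variants (rotationally symmetric molecules: succinate, fumarate).
# Compartment suffixes: .m mitochondria, .c cytosol, .x extracellular.
# Terms without an atom map are lumped pools or drains whose carbon never
# reaches a measured fragment (model reduction).
@unbalanced GLC.x LAC.x GLN.x GLU.x ALA.x ASP.x EAA.x CO2
@sink Biomass LipidBiomass
@dilution v38
# --- glycolysis ---
v1	GLC.x (abcdef) -> G6P (abcdef)
v2	G6P (abcdef) <-> F6P (abcdef)
v3	F6P (abcdef) -> FBP (abcdef)
v4	FBP (abcdef) <-> DHAP (cba) + GAP (def)
v5	DHAP (abc) <-> GAP (abc)
v6	GAP (abc) <-> PG3 (abc)
v7	PG3 (abc) <-> PEP (abc)
v8	PEP (abc) -> PYR (abc)
# --- lactate metabolism ---
v9	PYR (abc) <-> LAC (abc)
v10	LAC (abc) -> LAC.x (abc)
# --- pentose phosphate pathway ---
v11	G6P (abcdef) -> P5P (bcdef) + CO2 (a)
v12	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)
v13	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)
v14	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)
# --- TCA cycle ---
v15	PYR (abc) -> AcCoA.m (bc) + CO2 (a)
v16	OAA (abcd) + AcCoA.m (ef) -> CIT.m (dcbfea)
v17	CIT.m (abcdef) <-> AKG (abcde) + CO2 (f)
v18	AKG (abcde) -> SUC (bcde) + CO2 (a)
v19	SUC (abcd) <-> FUM (abcd|dcba)
v20	FUM (abcd|dcba) <-> MAL (abcd)
v21	MAL (abcd) <-> OAA (abcd)
# --- anaplerosis / cataplerosis ---
v22	PYR (abc) + CO2 (d) -> OAA (abcd)
v23	MAL (abcd) -> PYR (abc) + CO2 (d)
# --- glutamine metabolism ---
v24	GLN.x (abcde) -> GLN (abcde)
v25	GLN (abcde) -> GLU (abcde)
v26	GLU (abcde) <-> AKG (abcde)
v27	GLU (abcde) -> GLU.x (abcde)
# --- transaminases and amino acid exchange ---
v28	PYR (abc) <-> ALA (abc)
v29	OAA (abcd) <-> ASP (abcd)
v30	ALA (abc) -> ALA.x (abc)
v31	ASP (abcd) -> ASP.x (abcd)
# --- citrate shuttle and fatty acid synthesis ---
v32	CIT.m (abcdef) <-> CIT.c (abcdef)
v33	CIT.c (abcdef) -> AcCoA.c (ed) + OAA (fcba)
v34	8*AcCoA.c -> PALM
# --- essential / lumped amino acid uptake (no atom maps: carbon does not
# --- reach any measured fragment; includes Ser, Gly, branched-chain AAs)
v35	EAA.x -> EAA
# --- biomass drains; coefficients in mmol per g dry weight, drain flux in
# --- ug dry weight per 1e6 cells per h, so precursor fluxes are nmol/1e6 cells/h
v36	0.35*G6P + 0.35*P5P + 0.6*ALA + 0.35*ASP + 0.5*GLU + 0.35*GLN + 5.5*EAA -> Biomass
v37	0.27*PALM + 0.13*DHAP -> LipidBiomass
# --- lactate dilution exchange: mixes the intracellular lactate pool with the
# --- extracellular pool without net carbon transfer
v38	LAC.x (abc) <-> LAC (abc)
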