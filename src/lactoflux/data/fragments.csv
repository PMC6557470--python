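# Default GC-MS fragment table for TBDMS-derivatized intracellular metabolites.
# carbons: backbone carbon range covered by the fragment (1-based, inclusive).
# formula: elemental composition of the detected ion, used for natural-isotope
# abundance correction.  These are representative [M-57]+ compositions for
# TBDMS derivatives; the table is a configuration input and can be replaced.
fragment_id,metabolite,carbons,formula
PG3_123,PG3,1-3,C11H28O7PSi3
DHAP_123,DHAP,1-3,C9H22O6PSi2
PYR_123,PYR,1-3,C6H12NO3
LAC_123,LAC,1-3,C11H25O3Si2
ALA_123,ALA,1-3,C11H26NO2Si2
SUC_1234,SUC,1-4,C12H23O4Si2
MAL_1234,MAL,1-4,C18H39O5Si3
AKG_12345,AKG,1-5,C14H27O5Si2
GLU_12345,GLU,1-5,C19H42NO4Si3
GLN_12345,GLN,1-5,C19H43N2O3Si3
CIT_123456,CIT.m,1-6,C20H39O7Si3
FUM_1234,FUM,1-4,C12H21O4Si2
ASP_1234,ASP,1-4,C18H40NO4Si3
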