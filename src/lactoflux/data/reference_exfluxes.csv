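# Measured biomass-specific extracellular fluxes (nmol/1e6 cells/h) for three
# human breast cell lines grown in control and high-lactate media (10 mM added
# sodium lactate for MCF10A, 20 mM for MCF7 and MDA-MB-231).  Negative values
# are consumption, positive values production.  SDs are Monte-Carlo propagated.
# Used as scale anchors for synthetic studies and for glycolytic-efficiency
# calculations.
cell_line,condition,metabolite,flux,sd,n
MCF10A,control,GLC,-222,51,6
MCF10A,control,LAC,379,56,6
MCF10A,control,GLN,-48,18,3
MCF10A,control,ALA,11,1.5,3
MCF10A,control,ASP,4.9,0.8,3
MCF10A,control,GLU,12,1.9,3
MCF10A,high_lactate,GLC,-182,48,6
MCF10A,high_lactate,LAC,254,55,6
MCF10A,high_lactate,GLN,-55,19,3
MCF10A,high_lactate,ALA,11,1.9,3
MCF10A,high_lactate,ASP,3.7,0.7,3
MCF10A,high_lactate,GLU,10,1.8,3
MCF7,control,GLC,-208,44,6
MCF7,control,LAC,318,54,6
MCF7,control,GLN,-53,19,3
MCF7,control,ALA,14,2.3,3
MCF7,control,ASP,6.5,1.3,3
MCF7,control,GLU,11,2.0,3
MCF7,high_lactate,GLC,-158,42,6
MCF7,high_lactate,LAC,131,32,6
MCF7,high_lactate,GLN,-63,18,3
MCF7,high_lactate,ALA,12,2.3,3
MCF7,high_lactate,ASP,5.4,1.1,3
MCF7,high_lactate,GLU,12,2.3,3
MDA-MB-231,control,GLC,-337,65,6
MDA-MB-231,control,LAC,603,108,6
MDA-MB-231,control,GLN,-44,21,3
MDA-MB-231,control,ALA,10,1.8,3
MDA-MB-231,control,ASP,3.5,0.7,3
MDA-MB-231,control,GLU,8.5,1.6,3
MDA-MB-231,high_lactate,GLC,-267,67,6
MDA-MB-231,high_lactate,LAC,342,87,6
MDA-MB-231,high_lactate,GLN,-55,21,3
MDA-MB-231,high_lactate,ALA,8.2,2.0,3
MDA-MB-231,high_lactate,ASP,4.5,1.1,3
MDA-MB-231,high_lactate,GLU,10,2.5,3
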