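# Ligand donor/scaffold rule pack, version 1.0
# Format: <role>\t<rule_id>\t<SMARTS>
# Roles: donor (candidate donor atom, first matched atom), exclude (atoms that
# are never donors), scaffold (structural flags).
exclude	amide_N	[NX3][CX3]=[OX1]
exclude	nitro_N	[NX3](=[OX1])=[OX1]
exclude	nitro_N_charged	[NX3+](=[OX1])[OX1-]
donor	trivalent_P	[#15;X3]
donor	phosphine_oxide_P	[#15;X4]=[OX1]
donor	imine_N	[NX2]=[CX3]
donor	aromatic_azine_N	[n;X2;H0]
donor	nhc_carbene_C	[#6;X2;H0;R]([#7])[#7]
donor	thioether_S	[SX2;!a]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]
donor	ether_O	[OX2;!a]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]
scaffold	cp_ring_anion	[#6;-]1~[#6]~[#6]~[#6]~[#6]1
scaffold	ferrocene_iron	[Fe]
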