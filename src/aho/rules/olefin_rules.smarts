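# Olefin functional-class rule pack, version 1.0
# Format: <class>\t<rule_id>\t<SMARTS>
# Atom maps :1 and :2 anchor the pattern at the two vinylic carbons of the
# perceived reacting C=C. Within a class, rules are tried in file order and
# the first hit supplies the subtype annotation.
enamide_enamine	enamide_acyl_N	[C:1]=[C:2]-[NX3]-[CX3]=[OX1]
enamide_enamine	enamine_N	[C:1]=[C:2]-[NX3;!$([NX3][CX3]=[OX1])]
enol	enol_carbamate	[C:1]=[C:2]-[OX2][CX3](=[OX1])[NX3]
enol	enol_ester	[C:1]=[C:2]-[OX2][CX3]=[OX1]
enol	enol_phosphinate	[C:1]=[C:2]-[OX2][PX4](=[OX1])([#6])[#6]
enol	enol_phosphonate	[C:1]=[C:2]-[OX2][PX4](=[OX1])([OX2])[#6]
enol	silyl_enol_ether	[C:1]=[C:2]-[OX2][Si]
enol	enol_ether	[C:1]=[C:2]-[OX2][#6;!$([CX3]=[OX1])]
ab_unsat_carbonyl	absun_acid	[C:1]=[C:2]-[CX3](=[OX1])[OX2H1]
ab_unsat_carbonyl	absun_ester	[C:1]=[C:2]-[CX3](=[OX1])[OX2][#6]
ab_unsat_carbonyl	absun_amide	[C:1]=[C:2]-[CX3](=[OX1])[NX3]
ab_unsat_carbonyl	absun_ketone	[C:1]=[C:2]-[CX3](=[OX1])[#6]
ab_unsat_carbonyl	absun_aldehyde	[C:1]=[C:2]-[CX3H1]=[OX1]
other_heteroatom	vinylic_heteroatom	[C:1]=[C:2]-[!#6;!#1;!#7;!#8]
allylic_alcohol_ether	allylic_O	[C:1]=[C:2]-[CX4]-[OX2]
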