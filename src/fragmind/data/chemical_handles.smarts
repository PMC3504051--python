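# Chemical-handle catalog: substructures a chemist could elaborate
# synthetically. One entry per line: <name> <SMARTS>.
primary_amine [NX3;H2;!$([NX3][#6]=[O,S,N])]
secondary_amine [NX3;H1;!a;!$([NX3][#6]=[O,S,N])]
aryl_halide c[Cl,Br,I]
carboxylic_acid [CX3](=O)[OX2H1]
ester [CX3](=O)[OX2H0][#6]
aldehyde [CX3H1]=[OX1]
ketone [#6][CX3](=[OX1])[#6]
nitrile [CX2]#[NX1]
alcohol [OX2H][CX4]
phenol [OX2H]c
terminal_alkyne [CX2]#[CX2H1]
sulfonamide_nh [SX4](=[OX1])(=[OX1])[NX3;!H0]
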