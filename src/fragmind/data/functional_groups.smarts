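# Functional-group catalog for the joint functional-group key.
# One entry per line: <name> <SMARTS>. Lines starting with '#' are ignored.
tertiary_amine [NX3;H0;!a;!$([NX3][#6]=[O,S,N]);!$([NX3][S,P]=O)]
secondary_amine [NX3;H1;!a;!$([NX3][#6]=[O,S,N]);!$([NX3][S,P]=O)]
primary_amine [NX3;H2;!$([NX3][#6]=[O,S,N]);!$([NX3][S,P]=O)]
aromatic_heteroatom [a;!#6]
hydroxyl [OX2H][CX4,c]
carboxylic_acid [CX3](=O)[OX2H1]
amide [NX3][CX3]=[OX1]
sulfonamide [SX4](=[OX1])(=[OX1])[NX3]
nitrile [CX2]#[NX1]
halogen [F,Cl,Br,I]
ester [CX3](=O)[OX2H0][#6]
ketone [#6][CX3](=[OX1])[#6]
ether [OD2]([CX4])[CX4,c]
nitro [$([NX3](=O)=O),$([NX3+](=O)[O-])]
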