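{
  "azide": "[$([NX2]=[NX2+]=[NX1-]),$([NX1]#[NX2+][NX2-]),$([NX2]=[NX2]=[NX1])]",
  "azo compound": "[#6][NX2]=[NX2][#6]",
  "acyl fluoride": "[CX3](=[OX1])[F]",
  "aryl fluoride": "[F][c]",
  "alkyl fluoride": "[F][CX4]",
  "carbonitrile": "[CX2]#[NX1]",
  "secondary alcohol": "[CX4;H1]([#6])([#6])[OX2H]",
  "trialkylamine": "[NX3;H0]([CX4])([CX4])[CX4]",
  "alkyne": "[CX2]#[CX2]",
  "tertiary amine": "[NX3;H0]([#6])([#6])[#6]",
  "aromatic compound": "[a]",
  "dialkyl ether": "[CX4][OX2][CX4]",
  "heterocyclic compound": "[!#6;!#1;R]",
  "hydroperoxide": "[OX2H][OX2][#6]",
  "diaryl ether": "[c][OX2][c]",
  "peroxide": "[OX2]([#6,#1])[OX2][#6,#1]",
  "diarylamine": "[NX3;H1]([c])[c]",
  "carbamic acid halide": "[NX3][CX3](=[OX1])[F,Cl,Br,I]",
  "nitrite": "[#6][OX2][NX2]=[OX1]",
  "hydroxamic acid": "[CX3](=[OX1])[NX3][OX2H]",
  "nitroso compound": "[#6][NX2]=[OX1]",
  "hydroxylamine": "[NX3;!$([NX3][CX3]=[OX1])][OX2H]",
  "hemiacetal": "[CX4]([OX2H])[OX2][#6]",
  "enol ether": "[CX3]=[CX3][OX2][#6]",
  "amide acetal": "[NX3][CX4]([OX2][#6])[OX2][#6]",
  "carboxylic acid": "[CX3](=[OX1])[OX2H]",
  "hemiaminal": "[CX4]([OX2H])[NX3]",
  "acyl cyanide": "[CX3](=[OX1])[CX2]#[NX1]"
}
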