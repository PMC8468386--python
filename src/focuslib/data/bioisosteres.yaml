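# Bioisosteric replacement rules for seed expansion.
#
# Each rule rewrites a SMARTS-matched substructure into a replacement
# fragment (SMILES); the fragment's first atom inherits the bonds of
# the matched group. These are literature-common medicinal-chemistry
# pairs; edit or extend freely — the file is configuration, not code.
- name: carboxamidine_to_2_aminopyridine
  pattern: "[CX3](=[NH])[NH2]"
  replacement: "c1cccc(N)n1"
- name: carboxylic_acid_to_tetrazole
  pattern: "[CX3](=O)[OX2H1]"
  replacement: "c1nnn[nH]1"
- name: ester_O_to_amide_N
  pattern: "[OX2;$([O]([#6])[CX3]=O)]"
  replacement: "N"
- name: carbonyl_O_to_thiocarbonyl_S
  pattern: "[$([OX1]=[CX3])]"
  replacement: "S"
- name: chloro_to_bromo
  pattern: "[Cl;X1]"
  replacement: "Br"
- name: methyl_to_trifluoromethyl
  pattern: "[CH3;$([CH3][c,C])]"
  replacement: "C(F)(F)F"
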