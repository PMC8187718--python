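# Minimal heavy-atom interaction parameters (united polar groups).
# residue  atom  charge(e)  sigma(Angstrom)  epsilon(kJ/mol)
# '*' rows parameterise backbone atoms of any residue type.
# Side-chain charges sum to -1 (Asp/Glu) or +1 (Arg/Lys/His+) exactly.
*    N    -0.35  3.25  0.71
*    CA    0.10  3.40  0.36
*    C     0.55  3.40  0.36
*    O    -0.30  2.96  0.88
# Ionizable-group N/O atoms carry united-group parameters: no explicit
# hydrogens, so their LJ radii are reduced to keep H-bonding contact
# distances (2.4-3.2 Angstrom) on the attractive branch.
GLU  CB    0.00  3.40  0.36
GLU  CG   -0.10  3.40  0.36
GLU  CD    0.70  3.40  0.36
GLU  OE1  -0.80  2.50  0.20
GLU  OE2  -0.80  2.50  0.20
ASP  CB   -0.10  3.40  0.36
ASP  CG    0.70  3.40  0.36
ASP  OD1  -0.80  2.50  0.20
ASP  OD2  -0.80  2.50  0.20
ARG  CB    0.00  3.40  0.36
ARG  CG   -0.10  3.40  0.36
ARG  CD    0.00  3.40  0.36
ARG  NE    0.20  2.80  0.20
ARG  CZ    0.30  3.40  0.36
ARG  NH1   0.30  2.80  0.20
ARG  NH2   0.30  2.80  0.20
LYS  CB    0.00  3.40  0.36
LYS  CG    0.00  3.40  0.36
LYS  CD    0.05  3.40  0.36
LYS  CE    0.25  3.40  0.36
LYS  NZ    0.70  2.80  0.20
HIS  CB    0.00  3.40  0.36
HIS  CG    0.10  3.40  0.36
HIS  ND1   0.15  2.80  0.20
HIS  CD2   0.15  3.40  0.36
HIS  CE1   0.25  3.40  0.36
HIS  NE2   0.35  2.80  0.20
GLY  CB    0.00  3.40  0.36
ALA  CB    0.00  3.40  0.36
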