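# Reference solvent accessible areas (Angstrom^2): central
# residue of a fully extended Gly-X-Gly tripeptide built with
# the package's own backbone generator and side-chain templates.
name3	area
ALA	115.10
CYS	147.29
ASP	159.67
GLU	186.00
PHE	226.52
GLY	84.87
HIS	207.73
ILE	183.13
LYS	218.05
LEU	193.35
MET	207.52
ASN	166.92
PRO	135.81
GLN	193.46
ARG	257.86
SER	124.34
THR	149.63
VAL	158.64
TRP	269.24
TYR	237.27
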