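# Side-chain internal-coordinate templates.
# Geometry (bond lengths Angstrom, angles/torsions degrees) measured
# from PDB Chemical Component Dictionary ideal coordinates.
# Torsion column: number = fixed; chiK = rotatable (default below);
# chiK+D = branch locked at offset D from the chiK atom.

RESIDUE ALA
ATOM CB   C C   N   CA    1.529  109.46 -120.00

RESIDUE ARG
CHI -65.0 180.0 180.0 180.0
ATOM CB   C C   N   CA    1.536  111.55 -123.56
ATOM CG   C N   CA  CB    1.537  114.54 chi1
ATOM CD   C CA  CB  CG    1.527  112.42 chi2
ATOM NE   N CB  CG  CD    1.444  111.02 chi3
ATOM CZ   C CG  CD  NE    1.406  123.00 chi4
ATOM NH1  N CD  NE  CZ    1.391  121.00 179.99
ATOM NH2  N CD  NE  CZ    1.391  119.81 -0.01

RESIDUE ASN
CHI -65.0 -20.0
ATOM CB   C C   N   CA    1.531  109.45 -120.00
ATOM CG   C N   CA  CB    1.507  109.48 chi1
ATOM OD1  O CA  CB  CG    1.213  119.97 chi2
ATOM ND2  N CA  CB  CG    1.348  120.01 chi2-179.93

RESIDUE ASP
CHI -65.0 -15.0
ATOM CB   C C   N   CA    1.530  109.48 -120.01
ATOM CG   C N   CA  CB    1.508  109.46 chi1
ATOM OD1  O CA  CB  CG    1.208  119.96 chi2
ATOM OD2  O CA  CB  CG    1.341  120.00 chi2-179.94

RESIDUE CYS
CHI -65.0
ATOM CB   C C   N   CA    1.528  109.50 -120.01
ATOM SG   S N   CA  CB    1.814  109.50 chi1

RESIDUE GLN
CHI -65.0 180.0 -20.0
ATOM CB   C C   N   CA    1.529  109.46 -120.07
ATOM CG   C N   CA  CB    1.528  109.53 chi1
ATOM CD   C CA  CB  CG    1.507  109.54 chi2
ATOM OE1  O CB  CG  CD    1.212  119.94 chi3
ATOM NE2  N CB  CG  CD    1.347  120.09 chi3-179.96

RESIDUE GLU
CHI -65.0 180.0 -10.0
ATOM CB   C C   N   CA    1.530  109.48 -119.96
ATOM CG   C N   CA  CB    1.531  109.40 chi1
ATOM CD   C CA  CB  CG    1.508  109.43 chi2
ATOM OE1  O CB  CG  CD    1.208  120.00 chi3
ATOM OE2  O CB  CG  CD    1.343  120.00 chi3-179.94

RESIDUE GLY

RESIDUE HIS
CHI -65.0 -75.0
ATOM CB   C C   N   CA    1.534  111.13 -122.78
ATOM CG   C N   CA  CB    1.510  112.98 chi1
ATOM ND1  N CA  CB  CG    1.351  120.33 chi2
ATOM CD2  C CA  CB  CG    1.338  129.93 chi2+179.85
ATOM CE1  C CB  CG  ND1   1.337  107.86 179.90
ATOM NE2  N CB  CG  CD2   1.374  105.33 -179.86

RESIDUE ILE
CHI -65.0 170.0
ATOM CB   C C   N   CA    1.529  109.43 -120.07
ATOM CG1  C N   CA  CB    1.529  109.55 chi1
ATOM CG2  C N   CA  CB    1.530  109.46 chi1-119.97
ATOM CD1  C CA  CB  CG1   1.529  109.55 chi2

RESIDUE LEU
CHI -65.0 175.0
ATOM CB   C C   N   CA    1.529  109.42 -119.97
ATOM CG   C N   CA  CB    1.530  109.49 chi1
ATOM CD1  C CA  CB  CG    1.530  109.50 chi2
ATOM CD2  C CA  CB  CG    1.529  109.50 chi2+120.09

RESIDUE LYS
CHI -65.0 180.0 180.0 180.0
ATOM CB   C C   N   CA    1.530  109.45 -119.97
ATOM CG   C N   CA  CB    1.531  109.42 chi1
ATOM CD   C CA  CB  CG    1.531  109.44 chi2
ATOM CE   C CB  CG  CD    1.529  109.46 chi3
ATOM NZ   N CG  CD  CE    1.469  109.50 chi4

RESIDUE MET
CHI -65.0 180.0 180.0
ATOM CB   C C   N   CA    1.529  109.43 -120.04
ATOM CG   C N   CA  CB    1.528  109.54 chi1
ATOM SD   S CA  CB  CG    1.814  109.51 chi2
ATOM CE   C CB  CG  SD    1.814  100.03 chi3

RESIDUE PHE
CHI -65.0 90.0
ATOM CB   C C   N   CA    1.529  109.47 -120.09
ATOM CG   C N   CA  CB    1.505  109.52 chi1
ATOM CD1  C CA  CB  CG    1.382  120.06 chi2
ATOM CD2  C CA  CB  CG    1.383  120.00 chi2+179.76
ATOM CE1  C CB  CG  CD1   1.382  120.03 179.99
ATOM CE2  C CB  CG  CD2   1.382  119.98 179.84
ATOM CZ   C CG  CD1 CE1   1.381  120.05 -0.05

RESIDUE PRO
ATOM CB   C C   N   CA    1.543  104.72 -118.84
ATOM CG   C N   CA  CB    1.543  105.06 -23.80
ATOM CD   C CA  CB  CG    1.544  105.06 0.03

RESIDUE SER
CHI 62.0
ATOM CB   C C   N   CA    1.529  109.47 -120.02
ATOM OG   O N   CA  CB    1.428  109.51 chi1

RESIDUE THR
CHI 62.0
ATOM CB   C C   N   CA    1.529  109.41 -120.00
ATOM OG1  O N   CA  CB    1.428  109.51 chi1
ATOM CG2  C N   CA  CB    1.530  109.53 chi1-120.03

RESIDUE TRP
CHI -65.0 95.0
ATOM CB   C C   N   CA    1.529  109.52 -120.03
ATOM CG   C N   CA  CB    1.507  109.44 chi1
ATOM CD1  C CA  CB  CG    1.343  126.50 chi2
ATOM CD2  C CA  CB  CG    1.464  126.51 chi2+179.62
ATOM NE1  N CB  CG  CD1   1.369  109.93 179.94
ATOM CE2  C CB  CG  CD2   1.407  106.08 179.96
ATOM CE3  C CB  CG  CD2   1.396  134.05 0.78
ATOM CZ2  C CG  CD2 CE2   1.391  119.35 -179.83
ATOM CZ3  C CG  CD2 CE3   1.366  119.80 179.64
ATOM CH2  C CD2 CE2 CZ2   1.377  119.81 0.22

RESIDUE TYR
CHI -65.0 90.0
ATOM CB   C C   N   CA    1.529  109.47 -120.04
ATOM CG   C N   CA  CB    1.506  109.50 chi1
ATOM CD1  C CA  CB  CG    1.382  119.95 chi2
ATOM CD2  C CA  CB  CG    1.383  119.94 chi2+179.69
ATOM CE1  C CB  CG  CD1   1.381  120.07 -179.98
ATOM CE2  C CB  CG  CD2   1.381  120.02 179.77
ATOM CZ   C CG  CD1 CE1   1.387  119.98 -0.10
ATOM OH   O CD1 CE1 CZ    1.358  120.13 -179.97

RESIDUE VAL
CHI 175.0
ATOM CB   C C   N   CA    1.529  109.45 -120.00
ATOM CG1  C N   CA  CB    1.530  109.51 chi1
ATOM CG2  C N   CA  CB    1.529  109.49 chi1+120.03
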