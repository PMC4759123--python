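# Per-element van der Waals radii (Angstrom), NACCESS-style set.
C  1.87
N  1.65
O  1.40
S  1.85
P  1.80
SE 1.90
F  1.47
CL 1.75
BR 1.85
I  1.98
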