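# Synthetic residue-level coarse-grained parameter table, version 1.
# One bead per amino acid or ribonucleotide. Short-range term: Wang-Frenkel
# (mu, nu shape parameters, cutoff 3*sigma); electrostatics: Debye-Hueckel with
# the scaled ionizable-group charges (+/-0.75 e) customary for this force-field
# class. These values were authored for this package from standard residue
# sizes/masses and interaction-class reasoning (aromatics > aliphatics > polar;
# Arg cation-pi capable; nucleotides stacking-capable). They are NOT a
# transcription of any published parameter set.
code	kind	mass_gmol	charge_e	sigma_nm	epsilon_kJmol	mu	nu
A	protein	71.08	0.0	0.504	0.35	2	1
R	protein	156.19	0.75	0.656	1.00	2	1
N	protein	114.10	0.0	0.568	0.40	2	1
D	protein	115.09	-0.75	0.558	0.30	2	1
C	protein	103.14	0.0	0.548	0.45	2	1
Q	protein	128.13	0.0	0.602	0.40	2	1
E	protein	129.12	-0.75	0.592	0.30	2	1
G	protein	57.05	0.0	0.450	0.25	2	1
H	protein	137.14	0.375	0.608	0.60	2	1
I	protein	113.16	0.0	0.618	0.50	2	1
L	protein	113.16	0.0	0.618	0.50	2	1
K	protein	128.17	0.75	0.636	0.25	2	1
M	protein	131.19	0.0	0.618	0.50	2	1
F	protein	147.18	0.0	0.636	1.20	2	1
P	protein	97.12	0.0	0.556	0.35	2	1
S	protein	87.08	0.0	0.518	0.30	2	1
T	protein	101.10	0.0	0.562	0.35	2	1
W	protein	186.21	0.0	0.678	1.50	2	1
Y	protein	163.18	0.0	0.646	1.30	2	1
V	protein	99.07	0.0	0.586	0.45	2	1
a	rna	329.21	-0.75	0.820	0.80	2	1
c	rna	305.18	-0.75	0.780	0.70	2	1
g	rna	345.21	-0.75	0.820	0.85	2	1
u	rna	306.17	-0.75	0.780	0.70	2	1
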