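# element	mass_amu	vdw_radius_A	covalent_radius_A
# Masses: IUPAC standard atomic weights (abridged). vdW: Bondi (1964),
# with common extensions; covalent radii: Cordero et al. (2008).
H	1.008	1.20	0.31
C	12.011	1.70	0.76
N	14.007	1.55	0.71
O	15.999	1.52	0.66
F	18.998	1.47	0.57
NA	22.990	2.27	1.66
MG	24.305	1.73	1.41
P	30.974	1.80	1.07
S	32.06	1.80	1.05
CL	35.45	1.75	1.02
K	39.098	2.75	2.03
CA	40.078	2.31	1.76
MN	54.938	2.05	1.39
FE	55.845	2.04	1.32
CO	58.933	2.00	1.26
NI	58.693	1.97	1.24
CU	63.546	1.96	1.32
ZN	65.38	2.01	1.22
SE	78.971	1.90	1.20
BR	79.904	1.85	1.20
I	126.904	1.98	1.39
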