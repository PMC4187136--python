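# protocean-thermodb version 1.0
# Standard Gibbs energies of formation at 298.15 K, 1 bar.
# Aqueous species follow the NBS/CODATA 25 C compilations (infinite-dilution
# convention, dGf(H+) = 0).  Sparingly soluble solids are anchored to measured
# 25 C solubility products where direct solubility work exists; remaining
# solids carry NBS calorimetric values.  The anchor used is recorded per row.
# formula tokens: element symbol followed by stoichiometric count; waters of
# hydration are folded into the formula of hydrated solids.
name	formula	charge	phase_class	dGf_kJ_per_mol	source
H2O	H2 O1	0	solvent	-237.140	CODATA 1989
H+	H1	1	aqueous	0.000	convention
OH-	H1 O1	-1	aqueous	-157.228	CODATA 1989, adjusted within uncertainty to pKw 14.000
Na+	Na1	1	aqueous	-261.905	NBS 1982
Cl-	Cl1	-1	aqueous	-131.228	NBS 1982
Mg+2	Mg1	2	aqueous	-454.800	NBS 1982
Ca+2	Ca1	2	aqueous	-553.580	NBS 1982
H3PO4	H3 P1 O4	0	aqueous	-1142.540	NBS 1982
H2PO4-	H2 P1 O4	-1	aqueous	-1130.280	NBS 1982 (pKa1 2.148)
HPO4-2	H1 P1 O4	-2	aqueous	-1089.150	NBS 1982 (pKa2 7.206)
PO4-3	P1 O4	-3	aqueous	-1018.700	NBS 1982 (pKa3 12.342)
NH4+	N1 H4	1	aqueous	-79.310	NBS 1982
NH3	N1 H3	0	aqueous	-26.500	NBS 1982 (pKa NH4+ 9.252)
H2S	H2 S1	0	aqueous	-27.830	NBS 1982
HS-	H1 S1	-1	aqueous	12.080	NBS 1982 (pKa1 H2S 6.992)
N2	N2	0	aqueous	18.188	NBS 1982 (Henry logK -3.19)
H2	H2	0	aqueous	17.570	NBS 1982
O2	O2	0	aqueous	16.320	NBS 1982
HNO3	H1 N1 O3	0	aqueous	-111.250	NBS 1982; outside default active set
H3PO2	H3 P1 O2	0	aqueous	-523.000	compiled, reduced P; outside default active set
H2PO2-	H2 P1 O2	-1	aqueous	-512.100	compiled, reduced P; outside default active set
H3PO3	H3 P1 O3	0	aqueous	-856.900	compiled, reduced P; outside default active set
H2PO3-	H2 P1 O3	-1	aqueous	-846.600	compiled, reduced P; outside default active set
HPO3-2	H1 P1 O3	-2	aqueous	-812.100	compiled, reduced P; outside default active set
N2(g)	N2	0	gas	0.000	reference state
H2(g)	H2	0	gas	0.000	reference state
O2(g)	O2	0	gas	0.000	reference state
H(g)	H1	0	gas	203.260	NBS 1982; outside default active set
H2O(g)	H2 O1	0	gas	-228.570	NBS 1982
NH3(g)	N1 H3	0	gas	-16.450	NBS 1982
HCl(g)	H1 Cl1	0	gas	-95.300	NBS 1982
MgNH4PO4:6H2O	Mg1 N1 H16 P1 O10	0	solid	-3051.338	anchored to pKsp 13.26 (struvite, Ohlinger et al. 1998)
CaHPO4	Ca1 H1 P1 O4	0	solid	-1682.115	anchored to pKsp 6.90 (monetite, 25 C solubility)
CaHPO4:2H2O	Ca1 H5 P1 O6	0	solid	-2154.626	anchored to pKsp 6.59 (brushite, 25 C solubility)
Ca(H2PO4)2	Ca1 H4 P2 O8	0	solid	-2808.432	anchored to pKsp -1.00 (handbook; highly soluble)
Ca(H2PO4)2:H2O	Ca1 H6 P2 O9	0	solid	-3044.773	anchored to pKsp -1.14 (handbook; highly soluble)
Ca2P2O7	Ca2 P2 O7	0	solid	-3132.000	NBS 1982 (beta)
Ca3(PO4)2	Ca3 P2 O8	0	solid	-3863.216	anchored to pKsp 28.92 (beta-TCP, Gregory et al. 1974)
Ca5(PO4)3OH	Ca5 P3 O13 H1	0	solid	-6337.100	NBS 1982 (hydroxyapatite, calorimetric)
Mg2P2O7	Mg2 P2 O7	0	solid	-2569.400	NBS 1982
Mg3(PO4)2	Mg3 P2 O8	0	solid	-3545.642	anchored to pKsp 25.20 (farringtonite, Lange's Handbook)
CaHPO3	Ca1 H1 P1 O3	0	solid	-1400.000	estimate, reduced P; outside default active set
NaH2PO4(s)	Na1 H2 P1 O4	0	solid	-1386.100	NBS 1982
Na2HPO4(s)	Na2 H1 P1 O4	0	solid	-1608.300	NBS 1982
CaO	Ca1 O1	0	solid	-603.300	NBS 1982 (lime)
Ca(OH)2	Ca1 H2 O2	0	solid	-898.500	NBS 1982 (portlandite)
CaMgO2	Ca1 Mg1 O2	0	solid	-1180.000	estimate from component oxides
MgO	Mg1 O1	0	solid	-569.300	NBS 1982 (periclase)
Mg(OH)2	Mg1 H2 O2	0	solid	-833.500	NBS 1982 (brucite)
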