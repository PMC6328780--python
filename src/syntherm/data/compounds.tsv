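# Standard Gibbs energies of formation, kJ/mol at 25 degC, solutes 1 M, gases 1e5 Pa.
# Literature constants from Thauer, Jungermann & Decker (1977) Bacteriol. Rev. 41:100-180.
# The proton carries no formation energy; pH enters reaction energies via the
# transformed-state term only.  Oleate and isethionate have no tabulated
# constants: their entries are left blank and back-calibrated at load time
# from the reference dG0' of the beta-oxidation and desulfonation reactions
# (see reference_dg.tsv), which is how the network's printed energies were
# constructed.  BrES and bromide carry no formation energy; they enter only
# the hydrolysis mass balance, never an energy computation.
id	formula	charge	phase	dGf_kJ_per_mol	source
H2O	H2O	0	liquid-water	-237.18	Thauer1977
H2	H2	0	gas	0	reference state
H+	H+	1	aqueous	0	convention
HCO3-	HCO3-	-1	aqueous	-586.85	Thauer1977
CH4	CH4	0	gas	-50.75	Thauer1977
acetate	C2H3O2-	-1	aqueous	-369.41	Thauer1977
sulfite	SO3^2-	-2	aqueous	-486.6	Thauer1977
sulfate	SO4^2-	-2	aqueous	-744.63	Thauer1977
HS-	HS-	-1	aqueous	12.05	Thauer1977
oleate	C18H33O2-	-1	aqueous		calibrated
isethionate	C2H5O4S-	-1	aqueous		calibrated
BrES	C2H4BrO3S-	-1	aqueous		none
bromide	Br-	-1	aqueous		none
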