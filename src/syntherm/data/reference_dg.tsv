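# Reference standard transformed Gibbs energies (kJ per formula reaction) of
# the bundled network at pH 7, 25 degC, solutes 1 M, gases 1e5 Pa, as
# reported in the syntrophic oleate-degradation literature.  r1 and r3 double
# as calibration targets for the oleate and isethionate formation energies.
label	description	dg0_prime_kJ
r1	beta-oxidation of oleate	325.86
r2	methanogenesis from hydrogen	-135.58
r3	desulfonation of isethionate	-48.70
r4	disproportionation of sulfite	-235.52
r4.1	sulfite oxidation	-20.83
r4.2	sulfite reduction	-173.03
r5	sulfate reduction	-152.20
r6	isethionate conversion without hydrogen	-291.26
r7	isethionate conversion with hydrogen	-221.73
r8	oleate and isethionate conversion	-1337.12
r9	methanogenic oleate conversion	-182.57
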