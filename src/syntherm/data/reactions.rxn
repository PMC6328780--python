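# Anaerobic oleate / isethionate reaction network, canonical ASCII dialect.
# One reaction per line, "label: LHS -> RHS"; reference dG0' values and
# descriptions live in reference_dg.tsv.
r1: C18H33O2- + 16 H2O -> 9 C2H3O2- + 15 H2 + 8 H+
r2: 4 H2 + HCO3- + H+ -> CH4 + 3 H2O
r3: C2H5O4S- + H2O -> C2H3O2- + SO3^2- + 2 H+ + H2
r4: 4 SO3^2- + H+ -> 3 SO4^2- + HS-
r4.1: SO3^2- + H2O -> SO4^2- + H2
r4.2: SO3^2- + 3 H2 + H+ -> HS- + 3 H2O
r5: SO4^2- + 4 H2 + H+ -> HS- + 4 H2O
r6: 2 C2H5O4S- -> 2 C2H3O2- + SO4^2- + HS- + 3 H+
r7: C2H5O4S- + 2 H2 -> C2H3O2- + HS- + H+ + 2 H2O
r8: C18H33O2- + 7.5 C2H5O4S- + H2O -> 16.5 C2H3O2- + 7.5 HS- + 15.5 H+
r9: C18H33O2- + 4.75 H2O + 3.75 HCO3- -> 9 C2H3O2- + 3.75 CH4 + 4.25 H+
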