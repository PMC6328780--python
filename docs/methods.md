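# Methods

## Model

The package treats an anaerobic reaction network as a linear space over
chemical species. A reaction is a signed stoichiometric vector (reactants
negative, products positive) with exact rational coefficients; combining,
scaling and decomposing reactions is then ordinary linear algebra, carried
out exactly (sympy rationals for the solves). Energies are the only floats.

### Transformed Gibbs energies

The standard transformed Gibbs energy of a reaction at pH p is

    ΔG°′ = Σ_{i ≠ H+} ν_i ΔGf°_i + ν_{H+} · R·T·ln(10^−p)

with R = 8.314 J mol⁻¹ K⁻¹, T = 298.15 K by default, solutes at 1 M and
gases at 10⁵ Pa. The proton by convention carries no formation energy and
enters only through the pH term; this is the convention under which the
embedded literature constants (Thauer, Jungermann & Decker 1977) were
tabulated, and it reproduces the reference value for hydrogenotrophic
methanogenesis to within 0.1 kJ. Non-standard conditions add
R·T·Σ ν·ln a, with gas species counted as partial pressure over 10⁵ Pa.
No ionic-strength (Debye–Hückel) or temperature corrections are applied,
and CO2/HCO3⁻ speciation is not modelled: the network is written against
HCO3⁻ directly.

### Formation energies and calibration

Nine common species carry literature constants (see
`src/syntherm/data/compounds.tsv`). Oleate and isethionate have no tabulated
values; instead of a group-contribution estimate the package back-calibrates
them so that β-oxidation (r1) and desulfonation (r3) reproduce their
reference ΔG°′ exactly — an algebraic one-unknown solve performed at load
time. This is the faithful choice when the reference energies, not the
underlying group parameters, are the published quantities; the calibration
round-trips to machine precision by construction. Energies of the other
primitive reactions (r2, r4, r4.1, r4.2, r5) are *predictions* from the
constants and agree with the reference values to ≤ 0.12 kJ; the residual
reflects the 1–2 d.p. precision of the constants, and the constants are
deliberately not tuned to close it. Composite reactions accumulate this
drift multiplied by their coefficients (up to ≈0.7 kJ for the 7.5-fold
coupling), which is why composite *consistency* is always checked on linear
combinations of the 2-d.p. reference values (tolerance 0.02 kJ, the
worst-case accumulated rounding) rather than on formation-energy arithmetic.

### Electron bookkeeping

The degree of reduction γ = 4nC + nH − 2nO + 6nS − 3nN − nBr − charge counts
electron equivalents against the reference couple CO2 / H2O / H⁺ / SO4²⁻ /
NH4⁺ / Br⁻ (each reference species has γ = 0). γ is linear in composition
and conserved by any element- and charge-balanced reaction, so Σ ν·γ = 0 is
asserted exactly (rationals) for every network reaction and used as the
electron basis for aggregate recoveries. Elements outside {C,H,O,S,N,Br}
have no declared reference state and raise.

### Syntrophic coupling

`couple_on_intermediate(donor, sink, x)` requires x to be a donor product
and a sink reactant, runs the sink ν_x(donor)/|ν_x(sink)| times per donor
unit, and returns the exact sum; cancellation is perfect because the
arithmetic is rational, and the result is normalised to one formula unit of
the donor. The critical intermediate level solves
ΔG°′ + RT·(Σ_fixed ν ln a + ν_x ln a_x) = 0 in closed form. These
thresholds (e.g. an H2 ceiling of ≈1.6×10⁻⁴ standard-state units for
β-oxidation with all other activities at 1) are illustrations of the
feasibility window, not measured quantities.

## Mass balances

`predict_yields` scales an overall reaction to a substrate dose (mM);
`recovery` reports 100·measured/predicted per product, plus carbon- and
electron-weighted aggregates over the measured product channels. The
aggregates extend the per-product molar accounting and are labelled as such
in reports. A species measured above a zero prediction is flagged, not
divided. Methane is treated as liquid-equivalent mM; headspace partitioning
is out of scope. In the inhibited-enrichment scenario the package simply
reports the stoichiometric isethionate requirement (7.5 mM per mM oleate)
against whatever dose is available — e.g. the ≈3.2 mM produced by one
autoclave cycle on a 20 mM BrES dose — and leaves any deficit visible rather
than explaining it away.

## Synthetic data generator

No kinetic model is asserted anywhere in the analysis; the generator's
first-order substrate decay s(t) = s0·e^(−kt) is the simplest monotone law
consistent with batch-culture curves, and rate constants are user
parameters, never fitted. Products accumulate stoichiometrically from the
consumed substrate (computed with the same float expression the yield
predictor uses, so noise-free recoveries are exactly 100 % bit-for-bit);
co-substrates are drawn down from the dose required for complete conversion;
water and protons are not emitted as observables. Measurement noise is
additive Gaussian per observation, clipped at zero, default σ = 0.1 mM —
the order of typical triplicate error bars (±0.2 mM) in such experiments.
Clipping biases channels only when concentrations are within ~2σ of zero,
which the default scenarios avoid at the final timepoint.

Autoclave hydrolysis of BrES converts, per cycle, a truncated-normal
fraction (mean 0.16, sd 0.015, support [0,1]) of the *remaining* BrES to
isethionate plus an equimolar bromide ion. The 16 % ± 1.5 % figure is
treated as the sd of the generative distribution (whether it was an sd or
an sem of triplicates is not documented; sd is the conservative reading).
Bookkeeping is exact: BrES + isethionate equals the initial dose as a float
identity, not within a tolerance.

Randomness uses `numpy.random.default_rng(seed)` (PCG64) and, for the
truncated normal, `scipy.stats.truncnorm` driven by that generator; the same
seed reproduces identical output across platforms.

What the generator does **not** emulate: growth/OD dynamics, lag phases,
transient intermediates (e.g. the small palmitate peak seen in real LCFA
cultures), autocorrelated or multiplicative measurement error, and gas/liquid
partitioning. Tests passing on synthetic data therefore validate the
balance and recovery arithmetic, not any kinetic inference about real
cultures.

## Numerical choices and degenerate inputs

* Stoichiometry, compositions, charges: exact rationals; decimal
  coefficients such as 7.5 are parsed through their decimal string so they
  stay exact.
* Recoveries compute the ratio before scaling by 100 so that identical
  measured/predicted inputs give exactly 100.0.
* Reactions that cancel to nothing parse to an empty reaction with a
  warning; ΔG°′ of an empty reaction is exactly 0.
* Decompositions are exact: an underdetermined system raises (with the
  rank), an inconsistent one returns a typed infeasibility result carrying
  the exact least-squares residual. Nothing is silently regularised.
* The formula reader accepts unicode minus signs, superscript markup,
  subscript underscores and the `-2`/`^2-` charge dialects; digits before a
  bare trailing sign always bind to the formula (`C2H3O2-` is acetate with
  charge −1), and a caret is required to put a charge magnitude before the
  sign.
* Report output is fixed at 2 d.p. and fully deterministic; CSV outputs
  keep full precision. CLI exit codes: 0 ok, 2 validation failure,
  3 consistency failure.

## Problem sizes

The bundled network has 13 compounds and 11 reactions; property-based suites
run tens of random rational combinations over it, and the stochastic
generator checks use 1000–2000 seeded replicates of small (≤ 20-point) time
courses or single-cycle hydrolysis draws. The whole suite and the
reproduction script each complete in seconds.

## Known limitations

* 25 °C only — no ΔH/ΔS data are embedded, so the temperature field of the
  conditions object rescales RT terms but not formation energies.
* Formation energies for BrES and bromide are absent by design; BrES enters
  only the hydrolysis mass balance, never an energy computation.
* The multi-intermediate case (e.g. simultaneous formate + H2 transfer) is
  not implemented; couplings here are single-intermediate.
* Aggregate carbon/electron recoveries cover only the measured product
  channels; unmeasured products (e.g. biomass) are not imputed.
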