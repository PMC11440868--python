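# Methods

This note documents the models implemented in `frickedose`, the defaults and
their provenance, what the synthetic-data generator does and does not emulate,
and the numerical and design choices that were genuinely open.

## Physical decay and cumulated activity (`decay`)

Activity follows pure physical decay, A(t) = A₀·2^(−t/T½); the decay constant
is always derived from the half-life, never stored separately. ¹⁸F is shipped
with T½ = 109.77 min, β⁺ branching 0.9686 and mean positron energy 249.8 keV
(standard nuclear data); any other emitter is a `Radionuclide` value away.
Internal time is minutes; cumulated activity is reported in MBq·h, with the
unit conversion confined to the reporting boundary.

Cumulated activity Ã is available two ways:

* analytically, (A₀/λ)(1 − e^(−λt)), which for t → ∞ is A₀T½/ln 2 =
  2.639 MBq·h per MBq of ¹⁸F;
* by the trapezoid rule over sampled points, optionally adding the analytic
  tail A(t_last)/λ. The tail assumes physical decay only — the stated
  assumption of the vial experiments; biological clearance exists solely as a
  mono-exponential factor inside the synthetic generator.

The trapezoid rule overestimates the integral of a convex decaying
exponential; on the hourly 0–4 h grid used for vial PET data the result is
2.664 MBq·h/MBq, ~1 % above the analytic limit — a grid-dependent bias the
tests assert explicitly (it vanishes quadratically under refinement).

## Dosimeter equation (`fricke`)

Dose is strictly linear in the background-corrected absorbance change; all
constants are carried in a frozen `FrickeConstants` value with the reference
defaults (R_F = 1.0032, K_vial = K_dd = K_E = 1.00, ρ = 1.0227×10⁻³ kg cm⁻³,
l = 1 cm, εG = 3.5060 or 3.498 cm² J⁻¹ for ⁶⁰Co and ¹⁸F respectively). εG is
selected per radiation quality via the two constructors; other qualities
require an explicit value, since the low-LET energy independence of G(Fe³⁺)
is an approximation we do not extrapolate silently. εG for ¹⁸F is treated as
a given constant; its derivation is not modelled. K_E is fixed at 1.00 — no
temperature model.

Two deliberate behaviours: negative background-corrected differences are kept
(and logged), not clipped, because the FDG-control correction is small and
clipping would bias low-dose noise upward; and `delta_od_for_dose` is the
exact algebraic inverse, round-tripping to machine precision, because the
synthetic generator and the external-beam calibration curve both need it.

## Radiolysis kinetics (`kinetics`)

The seven elementary reactions are hard data (25 °C rate constants spanning
52 to 2.66×10¹⁰ M⁻¹ s⁻¹); element and charge balance of every reaction is
asserted at network construction. The printed form of the H·+Fe²⁺ reaction
omits the solvent water molecule that balances it; we carry H₂O explicitly on
the reactant side as a non-dynamic (solvent) participant. H₂ and OH⁻ are
tracked as inert sinks for mass-balance bookkeeping.

Primary yields default to the standard 0.4 M H₂SO₄ values g(e⁻_aq)+g(H·) =
3.70, g(·OH) = 2.92, g(H₂O₂) = 0.78 per 100 eV. Only the sum of the reducing
yields is physically meaningful here: the e⁻_aq/H· split (2.90/0.80 by
default) is immaterial because reaction 1 converts hydrated electrons to H
atoms within nanoseconds in 0.4 M acid — this is also why the closed form
counts e⁻_aq inside "3G(H·)", which is what reproduces the aerated yield of
15.58 ions/100 eV (anoxic: 8.18, the H-atom factor dropping from three to
one). Each primary e⁻_aq is injected together with a charge-balancing proton.

Other chemistry defaults: [H⁺] = 0.4 M (first dissociation of H₂SO₄ complete,
second suppressed; only the two fast H⁺ reactions depend on it, weakly, since
H⁺ is in ~400-fold excess); air-saturated [O₂] = 0.25 mM at 25 °C. The
per-100 eV ↔ mol/J conversion (1.0364×10⁻⁷) lives in exactly one constant.

Numerics: the system is stiff (nine orders of magnitude in rate constants,
radical quasi-steady states near 10⁻¹² M), so `scipy.integrate.solve_ivp`
with the BDF method is used at rtol = 10⁻⁸, atol = 10⁻¹⁶. Yield measurements
append a source-free relaxation leg after the irradiation: the Fenton step
Fe²⁺+H₂O₂ has a ~19 s timescale at 1 mM Fe²⁺, and reading Fe³⁺ before it
completes understates the yield. 300 s (>15 time constants) is the default in
tests. Oxygen-depletion times are found with a terminal ODE event at 1 % of
the initial [O₂]; because the event root lands between `t_eval` points, the
event state itself is appended to the trajectory.

Out of scope: track-structure/spur chemistry, LET and dose-rate dependence of
the primary yields, and glucose/FDG scavenging chemistry — the dosimeter is
simulated as the pure Fricke system.

## Calibration (`calibration`)

Both calibration lines are forced through the origin (zero activity must give
zero signal), slope = Σxy/Σx². For a forced-origin fit the centered R² is not
meaningful and gives ≈0.97 on the reference series; the **uncentered**
convention R² = 1 − SS_res/Σy² (≈0.994) is therefore fixed and documented.
Points are unweighted by default (no weights are stated for the source data);
a weight vector is accepted behind a keyword. Slope uncertainty is the usual
residual-based standard error with n−1 degrees of freedom — the published
"±" figures have an unstated derivation and are matched only qualitatively.

The conversion factor is the slope ratio C = (Gy/MBq)/(MBq·h/MBq). Two
published values of C coexist (0.064 and 0.090 Gy/MBq·h); 0.064 is the
default, 0.090 is selectable, and dose reports name the value they used in
their header rather than adjudicating.

## PET quantification (`pet`)

ROI series are assumed already reconstruction-corrected (decay, dead time,
crystal efficiency), as scanner software emits them; the `decay_corrected`
flag records whether values were referred back to injection time, and the
physical series is recovered by multiplying with 2^(−t/T½) before
integration. The phantom calibration factor is simply (true MBq/mL)/(measured
cps/mL) from a uniform phantom (reference: 2.02 MBq in 25.7 mL). Tissue
density defaults to 1.0 g/mL unless supplied. Scan-time compensation and any
image-domain correction are out of scope.

## Organ dosimetry (`organ`)

The conversion-factor method D = Ã/g·M·C is documented as a self-dose
(local-energy-deposition) estimate — appropriate for short-range positrons —
and cross-fire enters only through user-supplied S-values in the MIRD sum.
Organ masses have **no defaults**: the study-specific mass and S-value tables
are not publicly available, so a missing mass is an error, never a silent
assumption. The package ships a clearly-labelled synthetic mouse fixture
(masses and local-deposition self-S-values generated in `synth`; the tumor
mass of 0.126 g is back-solved from a published dose and the rest are
plausible nude-mouse values). Missing S-value pairs contribute zero with a
warning.

## Synthetic data (`synth`)

The generator emits every input format the pipeline reads, under the stated
experimental design: activities (15, 20, 30, 40, 60, 80) MBq, OD readings at
(0, 30, 60, 110, 240, 350, 430, 1450) min, ground-truth dose per activity
0.17 Gy/MBq, vial TACs sampled hourly to 4 h, dynamic organ TACs over
0–120 min.

Dose accrues with the cumulated-activity fraction, D(t) = 0.17·A₀·
(1 − e^(−λt)) — rapid growth over the first ~4 h, then a plateau. The OD
reading is blank + FDG offset + ΔOA(D(t)) + noise.

Noise models, simplest consistent with the reported variability:

* OD: Gaussian with sd proportional to the radiation-induced increment
  (cv default 0.03, matching the reported 0.5–2.9 % spectrophotometer
  repeatability). Proportional rather than absolute, so that "3 % OD noise"
  is exactly cv = 0.03 regardless of blank absorbance.
* PET values: proportional Gaussian (cv 0.02).
* Inter-animal variation: lognormal on the organ uptake fraction, with
  per-organ σ chosen to reflect the reported biodistribution scatter.

The end-to-end recovery pipeline corrects each vial's final dose for the
small residual decay beyond the last reading (dividing by 1 − e^(−λt_last)),
which makes the noiseless recovery exact rather than 10⁻⁴-biased.

What a green recovery test establishes: that the pipeline inverts its own
generative model (identifiability, absence of unit/convention bugs, correct
propagation at realistic noise). What it does not establish: accuracy under
real-data pathologies — FDG scavenging chemistry, oxygen depletion at high
dose, partial-volume and spill-over effects in PET, non-exponential biology —
none of which the generator emulates.

## Known limitations

* The dosimeter model is valid in the linear, aerated regime (≲400 Gy,
  oxygen not depleted); the kinetics module can check the oxygen budget but
  the dose equation itself has no saturation model.
* MIRD results are only as good as the supplied S-table; the shipped one is
  an illustrative local-deposition construction, not a phantom computation.
* Published per-animal averaged uptake tables are not reproducible from
  their own normalized columns (averaging order unstated); such columns are
  treated as inputs, never as oracles.
* The "calculated decay activity" columns of the source vial experiment
  deviate up to ~10 % from pure exponential decay of the stated initial
  activities; pure decay is used as ground truth and those columns are not
  asserted against.
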