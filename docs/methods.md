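# Methods

## Model structure and assumptions

The body is lumped into eight perfused compartments — venous blood,
arterial blood, lung, liver, kidney, gut wall, a richly perfused lump
(brain, heart, spleen, endocrine) and a poorly perfused lump (muscle,
skin, adipose, bone).  Tissues are perfusion-limited,
`dA_T/dt = Q_T (C_art − A_T/(V_T·Kp_T))`; the liver additionally receives
the portal outflow of the gut wall.  This resolution is deliberately
coarse: lisinopril is hydrophilic, does not bind plasma proteins, is not
metabolised and is cleared exclusively by glomerular filtration, so organ-level
detail beyond the kidney, liver and gut adds parameters without
information.  Partitioning uses one scalar on tissue water fractions
(`Kp = s·wf_T`), appropriate for a non-binding hydrophilic solute; the
scalar is solved in closed form from the steady-state distribution volume
anchor (0.89 L/kg).

Lisinopril's slow, saturable binding to tissue ACE produces a long,
low-amplitude terminal phase.  We approximate it with a **linear** deep
compartment exchanging with venous plasma (k_in, k_out), calibrated to the
multiple-dose trough series.  This reproduces single- and multiple-dose
kinetics at therapeutic doses but, being linear, cannot reproduce the
sub-proportional exposure seen across widely spaced IV doses (the
packaged validation table carries the three IV dose levels; only the
2.97 mg level is a calibration anchor, and the model is exactly
dose-proportional by construction).

Renal elimination is `CL_R · C_ven`, removed from the venous compartment
itself and capped at kidney plasma flow.  Referencing dosing, sampling and
elimination to the same (venous) compartment makes the moment identity
`Vss = D·AUMC/AUC²` exact for this model, which is what lets the partition
solve and the moment analysis round-trip to 0.1 %.

### Absorption

The lumen is a five-segment transit chain (stomach, duodenum, jejunum,
ileum, colon), each segment with a solid and a dissolved state.  Release
is first-order with `k = −ln(0.2)/(t80/60)` so that exactly 80 % is
released at t80 = 30 min; at a solubility of 97 g/L dissolution is never
rate-limiting (the simulator tracks the peak lumen concentration, which
stays below 0.1 % of solubility at 20 mg).  Absorption flux per segment is
`Peff · SA_seg · w_seg · C_dissolved` with cylindrical geometry
(`SA = 2πrL`, lengths scaling with height, radii with an age table), so
the rate constant scales as `2·Peff·w/r` — children absorb somewhat faster
per unit lumen volume, which raises pediatric bioavailability as their gut
calibre shrinks.

Two structural constants required care.  The regional weights
`w = 0.2 / 0.6 / 1.0 / 0.1` (duodenum/jejunum/ileum/colon) follow the
distally **increasing** expression of the intestinal peptide transporter
PEPT1 that carries lisinopril; the absolute scale lives in the calibrated
effective permeability, so only the profile matters.  The mean
small-intestinal residence is set to 6.5 h (split across segments by
length; stomach 0.25 h fasting, colon 15 h), at the upper end of the
published human range.  Both choices are driven by the drug's reference
kinetics: the trough series pins the fast-phase half-life near 5 h, so a
6 h time-to-peak is only possible if absorption flux persists to ~6 h —
i.e. an effective absorption window extending through the distal ileum.
A front-loaded absorption profile with a 3.5 h window cannot produce the
observed peak time for any permeability value.  With these constants fixed
once, a single calibrated permeability reproduces Cmax, AUC and Tmax
simultaneously.

The only fed-state mechanism is gastric emptying: a meal multiplies the
gastric residence time by `1 + α·kcal/524` with α calibrated.  Because
nothing else changes, oral bioavailability is identical fed vs fasting
(the model's food-effect AUC ratio is 1.01), the peak is delayed and
lowered — the qualitative pattern reported for this drug.

## Calibrated parameters

| Parameter | Units | Fitted value | Anchor |
| --- | --- | --- | --- |
| kp_scalar | – | ≈ 0.30 | Vss 0.89 L/kg (closed form) |
| CL_renal (adult, 70 kg) | L/h | ≈ 4.12 | IV 2.97 mg AUC₀₋₇₂ = 682 ng·h/ml |
| Peff | cm/h | ≈ 0.038 | oral fasting Cmax 86, AUC₀₋₁₂₀ 1231 |
| k_in, k_out (deep) | 1/h | ≈ 0.12, 0.0096 | troughs day 1 = 8.40, day 10 = 12.79 ng/ml |
| α (fed delay slope) | – | ≈ 9.2 | fed Cmax 69 ng/ml, Tmax 6.8 h |

The printed literature clearances for this drug are mutually inconsistent
(0.56 ml/min/kg, 47 ml/min and 2.82 L/h are all quoted for the same
quantity), so clearance is identified from the IV exposure instead, with
the printed 2.82 L/h seeding the search bracket only.  The fitted
~4.1 L/h is what the IV AUC actually implies (Dose/AUC∞).  The fitted
Peff is an effective lumped constant on the package's own geometry and is
not comparable to permeability values quoted for other gut models.

### Staged identification

Each outer pass runs: (1) partition scalar — closed-form solve including
the current deep-exchange volume; (2) clearance — golden-section on the IV
AUC; (3) permeability — golden-section in log₁₀ Peff against Cmax, AUC
and (at half weight, being a coarse-grid quantity) Tmax; (4) deep exchange
— Nelder–Mead in log(k_in), log(k_out) against the day-1/day-10 troughs,
re-solving the partition scalar inside the objective so the Vss anchor is
never violated; (5) food effect — golden-section on α.  The food-effect
stage runs last because every other anchor is a fasting protocol, so α
inherits the final disposition and feeds back into nothing.  The outer
loop is a block-coordinate fixed-point iteration that stops when no
parameter moves by more than 0.1 % (at most 8 passes; the packaged set
converges in ~6).  All stages are deterministic: identical observations
give bit-identical results.  The objective is `Σ w·ln(pred/obs)²` —
scale-free across metrics with different units — with a documented penalty
constant (10⁶) for non-positive predictions.

## Numerical choices

* The full system is linear and time-invariant between dose events, so the
  default integrator propagates `exp(A·Δt)` exactly over the uniform
  output grid (0.05 h).  Conservation, dose linearity and superposition
  then hold to ~10⁻¹³, and simulation is fast enough to run
  2 500 population-dose simulations in ~15 s.  An adaptive stiff LSODA
  route with rtol 10⁻⁸/atol 10⁻¹⁰ is retained and cross-checked against
  the matrix-exponential route in the test suite.
* IV bolus runs use a finer 0.005 h grid: the venous mixing transient
  after a bolus has a ~0.6 min time constant, and trapezoidal integration
  on a 3 min grid would bias the AUC by 1–2 % (enough to break the Vss
  round-trip at its 2 % band).
* Tmax is reported at the grid point of the (first) maximum; no
  interpolation.
* AUC∞ extrapolates the tail as `C_last/λz` with λz from a log-linear fit
  over the last 20 % of the time span; the moment analysis warns when the
  extrapolated tail exceeds 20 % of AUC∞.
* Dose times must fall on the output grid (they do for all shipped
  protocols); the trough reader uses the grid value at `k·τ`, which for
  oral dosing is the pre-dose concentration because an oral dose event is
  discontinuous only in the stomach, not in plasma.

## Virtual populations

Anthropometry comes from a built-in median growth table (piecewise-linear
in age) whose anchors include the worked-example weights (10 kg at 1 y,
17 kg at 5 y, 40 kg at 12 y, 60 kg at 17 y) and whose male track reaches
exactly 70 kg / 170 cm in adulthood; a ±3 % sex offset ramps in over ages
12–15.  Sampling draws ages uniformly within the group band, multiplies
median height by a lognormal factor with CV 10 % (the stated height SD),
and co-varies weight as `w = w_med·(h/h_med)²`, i.e. BMI is held at the
age-typical median.  Female counts are exact (round-half-up of
`n·prop_female`).  Organ volumes are fixed fractions of body weight
(with an infancy surcharge on the richly perfused lump for the relatively
large brain), flows are fixed fractions of an allometric cardiac output
`336·(W/70)^0.75 L/h`, and renal clearance scales as
`(W/70)^0.75 · f_GFR(age)`, with GFR maturation a Hill sigmoid in
postmenstrual age (hill 3.4, TM50 47.7 weeks) that passes 90 % of the
adult level just before the first birthday.

## Dose classification

Each grid dose is labelled from the population min/mean/max of Cmax and
AUC₀₋₁₂₀ against the adult window (Cmax 38–124 ng/ml, AUC 611–1851
ng·h/ml): **green** when even the maximally exposed subject is inside the
window for both metrics, **blue** when the AUC min and mean are inside,
**yellow** when even the minimally exposed subject reaches the window for
both metrics; otherwise out, with precedence green > blue > yellow when
several hold.  These are three independent screens (a safety screen, a
central-tendency screen and an efficacy-floor screen), not nested ones;
the rule set is isolated in one function (`dosefind.classify_dose`)
because reasonable alternatives exist.  Tmax is reported but never
classifies — its population spread under a transit-chain model is narrow
and uninformative at the 0.05 h grid.  The recommended range is the
lowest-to-highest grid dose whose label is not "out"; endpoints are
restricted to grid members.

## Synthetic data

`gen_observed` emulates a sampled clinical study: sparse schedule
(0.5–120 h, 13 samples), per-sample multiplicative lognormal error
`exp(N(0, σ))` with `σ = √ln(1+cv²)` — median-unbiased, positivity
preserved.  `gen_reference_observation_set` emulates the *summary tables*
such studies publish: per-subject lognormal scale factors on the whole
profile, geometric-mean aggregation across subjects, default noise CV 15 %
in line with the 6–60 % inter-individual variability reported for this
drug.  Every generated subject defaults to the age-29 reference adult, so
the zero-noise set reproduces the model metrics exactly and the
calibration workflow recovers the generating parameters to < 0.1 % — the
package's parameter-recovery oracle.  What these generators do **not**
emulate: between-subject parameter variability in clearance or
permeability (variability enters only as an observation-scale factor or
sampling of demographics), assay quantification limits, and censoring.
Passing recovery tests therefore demonstrate identifiability of the
staged workflow under the assumed error model, not robustness to model
misspecification.

## Problem sizes

The shipped analyses use the reference study sizes: 18 fasting adult males
(21–37 y) for the oral protocols, the single age-29 reference male for
IV/trough/fed anchors, and 100 subjects (50 % female) per pediatric group
for dose finding.  The calibration converges in about ten seconds and the
full pediatric search in well under a minute on one CPU.

## Known limitations

* Linear ACE-binding surrogate: no dose-dependent bioavailability or
  clearance; exposure is exactly proportional to dose.
* pKa is stored but ionisation is not modelled; regional gut pH plays no
  role (defensible for a zwitterion absorbed by a carrier, but untested).
* The fed state affects gastric emptying only; bile, splanchnic flow and
  luminal volume changes are not represented.
* Conventional-dose comparisons reproduce printed tables whose own
  rounding is inconsistent cell-to-cell; the report applies one stated
  rule (two decimals below 10 mg, integer above) and the tests compare at
  each printed value's own precision.
* The adult reference BSA implied by published BSA-dose tables varies
  (≈1.82–1.92 m²); the package defaults to 1.73 m² and exposes the
  parameter.
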