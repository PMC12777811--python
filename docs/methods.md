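# Methods

## The estimation problem

In a lymph-duct-cannulated animal, lymph-borne drug is diverted out of
the body, so the oral serum profile reflects portal absorption only,
while the collected lymph carries the lymphatic route directly. The
package computes, per animal and period:

- `F_AL` by mass balance over timed lymph collections: the drug amount
  in interval *i* is `C_i × V_i` (aliquot concentration × collected
  volume), cumulated in time order and expressed as percent of dose.
  The aliquot concentration is treated as the flow-weighted mean over
  the interval, which makes `C × V` the exact interval mass. Aliquot
  withdrawal (2 ml per interval in practice) is ignored in the balance
  since it is small against interval volumes of tens of ml.
- `F_AP` from the dose-normalized serum AUC ratio against a separate
  intravenously dosed animal, `100·(AUC_ent/D_ent)/(AUC_iv/D_iv)`.
- `F = F_AL + F_AP` and `F_RL = 100·F_AL/F`, both identities enforced
  exactly on every result object (`F_RL` is defined as 0 when
  `F_AL = 0`, and `F = 0` with `F_AL > 0` is rejected as inconsistent).

All derived quantities (ratios, `F_RL`) are computed per animal and then
summarized, so group means of ratios do not equal ratios of group
means — the convention of within-subject cross-over reporting.

### Truncated mode

For cross-species tables both `F_AL` and the oral AUC are cut at a
common time `t*` (8 h by default): `F_AL` keeps only intervals ending at
or before `t*` and `AUC_ent` becomes `AUC[0, t*]`. The IV reference is
always normalized by its full `AUC_inf` — the reference animal's
disposition is not truncated by the design, only the oral observation
window is. This choice is configurable and recorded in every output
ledger.

## Non-compartmental engine

- **AUC/AUMC**: linear trapezoid on the actual sampling times,
  everywhere including the descending limb. Boundary times between
  samples are linearly interpolated first, making the AUC additive over
  adjacent sub-intervals to machine precision. Extravascular profiles
  get an imputed `C = 0` at `t = 0` when the first sample is post-dose;
  IV boluses get a `C(0)` back-extrapolated log-linearly from the first
  two declining samples (falling back to carrying the first value back
  when the start does not decline).
- **λz**: ordinary least squares on `ln C` vs `t` over every suffix of
  ≥ 3 positive points strictly after Tmax; the suffix with the highest
  adjusted R² wins and ties go to the longer tail. A negative slope is
  required; when no admissible tail exists the terminal fit is absent,
  `AUC_inf` is undefined and the result carries an explicit warning
  rather than a number. On an exact mono-exponential every suffix is an
  exact fit, so the estimate is exact regardless of the selection rule.
- **Extrapolation**: `AUC_inf = AUC_last + C_last/λz` with the
  *observed* last quantifiable concentration (not the λz-predicted
  one); the percentage extrapolated is reported and flagged above 20%.
- **IV disposition**: `CL = D/AUC_inf` (so `CL·AUC_inf = D` holds by
  construction), `MRT = AUMC_inf/AUC_inf` with the bolus formula and no
  infusion correction, `Vss = CL·MRT`, per-kg variants when a
  bodyweight is supplied.
- **BLQ policy**: observations below the LLOQ (1 ng/ml by default)
  before the first quantifiable point are set to 0 (pre-dose
  convention); embedded and trailing BLQ observations are dropped.
  Substitution by LLOQ/2 was deliberately not used; every edit is
  logged on the returned profile. BLQ lymph aliquots contribute zero
  mass to `F_AL`, which is conservative.
- **Tmax ties** break to the earliest time.

Units are fixed internally (h, ng/ml, ml, mg; CL in l/h, volumes in l)
with the single conversion constant 1 mg = 10⁶ ng applied at module
boundaries.

## The simulator

A linear, constant-coefficient compartment system per animal:

- gut depot `fa·D` emptying at `ka` (the unabsorbable `(1−fa)·D` never
  enters the system);
- absorbed flux splits `φ_lymph` into a lymph compartment drained at
  `klt` into the cannula, where the drained mass is **permanently
  removed** (collected), and `(1−φ_lymph)` through the liver where
  fraction `eh` is extracted first-pass, the rest entering the central
  compartment;
- central volume `vc`, elimination `cl/vc`, optional peripheral
  exchange `k12`/`k21`.

This is the minimal mechanism that reproduces the cannulated design
while making the transport fractions identifiable closed-form truths:
`F_AL = 100·fa·φ_lymph`, `F_AP = 100·fa·(1−φ_lymph)·(1−eh)`.
Formulation effects (chylomicron stimulation by long-chain
triglycerides) are encoded solely through `φ_lymph` and `ka`; there is
no lipid-digestion submodel, no enterohepatic recirculation and no
PBPK gut.

**Numerics.** The system is propagated between output times with the
matrix exponential of the 7-state rate matrix — exact for a linear
system — rather than an adaptive ODE solver. Mass balance
(states + collected + eliminated + first-pass + unabsorbable = dose) is
asserted at every output time to 10⁻⁶ relative and holds in practice to
~10⁻¹⁴; non-finite or negative solutions fail hard naming the parameter
set.

**Observation model.** Serum concentration is central amount / `vc` at
the scheduled times. Each lymph interval reports volume = flow draw ×
width (flow log-normal around the mean with the configured CV;
deterministic when the CV is 0) and concentration = drained mass /
volume, so the recorded mass is exact regardless of flow noise — as in
the real assay, where volume and aliquot concentration are both
measured. Measurement error multiplies every concentration by
`exp(ε)`, `ε ~ N(0, σ)` with `σ = √ln(1+CV²)` (mean-1 multiplicative
error); values below the LLOQ are flagged BLQ. Every stochastic
operation takes an explicit seed; there is no global RNG state.

### Study conditions (generator defaults)

The default cross-over emulates the reference cannulated-pig design:
3 animals, two periods (oil solution vs nanoemulsion, order
alternating), 200 mg oral doses; 13 serum samples and 13 contiguous
lymph intervals at 1–12 and 24 h; one separate IV animal (20 mg;
sampling 5, 15, 30 min, 1, 1.5, 2, 2.5, 3, 4, 6, 8, 12, 24 h; no lymph
sampled); LLOQ 1 ng/ml; mean lymph flow 70 ml/h (centre of the observed
36–109 ml/h range) with 25% between-interval CV; 30% inter-animal and
15% residual log-normal CV — typical magnitudes for small-animal-number
PK work.

Per-animal parameters are drawn log-normally around the formulation
means with multipliers on `fa`, `φ_lymph`, `ka`, `klt`, `cl`, `vc`
shared across the animal's two periods (disposition and absorption
capacity are animal properties); `eh` is left fixed and fractions are
capped at 0.99 to respect [0, 1]. Truth sidecars are computed from the
realized per-animal parameters, so recovery is well defined under
variability.

The default parameter sets are *fixtures, not claims*: disposition is
anchored to the measured IV values (`cl = 33.6` l/h; `vc = 40` l with
`k12 = 1.7`, `k21 = 0.25` giving `Vss = vc(1+k12/k21) = 312` l and a
terminal half-life near 9 h), and the fractions are chosen so simulated
outputs fall in the observed ranges — oil solution `fa = 0.35`,
`φ_lymph = 0.035`, `eh = 0.85` (F ≈ 6.3%, F_RL ≈ 19.5%); nanoemulsion
`fa = 0.55`, `φ_lymph = 0.0182`, `eh = 0.85` (F ≈ 9.1%, F_RL ≈ 11%);
lymph/serum concentration ratios ~10².

### What the generator does not emulate

First-order gut emptying with fast two-compartment distribution puts
the simulated serum Tmax at the first post-dose sample, earlier than
the 3–5 h observed in vivo (which would require transit-compartment
absorption); lymph appearance kinetics, by contrast, peak realistically
at 2–6 h. There is no blood contamination of lymph, no food effect, no
enterohepatic recirculation, and residual errors are independent across
samples. Passing recovery gates therefore shows the *estimators* are
faithful under the stated error model, not that the model captures
every feature of real cannulated-animal data.

## Statistics

Two-sided tests at α = 0.05 throughout, no multiplicity correction and
no period/sequence adjustment (matching the small-n cross-over
reporting convention): paired t-test across formulations
(within-animal), Student's equal-variance t-test between independent
groups with Welch behind a flag. Degenerate inputs are reported
explicitly: identical samples give `t = 0, p = 1`; a zero-variance
non-zero difference is flagged degenerate with an undefined p rather
than `p = 0`. Summaries report mean ± sample SD (n−1), with SD absent
(not 0) for singleton groups, and significance markers driven by the
comparison results.

## Validation gates

- Noise-free grid over `φ_lymph ∈ {0.05…0.5}` (20 animals each, 24 h
  collection): `F_AL` recovered within 5% relative (observed ≤ 0.06%;
  the residual is drug still in lymph transit at 24 h) and `F_RL`
  within 2 percentage points (observed ≤ 0.9).
- 200 animals with 15% residual error: median |F_RL error| below 3
  percentage points (observed ≈ 0.9–2).
- One-compartment limit: simulator matches the analytic solution
  pointwise to 10⁻⁶ relative (observed ~10⁻¹⁴); trapezoidal AUC error
  shrinks at second order under grid refinement.
- Both t-tests show type-I error within the 3σ binomial band of 0.05 at
  2000 simulated nulls.

Problem sizes (200-animal cohorts, 2000 statistical replicates) keep
the full validation under ~10 s while leaving Monte-Carlo error well
inside the gates.

## Known limitations

Sparse 13-point sampling biases trapezoidal AUCs upward by 1–3% on
convex decays (visible as a small systematic `F_AP` offset that largely
cancels in the oral/IV ratio); a single IV reference animal makes every
`F_AP` in a study share that animal's estimation error and biological
offset — a design property, not an implementation one; `λz` from the
24 h-truncated oral schedule contaminates slightly with absorption when
`ka` is within an order of magnitude of the terminal rate. The readers
accept only the documented CSV schemas (hours, ng/ml, ml, mg) and
reject other units by name rather than converting.
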