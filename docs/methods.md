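# Methods

## Pairing model and rate estimators

N₂ formation is modeled as molecule-by-molecule assembly from two nitrogen
atoms. A denitrification molecule draws both atoms independently from the
nitrite/nitrate pool, labeled at fraction Fₙ; an anammox molecule draws one
atom from the ammonium pool (fraction Fₐ) and one from the nitrite pool.
The isotopologue production rates are therefore mixtures of Bernoulli
pairings and always conserve total production, P28 + P29 + P30 = A + D.
A discrete Monte-Carlo oracle (`pairing_oracle`) that literally draws
molecules and atoms provides an implementation-independent check of these
closed forms; agreement is verified within three binomial standard errors
at 10⁶ draws over a grid of rate shares and label fractions.

The inverse estimators are the unique algebraic inversion of the forward
model for each treatment:

* ¹⁵NO₂⁻ (Fₐ = 0): `D = P30/Fₙ²`, `A = (P29 − 2Fₙ(1−Fₙ)D)/Fₙ`. When the
  nitrite pool is fully labeled (Fₙ = 1, the case when background nitrite is
  below detection) this reduces to D = P30, A = P29.
* ¹⁵NH₄⁺ (unlabeled nitrite): `A = P29/Fₐ`. D leaves no labeled signature
  and is reported as NaN, not zero. A statistically significant ³⁰N₂ slope
  in this treatment contradicts the model assumptions (it implies a labeled
  nitrite pool or another ³⁰N₂ source) and raises a warning rather than an
  error.

Model assumptions worth stating: rates are zero-order over the incubation
(tracer consumption is negligible — production of a few nmol L⁻¹ d⁻¹
against µmol L⁻¹ substrate pools turns over ≪1% of the pool in 48 h);
labeled fractions are constant in time; the two pools mix ideally; no
nitrification, DNRA or N-fixation re-routes label between pools during the
incubation.

## Slope fitting and uncertainty

Excess ²⁹N₂ and ³⁰N₂ (nmol per liter of incubation water) are regressed on
time separately by ordinary least squares. Because sampling is destructive,
every bottle is an independent observation, so all replicates enter one
pooled fit per isotopologue (time-point averaging is available as an option
but discards the replicate-level scatter the standard errors need). Times
are entered in hours and divided by 24 inside the fit so slopes are per
day. Detection is a one-sided t-test of slope > 0 at configurable α
(default 0.05). Rate standard errors come from the delta method treating
the labeled fractions as exact:
se(D) = se(P30)/Fₙ², se(A) = √[(se(P29)/Fₙ)² + (2(1−Fₙ)/Fₙ² · se(P30))²],
with the two slopes treated as independent (separate fits on independent
noise). Negative point estimates are reported unclamped with a warning and
`detected = False`; truncation at zero would bias ensemble statistics.

A pairs bootstrap (`bootstrap_rates_nitrite_label`) offers a
delta-method-free alternative: whole bottles are resampled with
replacement — valid because destructive sampling makes bottles independent
— and the fit-and-invert chain is re-run per replicate. A stratified
(within-time) variant was rejected: with three bottles per stratum it
freezes the group-mean component of the residual and understates slope
variance.

In `recovery_experiment`, confidence intervals use t quantiles with
n_points − 2 degrees of freedom from the pooled fit. Under the default
design (15 bottles) the nominal 95% intervals cover the true rates at
measured frequencies near 0.95 (validated over 500 replicates at noise
SD 0.5 nmol L⁻¹).

## Headspace partitioning

Inputs begin at excess isotopologue amounts; if those are measured as
headspace amounts, `headspace_to_aqueous` normalizes by the water volume.
An optional dissolved-gas correction scales the headspace amount by
(1 + β·V_water/V_headspace) with a Bunsen-type coefficient β (default
0.015, the order of N₂ aqueous/gas partitioning near 15 °C). The correction
is off by default, matching a headspace-only measurement protocol; because
it is a constant multiplier it rescales rates but cancels from the A/(A+D)
contribution.

## Synthetic incubations

`simulate_incubation` draws bottle observations around the exact forward
model (excess = P·t) with additive Gaussian noise of configurable SD, the
simplest model consistent with linear accumulation plus instrument scatter;
a multiplicative-noise option exists for variance growing with signal.
Defaults are the emulated study conditions: triplicate bottles at
0/14/24/36/48 h, 30 mL water with an 8 mL headspace at 15 °C, true rates
A = 3.5 and D = 0.7 nmol N₂ L⁻¹ d⁻¹ with a fully labeled nitrite pool. The
replicate-level noise SD is a free parameter (no published replicate
scatter constrains it); the default 0.5 nmol L⁻¹ puts the 48-h signal-to-
noise near 14 for ²⁹N₂ — a clean but not noiseless experiment. The
generator does not model pool dilution over time, Michaelis–Menten uptake,
or oxygen intrusion; passing recovery tests therefore validates the
estimator chain, not robustness to those real-world violations.

All generators take one integer seed; replicate r of a recovery experiment
uses seed + r, so reports are bit-reproducible.

## Marker survey generator

`simulate_marker_survey` places wells evenly along an oxygen gradient
(default 2–100 µmol L⁻¹, 7 wells) and draws log-normal marker abundances:
16S at 10⁸ copies L⁻¹, a hzsA hotspot of 10⁷ at the anoxic end suppressed
by oxygen at `effect_size` (default −0.03 log₁₀ units per µmol O₂ L⁻¹,
spreading the hzsA/amoA ratio over ≈3 decades across the gradient), other
functional genes at 10⁴–10⁶, transcripts one decade below genes, per-marker
log₁₀ SD 0.3, detection limit 10³ copies L⁻¹. Under these defaults the
gene-level index pipeline recovers a significant negative
hzsA/amoA-vs-oxygen correlation (exact p < 0.05) in ≈99% of seeded runs.
At the transcript level, hzsA transcripts at the oxic end fall below the
detection limit in a fraction of runs; those wells are excluded from the
ratio (see below) and the smaller n lowers the power of the exact test to
≈86% — the same mechanism that forces the exclusion of near-detection-limit
wells in real surveys.

## Index definitions and decisions

* hzsA/amoA ratio: hzsA copies over the sum of archaeal + bacterial amoA,
  computed separately for genes and transcripts.
* Below-detection policy: measurements below the quantification limit are
  excluded from ratios, not imputed (no LOQ/2 substitution). If exactly one
  amoA domain is below detection the ratio is computed against the
  quantified domain and flagged `partial`; if hzsA or both amoA domains are
  below detection the well is excluded with a recorded reason.
* nirS/16S: gene-level only (denitrifier proportion proxy); a zero or
  below-detection 16S denominator flags the well rather than producing an
  infinite ratio.
* Ladderane relative concentration: ([3]-FAME + [5]-FAME peak area) / C19:0
  internal-standard peak area per well and date; values < 0.01 are flagged
  below detection. Fold contrasts between wells are undefined (NaN + flag)
  when the denominator well is below detection or zero.
* Spearman correlation: average ranks for ties; two-sided p by full
  enumeration of all n! rank permutations for n ≤ 8, seeded Monte-Carlo
  permutation (10⁵ draws, add-one correction) for n = 9–10, and the t
  approximation beyond. The permutation count uses |ρ_perm| ≥ |ρ_obs| with
  a 10⁻¹² tolerance against floating-point ties. A constant index returns
  ρ = 0 with a `degenerate` flag instead of NaN propagation. Exact and
  t-approximate p-values agree within 0.02 by n = 10.

## Numerical choices and degenerate inputs

* Slope fitting requires ≥3 distinct time points; a single time point is a
  degenerate design and raises.
* A perfectly noise-free series yields se = 0; the one-sided p-value is then
  taken as 0/0.5/1 by the slope's sign rather than dividing by zero, and an
  all-zero series reports r² = 0 (the centered fit is undefined).
* Fₙ = 0 (or Fₐ = 0 for the ammonium treatment) is non-identifiable and
  raises, rather than returning infinities.
* A/(A+D) with A + D = 0 is undefined and returned as NaN with a flag.
  Negative rates propagate raw by default; an explicit clamp option pins
  the contribution into [0, 1] and flags that it did.
* Excess concentrations slightly below zero (noise at early time points)
  are retained in fits and flagged, never truncated or dropped.

## Problem sizes

The validation suite uses 10⁶ oracle draws per grid point (27 points), 500
replicate experiments for coverage, 200 seeded survey runs for the
detection-power check, and full 7!-permutation enumeration in the exact
Spearman test; the whole suite and the acceptance script each run in well
under a minute.

## Known limitations

* The ¹⁵NH₄⁺ treatment cannot estimate denitrification; combining both
  treatments into a joint estimator (shared A) is not implemented.
* Delta-method uncertainties ignore uncertainty in the labeled fractions;
  supplying an Fₙ interval (e.g. from a nitrite detection limit) is
  supported only by re-running the estimator at the interval endpoints.
* The survey generator draws genes and transcripts independently per
  marker; real gene–transcript pairs are correlated within a well.
* No isotope-ratio mass-spectrometry signal processing: inputs begin at
  excess isotopologue amounts.
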