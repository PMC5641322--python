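# n2pair

**¹⁵N isotope-pairing analysis of N₂ production: partitioning anammox and
denitrification in groundwater incubations, with nitrogen-cycle marker
indices.**

Anaerobic ammonium oxidation (anammox, NH₄⁺ + NO₂⁻ → N₂) and denitrification
(NO₂⁻/NO₃⁻ → N₂) both remove fixed nitrogen from aquatic systems, but they
leave different isotopic fingerprints. After spiking an anoxic water sample
with ¹⁵N-labeled substrate, the N₂ isotopologues ²⁸N₂/²⁹N₂/³⁰N₂ accumulate in
proportions set by how each process pairs nitrogen atoms: denitrification
draws **both** atoms from the nitrite pool (binomial in the nitrite labeled
fraction Fₙ), while anammox pairs **one** atom from the ammonium pool with
**one** from the nitrite pool. `n2pair` implements the forward pairing model,
the inverse rate estimators, a synthetic-experiment generator for validating
them, and the qPCR/lipid marker indices used to map the two guilds across
groundwater wells.

## The model

For process rates A (anammox) and D (denitrification) and labeled fractions
Fₐ (ammonium) and Fₙ (nitrite), the isotopologue production rates are

    P30 = D·Fₙ² + A·Fₐ·Fₙ
    P29 = 2·D·Fₙ(1−Fₙ) + A·[Fₐ(1−Fₙ) + Fₙ(1−Fₐ)]
    P28 = D·(1−Fₙ)² + A·(1−Fₐ)(1−Fₙ)

with P28 + P29 + P30 = A + D. In a ¹⁵NO₂⁻ incubation (Fₐ = 0) this inverts
uniquely:

    D = P30 / Fₙ²        A = (P29 − 2·Fₙ(1−Fₙ)·D) / Fₙ

and in a ¹⁵NH₄⁺ incubation A = P29 / Fₐ (D is not identifiable there). P29
and P30 are obtained as pooled ordinary-least-squares slopes of excess
isotopologue concentration versus time across all destructively sampled
bottles; standard errors propagate to the rates by the delta method, and
detection is a one-sided t-test on each slope. Labeled fractions account for
dilution of the tracer by the unlabeled background pool,
F = added / (background + added), or F = added / measured-total when the
pool is assayed after spiking.

The marker module computes per-well hzsA/(archaeal + bacterial amoA) and
nirS/16S rRNA gene-copy ratios, ladderane-lipid relative concentrations
(sum of [3]- and [5]-ladderane FAME peak areas over the C19:0 internal
standard, below detection when < 0.01), and Spearman correlations of any
index against oxygen with exact-permutation p-values at small n.

## Worked example

Simulate a noise-free tracer incubation (triplicates sacrificed at
0/14/24/36/48 h, fully labeled nitrite pool, true rates A = 3.5 and
D = 0.7 nmol N₂ L⁻¹ d⁻¹) and re-estimate the rates from the series:

```sh
$ n2pair simulate -o demo_sim --seed 7 --noise-sd 0
wrote demo_sim/series.csv
$ n2pair estimate -i demo_sim/series.csv -o demo_est
anammox 3.5, denitrification 0.7 nmol N2 L-1 d-1; total 4.2; anammox contribution 83%
```

The estimator recovers the true rates exactly and reports the total N₂
production (4.2 nmol L⁻¹ d⁻¹) and the anammox share of nitrogen loss, 83%.
The same chain works on measured series tables (CSV columns `time_h`,
`replicate`, `excess29_nmol_per_L`, `excess30_nmol_per_L`) with the
incubation design — volumes, tracer additions, backgrounds — supplied as a
YAML file via `--config`.

A synthetic seven-well survey along an oxygen gradient, fed through the
index pipeline:

```sh
$ n2pair survey -o demo_survey --seed 1
$ n2pair indices -i demo_survey/markers.csv --oxygen demo_survey/oxygen.csv -o demo_idx
hzsA/amoA (gene) vs oxygen: Spearman rho -1.000, p 0.0003968 (exact, n=7)
```

The anammox/aerobic-ammonia-oxidizer ratio declines with oxygen; at n = 7
the exact permutation p-value of a perfect rank reversal is 2/7! ≈ 4·10⁻⁴.
Monte-Carlo validation of the estimators under measurement noise:

```sh
$ n2pair recover -o demo_rec --n-reps 200 --seed 1
bias A -0.0022, D +0.0038; RMSE A 0.1919, D 0.1926; 95% CI coverage A 0.950, D 0.935
```

Every command writes its tables plus a `run_log.txt` echoing the version,
seed and parameters needed to reproduce the result.

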