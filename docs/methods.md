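# Methods

## The measurement model

A urine cell-pellet DNA sample is sequenced ultra-deep over a small panel
of non-coding hotspot SNVs. Reads carry unique molecular identifiers
(UMIs): reads sharing a UMI and fragment start derive from one input
molecule. Collapsing each family to a consensus base suppresses PCR and
sequencing errors roughly to the rate at which *both* strands of a
molecule are misread, which is what pushes the noise floor low enough to
quantify variant allele frequencies (VAFs) of a few tenths of a percent.

The package models the post-suppression data directly:

* quality-passing consensus depth per site `D ~ Poisson(d)`, `d = 2400` by
  default (matching a raw depth of ~35,400× at ~15 raw reads per family);
* alt count `A ~ Binomial(D, v + e/3 · (1 − v))`, where `v` is the true
  somatic VAF at the site and `e = 10⁻³` is the per-consensus-base
  substitution error, split evenly over the three non-reference bases.

VAF is `A/D` with denominator all quality-passing (Q ≥ 30, non-N) calls —
bam-readcount semantics. A site with `D = 0` is *undefined*, never zero;
a sample with no defined site raises an unevaluable-sample error rather
than silently producing a negative call.

The classifier score is the maximum VAF over the non-excluded panel sites,
and a sample is positive when that score strictly exceeds the threshold
(a score exactly at the threshold is negative). Thresholds are carried as
exact rationals so the boundary (e.g. 48/2400 vs 2%) is never decided by
floating-point representation.

## Consensus rules

A consensus requires ≥ 3 raw reads (families of 1–2 are discarded, not
down-weighted). The consensus base is the most frequent member base if it
is supported by a strict majority of the family, otherwise `N`; `N`
consensus bases are excluded from depth downstream. Consensus quality is
the mean quality of supporting reads capped at Q40 — a deliberate
simplification of Bayesian consensus models, adequate because the only
downstream use is the Q30 pass/fail filter. UMI grouping is exact-match by
default; an optional greedy Hamming-distance-1 merge absorbs UMIs with a
single sequencing error into the more abundant family at the same fragment
start. Duplex (strand-aware) consensus is out of scope.

## Statistics

* **Exact binomial CI**: Clopper–Pearson via beta quantiles
  (`lower = B(α/2; k, n−k+1)`, `upper = B(1−α/2; k+1, n−k)`), the method
  that reproduces the printed intervals of the reference analysis for the
  contingency counts checked. Coverage is conservative by construction.
* **Printing**: percentages round half-away-from-zero to integers (one
  decimal for the design/sample-size computation).
* **ROC/AUC**: a sweep over all distinct observed scores with the same
  strict-inequality rule as the classifier; the trapezoid over those
  points equals the Mann–Whitney U statistic scaled by `n₁n₂`, ties given
  half credit. The test suite checks equality with a literal all-pairs
  oracle and with an independent library implementation.
* **Group comparison**: two-sided Mann–Whitney with normal approximation
  and tie correction (the asymptotic regime fits the cohort sizes);
  medians are always reported alongside so the headline summary does not
  depend on the test choice.
* **Relative risk**: for cystoscopy-negative surveillance samples, risk of
  future recurrence in test-positive vs test-negative patients, with a
  Katz log-normal CI (explicitly labelled; zero event cells get a 0.5
  continuity correction and a flag). The point estimate, not the CI, is
  the comparable quantity.
* **Strata**: incident-disease reporting uses G1pTa, G2pTa, G3pTa, G2pT1,
  G3pT1, MIBC (any stage T2+), and "Other BC" (CIS, G1pT1, or unrecorded
  stage/grade). The "Any"-gene row of the stratified table is by
  construction identical to the sample-level max-VAF call.

## The synthetic cohort generator

The generator's defaults are the study conditions; they are not tuning
knobs for tests.

| parameter | default | meaning |
|---|---|---|
| consensus_depth_mean | 2400 | quality-passing consensus depth per site |
| raw_per_consensus_mean | 15 | raw reads per UMI family (raw depth ~35,400×) |
| per_base_error | 1e-3 | consensus-level substitution error per base |
| background_clonal_prob_by_age | 0.01 / 0.09 / 0.14 | P(one clonal hotspot) for ages <50 / 50–65 / ≥65 |
| background_clonal_vaf_median, log-sd | 3%, 0.25 | log-normal clonal VAF in cancer-free urine |
| tumour_mutation_prevalence | 0.74 | P(a cancer carries ≥1 panel mutation) |
| tumour_vaf_median (incident / recurrence / pre-recurrence) | 6% / 3.3% / 1.7% | log-normal median of the tumour max VAF |
| tumour_vaf_log_sd | 0.8 | spread of tumour max VAF (orders of magnitude) |
| age means (non-BC / BC / surveillance) | 59.5 / 72.5 / 74 | Gaussian age draws, sd 12, clipped to [18, 100] |

Design choices where the form was genuinely open:

* **Background error is modelled per consensus base**, not per raw read:
  every reported quantity is consensus-level, so this keeps the cohort
  simulation fast and the noise model identifiable. Read-level simulation
  exists solely to exercise the consensus module.
* **Clonal background is at most one mutated hotspot per sample** (isolated
  high-VAF points; a multi-site option exists, off by default), and the
  tumour signal likewise parameterises the *max* VAF directly on a single
  hotspot by default — the classifier statistic is the max, so this is the
  identifiable parameterisation; a multi-site tumour option exists.
* **Log-normal VAF laws**: the reference analysis reports only medians, so
  the distributional form is a modelling choice exposed in config. The
  background log-sd of 0.25 makes a clonal event a near-binary positive at
  the 2% threshold, which is what makes the age-band probabilities a
  recoverable parameter; the tumour log-sd of 0.8 reflects the
  orders-of-magnitude variation of tumour DNA fraction in urine.
* **WDR74 chr11:62609254G>A germline noise** is available as an optional
  per-site elevated background error (0.3% when enabled, off by default),
  paired with the panel's exclusion mechanism for the max-VAF statistic.
* **Seeding**: every draw flows from one root seed through named
  sub-streams keyed by (seed, stream, sample index), so enlarging a cohort
  never perturbs already-generated samples, and identical seeds give
  bit-identical outputs.

Analytic companions (`analytic_detection_prob`,
`analytic_band_positive_rate`, `analytic_sensitivity`) integrate the
binomial tail over the log-normal VAF law and the Poisson depth
distribution with exact rational threshold counts; they agree with direct
Monte Carlo to ~10⁻⁴ and serve as the independent oracle for
parameter-recovery tests.

What the generator does **not** emulate: fragmentomics, GC and strand
bias, UMI collisions, germline contamination, sample QC failures, and —
deliberately — the *continuum* of near-threshold background VAFs seen in
real training data (the real threshold sweep yields specificities
68/86/90% at 1/1.5/2% because background VAFs crowd the 1–2% region; the
binary clonal model concentrates specificity changes at the clonal event
probability instead). Passing tests therefore demonstrate correctness of
the pipeline's rules and estimators under the stated model, not clinical
performance on real urine.

## Problem sizes and numerics

Simulation-based tests use cohorts of 1,500–5,000 samples per arm, chosen
so that 3-standard-error recovery bands are a few tenths of a percentage
point wide while the full suite runs in about a minute. Quadrature for the
analytic oracles spans ±8 log-normal SDs; Poisson depth is truncated at
±6 SDs and renormalised. Consensus ties at exactly 50% support yield `N`
(never a guess); max-VAF ties break toward the earlier panel site; exact
rational arithmetic is used wherever a VAF meets a threshold.

## Known limitations

* The shipped default panel contains only the two published hotspot
  coordinates; the other 17 are synthetic placeholders and must be
  replaced for real data.
* SAM ingestion handles aligned, soft-clip-free, single-end records with
  RX-tag or read-name UMIs; it is a convenience path, not a full aligner
  interface.
* The Katz CI for the relative risk is wide at small event counts; no
  exact or bootstrap alternative is provided.
* The consensus quality model is intentionally cruder than fgbio-style
  Bayesian scoring; results are insensitive to it as long as qualities
  straddle the Q30 filter realistically.
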