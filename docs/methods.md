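# Methods

This note documents the models, numerical choices and limitations of
the package: what each stage computes, why the defaults are what they
are, and what the synthetic-data studies do and do not demonstrate.

## Functional profiling

Inputs are per-sample tables of tied best-hit read→gene alignments
(ties at the best alignment score; e-value filtering is assumed done
upstream by the aligner), a gene→KO map, KO→module and KO→pathway
membership maps, and a list of universal single-copy KOs.

* **Fractional counting.** Each read carries unit weight split evenly
  over its *k* tied genes; each annotated gene's count splits evenly
  over its KOs. Genes without KO annotation contribute to an explicit
  annotation-loss tally, so read mass is conserved exactly:
  Σ KO counts + loss = number of reads.
* **Single-copy normalization.** Each sample's KO counts are divided by
  the median count of the universal single-copy KOs in that sample,
  making abundances approximate average copy number per cell and, by
  construction, scale-invariant and idempotent. The full learned
  corrections of tools in this space (gene-length models, intra-sample
  regressions) are deliberately reduced to this core median scaling:
  it is parameter-free, exactly testable, and sufficient for
  cross-sample comparability of the synthetic studies. A sample whose
  universal median is zero is reported as unnormalizable rather than
  silently passed through.
* **Support-based aggregation.** For a sample, a group's support is the
  detected fraction of its member KOs. A multi-membership KO allocates
  its abundance across candidate groups proportionally to their
  supports (evenly in the degenerate all-zero-support case), so a KO
  shared between a fully detected module and a barely detected one
  credits the former. Presence/absence support (not abundance-weighted)
  is used; the allocation conserves per-sample mass up to the reported
  unmapped tally.

## Differential abundance

Per feature level (module or pathway) and time point, a two-tailed
Wilcoxon rank-sum test compares cohorts. The exact permutation
distribution is used when both groups have ≤12 tie-free observations;
otherwise the normal approximation with midranks, tie correction and
continuity correction. The BH family is one feature level at one time
point (modules at month 4 are corrected together, separately from
pathways and from other months), matching the granularity at which such
studies report counts; this is configurable by concatenating result
frames before adjustment. Effect size is log₁₀((median_ref+ε)/
(median_comp+ε)) with ε = 1e-10 on the normalized-abundance scale —
small enough never to matter for nonzero medians, large enough to keep
zero medians finite. "Expansion" between two time points means the
absolute log-ratio strictly increased; ties (measure-zero on continuous
data) count as non-expanding. Category enrichment is Pearson's χ² on
the 2×2 (cohort-association × category) table, 1 df, no continuity
correction by default.

## Metagenomic age

* **Balanced subsampling.** Each modeled time point contributes the
  same number of samples n_t (default: the smallest per-time-point
  count, or a configured cap), drawn uniformly without replacement.
  The 70–30 split takes ⌊0.7·n_t⌋ training samples per time point;
  this floor rule reproduces both canonical split tables: n_t=23 over
  5 time points → 80/35 total and 16/7 per time point; n_t=29 over 8 →
  160/72 and 20/9.
* **Regularized random forest.** CART regression trees (variance
  reduction, bootstrap, mtry = p/3, nodes of ≤5 samples left unsplit)
  grown sequentially with guided regularization: the split gain of a
  feature not yet used anywhere in the ensemble is multiplied by
  γ ∈ (0,1], default 0.8, steering later trees onto the feature set
  discovered early; γ = 1 is a plain random forest, and test properties
  hold for both. Default 10,000 trees; the simulation studies and
  tests use 200, past the point where additional trees changed any
  study-level conclusion. Tree-averaged predictions lie in the convex
  hull of training ages by construction. The builder is numba-compiled
  and deterministic under its seed.
* **Calibration spline.** A penalized natural cubic smoothing spline
  (Reinsch/Green–Silverman band-matrix form) of test-set predictions
  against true test age, with the smoothing parameter bisected so the
  smoother-matrix trace equals 3 effective df (tolerance 0.01).
  Observations are collapsed to unique ages with weights, exactly as
  R's `smooth.spline` does; a cross-check against that implementation
  agrees to <0.01 months on tied-age fixtures. Because the penalty's
  null space is the linear functions, exactly linear data are
  reproduced with zero residual at any df. Evaluation interpolates the
  fitted values with a natural cubic spline (the exact minimizer) and
  extrapolates linearly outside the observed age range. At least 4
  distinct test ages are required.
* **Relative age and delay test.** relative age = prediction −
  spline(true age), one estimate per opposite-cohort sample per
  replicate (10 replicates by default, each with a fresh subsample and
  split). Per replicate and time point, a two-tailed Wilcoxon
  signed-rank test (exact by sign-vector enumeration for n ≤ 12, with
  midranks so exactness survives ties; normal approximation beyond)
  against zero median; the summary is the fraction of replicates with
  p < 0.05 and a negative (delay) or positive (acceleration) median.
  Replicate significance is assessed per replicate; pooled estimates
  are used only for density reporting and pooled medians.

## Synthetic-data generator

The generator emulates two-cohort longitudinal KO profiles with three
feature classes: *trending* features follow logistic (monotone
saturating) age curves with feature-specific midpoint U(2,12) months,
rate U(1,3) months, and amplitude either +U(1,3)× or −U(0.4,0.8)× the
baseline (both directions occur; decreasing amplitudes are bounded to
keep abundances positive); *cohort-shifted* features are age-constant
but multiplied in cohort B by exp(±U(log 1.5, log 3)) — a
non-developmental disruption deliberately separable from delay; the
rest are constant. Cohort B's mean for every feature is evaluated at
max(t − δ, t_min): the delay is a time shift floored at the youngest
modeled age, so both cohorts coincide at the first time point.
Observed values are means times exp(N(0, σ²)) log-normal noise,
σ = 0.3 by default — set for adequate test power at 25 subjects per
cohort rather than estimated from real data, whose module-level noise
distribution is not characterized. Universal single-copy KOs with
constant unit mean are appended for normalization. Covariate flags
(breastfed, formula-fed, antibiotics) are generated with plausible
age patterns but do not influence abundances; they exercise the
covariate-grouping code paths only.

Default study conditions: 25 subjects per cohort, time points
(2, 4, 6, 9, 12) months, 150 KOs + 20 universal, δ = 2 months,
50% trending, 10% cohort-shifted. The synthetic hierarchy partitions
KOs into modules of 5 (15% of KOs join a second module) and unions
modules into pathways, so support-based aggregation faces genuine
multi-membership.

What the generator does **not** emulate: raw reads, taxonomic
composition, compositional (relative-abundance) coupling between
features, subject-level autocorrelation across time points (each
sample's noise is independent), covariate effects on abundances, and
dropout/zero-inflation. Passing tests therefore demonstrate the
statistical machinery's correctness and the protocol's behavior under
a controlled delay, not performance on real sequencing data.

## Simulation studies and their interpretation

The calibration module runs repeated synthetic studies at desk scale
(200 trees, 10 replicates; 20 runs for the null and recovery studies,
10 paired runs across δ ∈ {0,1,2,3} for the dose-response):

* **Null calibration** uses δ = 0 *and* no cohort shifts (fully
  exchangeable cohorts). A run "calls a delay" if, at the final time
  point, a majority of either cohort's replicates report significant
  delay. The observed call rate is one to several runs in twenty
  depending on the draw (about 0.15 on average across repeated
  studies) — materially above the naive α-scale expectation because a
  replicate's
  calibration-spline error is a *common offset* to all of its
  estimates, so the signed-rank test's effective sample size is far
  smaller than the number of samples. This inflation is inherent to
  the calibrate-then-test design and is the main reason delay findings
  should rest on a majority of replicates rather than any single one.
  The rank-sum false-positive rate is checked against a band of
  [0.03, 0.05 + 3·SE]: asymmetric because the continuity-corrected
  test is conservative by construction, so the failure mode worth
  excluding is anti-conservatism.
* **Delay recovery** imposes δ = 2 months with the shift channel off,
  isolating the delay signal: the delayed cohort's pooled median
  relative age at the final time point is negative (and the reference
  cohort's positive — the mirror-image property) in ≥18 of 20 runs.
  With the 10% cohort-shift channel on, B-trained models receive
  off-manifold inputs from cohort A and the reference cohort's
  final-time-point median is intermittently dragged negative by the
  disruption signal alone — a caution for interpreting mirror-image
  asymmetries in real data where non-developmental differences
  coexist with delay. The final time point also compresses the
  reference cohort's acceleration (forest predictions cannot exceed
  the training-age maximum), so mid-study time points show the mirror
  more strongly.
* **Monotonicity**: within paired runs, the delayed cohort's median
  relative age decreases monotonically in δ (mean Spearman −1.0).

## Pipeline

A YAML config drives simulate → profile → diff → age. Every stage's
seed derives from the single run seed, all outputs are TSV with a
fixed float format, and `manifest.json` records per-stage parameter
signatures, seeds and output SHA-256 hashes; a rerun with unchanged
inputs verifies hashes and skips the stage. Two runs with the same
config are byte-identical in all numeric outputs. Exit codes: 0 ok,
1 user error, 2 internal.

## Known limitations

* The null false-call rate of the delay test (≈15% of runs on average
  at these conditions, varying 5–30% across study draws) is a property
  of the calibrate-then-test protocol, not of the test statistic;
  stricter decision rules (higher replicate majorities, consistency
  across adjacent time points) reduce it.
* The regularized forest implements the guided split-gain penalty
  only; it does not reproduce any specific external RRF package
  tree-for-tree.
* Single-copy normalization omits gene-length and learned intra-sample
  corrections.
* The generator's noise and effect-size defaults are chosen for test
  power, not fitted to real data.
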