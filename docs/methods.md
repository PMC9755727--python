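# Methods

This note documents the model and procedure choices behind `tractstrata`,
their defaults, and what the synthetic cohorts do and do not establish.

## Length stratification

The unit of analysis is the connectome edge: a pair of parcellation
regions with its mean streamline length, streamline count (FN) and mean FA.
The healthy-control cohort defines the length scale. For each edge, the
HC-average length is the mean over the HC subjects in which the edge exists
(FN > 0); edges absent from every HC subject average to 0 and take no part
in the trisection. The range of positive HC-average lengths is split into
three equal-width bins. Two conventions are fixed deliberately:

* **Half-open intervals** `[l_min, b1)`, `[b1, b2)`, `[b2, l_max]`, so an
  edge exactly at a cut point is classified deterministically (into the
  upper bin). Ties are measure-zero for continuous lengths but finite
  files make an explicit rule necessary.
* **Clamping**: a patient edge shorter than `l_min` or longer than `l_max`
  (possible, since boundaries come from HC only) is classified into the
  nearest extreme class rather than dropped, so per-subject FN totals are
  never silently biased.

Classification defaults to each subject's own edge lengths thresholded at
the HC cut points (`basis="subject"`), which uses the data actually
measured per subject and handles edges absent in HC; `basis="hc_average"`
makes every subject inherit the HC-average edge's class, giving one shared
mask. Per-class FA is the unweighted mean over existing edges — the
plainest reading of "average FA" — with an FN-weighted variant available.
Per-class FN is the plain sum. The subject's total FN is defined as the
sum over class-labeled existing edges, which makes
`fn_short + fn_middle + fn_long = fn_total` an exact identity under either
basis (under the default subject basis it equals the sum over all existing
edges).

## Network topology

Four global metrics are computed on weighted networks with edge distance
`d(i,j) = 1/w(i,j)` (a log-distance `−log(w/w_max)` is available):

* `Lp`: mean shortest-path distance over *connected* ordered pairs;
  disconnected pairs are reported in a separate count rather than folded
  into the mean, keeping `Lp` finite.
* `Eglob`: mean of `1/d` over all ordered pairs, 0 for disconnected pairs
  (Latora–Marchiori), which handles disconnection natively.
* `Cp`: mean over nodes of the Onnela geometric-mean triangle intensity on
  weights normalized by the global maximum; nodes of degree < 2
  contribute 0. This makes `Cp` scale-invariant by construction.
* `Eloc`: mean over nodes of `Eglob` applied to each node's
  neighbor-induced subgraph.

Structural networks are FN-weighted by default (FA available), with
weights max-normalized before the distance transform so `Eglob, Eloc ≤ 1`
and metrics are comparable across subjects with different total counts.
Functional correlation matrices are thresholded at a fixed sparsity
(default 0.2, binarized, deterministic index-order tie-breaks); negative
correlations are never retained. These are defaults, not reconstructions
of any particular study's thresholding. The implementation is verified to
1e-10 against a brute-force Floyd–Warshall and triangle-enumeration oracle
on small random graphs, and cross-checked against networkx where the
formulas coincide.

## Statistics

Group comparisons fit `y ~ group + age + sex` by OLS with dummy coding;
the omnibus group test is the partial F of the group block, which reduces
exactly to classical one-way ANOVA with no covariates. Pairwise contrasts
are differences of adjusted group means from the same fit; no extra Tukey
layer is applied, so multiplicity is handled once, by Benjamini–Hochberg
FDR within declared families that mirror how result tables are presented:

* the six stratified outcomes (FN and FA × three classes) × three group
  contrasts form one family; total FN forms its own small family;
* each correlation table (disease × metric × feature set — 14 global or 16
  deep grey-matter volumes, network metrics, clinical measures) is one
  family;
* the longitudinal outcome set (2 groups × 7 outcomes) is one family.

Note that with many true effects in a family, BH's step-up threshold for
the remaining null hypotheses rises toward α, so per-null rejection rates
near (not far below) 5% are the expected behaviour, and "no effect
detected" claims in the tests are asserted per contrast rather than as
"any rejection in the family".

Cohen's d uses Cohen's original pooled standard deviation
`sqrt((SS_x + SS_y)/(n_x + n_y))` (maximum-likelihood pooling), under
which two unit-SD samples pool to exactly 1. In the covariate-adjusted
comparison, d is the adjusted contrast estimate divided by the two groups'
pooled raw SD, so the effect-size sign always agrees with the contrast.

Correlations default to Pearson with an automatic fallback to Spearman
when either variable fails a Kolmogorov–Smirnov-type normality pre-check
(the Lilliefors variant, since mean and SD are estimated from the sample);
the method actually used is recorded per result row. All tests are
two-sided. Longitudinal change is tested by paired t-tests on follow-up
minus baseline over complete pairs; all-zero differences return
`t = 0, p = 1`, constant nonzero differences are flagged as
degenerate-variance with `p → 0`.

## Classification

RRMS-vs-NMOSD discrimination uses the six class features with a Fisher
linear discriminant: features standardized by training-fold mean/SD,
pooled within-class covariance with a ridge of `1e-6 × trace(S)` on the
diagonal (six features against ~40 training subjects per fold make an
unregularized inverse fragile), decision scores `x'S⁻¹(μ₁ − μ₀)`.
Discrimination is summarized as ROC AUC per stratified fold, reported as
mean ± SD across the k = 5 folds (a pooled-score AUC is available).
Features constant within a training fold are dropped for that fold and
logged. Fold assignment is seeded and reproducible.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not tractography itself:

* **Geometry.** 148 nodes fixed on a 70 mm-radius sphere give each region
  pair a Euclidean base length (range ≈ 1–140 mm); per-subject lengths add
  2% multiplicative jitter. Edge existence is Bernoulli with probability
  `0.9·exp(−d/150 mm)` and expected streamline count `50·exp(−d/70 mm)`,
  drawn as negative-binomial counts (gamma-Poisson, dispersion θ = 20).
  Together with the pair-count distance distribution this reproduces the
  empirical class ordering of total FN (middle > short > long) and a
  nondegenerate trisection.
* **FA.** Edge-level FA means rise with length tercile
  (0.38 / 0.45 / 0.52, edge SD 0.03), giving the long > middle > short FA
  ordering; per-subject offsets (SD 0.015) and per-edge noise (SD 0.02)
  are added and values clipped to (0.01, 0.99).
* **Disease effects** are multiplicative on FN (counts) and additive on FA
  (bounded): RRMS-like ×1.15/×0.80/×0.70 on short/middle/long FN and
  −0.06 FA in all classes; NMOSD-like FN-unchanged with −0.03 FA. HC
  effects are identities.
* **Subject heterogeneity.** Each subject carries a shared FN scale
  (lognormal SD 0.05, a head-size-like factor) and independent per-class
  scales (SD 0.10). The per-class components are what make the
  long-vs-short balance a subject-level trait.
* **Morphometry.** The 30 volume features scale with
  `1 + 0.08·z + N(0, 0.06)`, where `z` is the subject's long-minus-short
  FN contrast computed on within-group z-scores of the class totals
  (within-group standardization cancels both the shared scale factor and
  the group-level disease shift). This yields within-disease correlations
  of about −0.5 with short-range FN and +0.5 with long-range FN — the
  intended sign structure at realistic magnitudes.
* **Demographics** approximate the modeled study margins: 56/51/42
  subjects (HC/RRMS/NMOSD), ages ~N(39, 14) clipped to 18–60, group-wise
  female fractions, EDSS/duration/lesion volume for patients only (HC
  carry explicit nulls — EDSS 0 is a valid score and is never used as a
  missing-value sentinel).
* **Follow-up.** 25 RRMS-like and 20 NMOSD-like subjects get a second
  timepoint that keeps each subject's latent state and redraws measurement
  noise, with optional per-class drift. The default zero drift is an exact
  longitudinal null; EDSS and lesion volume increase slightly at follow-up
  but do not feed back into the connectome data.

All randomness derives from a single integer seed via seed sequences;
identical configs are bit-identical.

**What passing tests show — and do not.** Calibration, effect-recovery and
sign-recovery results demonstrate that the pipeline is statistically
correct and sensitive *under the generator's assumptions*: independent
subjects, Gaussian-ish class summaries, effects uniform within a class,
no lesion geometry, no spatially structured misregistration, and
functional matrices that are noise rather than BOLD-derived. Real cohorts
can violate any of these; the synthetic results validate the machinery,
not the biology.

## Problem sizes and numerical choices

The replicate simulations used by the tests and the acceptance script run
at n = 50 per group with the full 148-node geometry: 200 zero-effect
replicates for null calibration and 100 default-effect replicates for
recovery in the test suite (120 and 60 in the acceptance script), sizes at
which the binomial uncertainty on the reported rates is a few percent.
Graph-metric exactness is checked on 50 random graphs of up to 12 nodes,
where exhaustive Floyd–Warshall enumeration is feasible. Matrix
serialization uses 17 significant digits, so write-then-read round-trips
are exact. Symmetrization tolerance is 1e-6 relative; trisection
equal-width bins are validated to 1e-12 relative.

## Known limitations

* Boundaries require at least two distinct positive HC-average lengths;
  degenerate ranges raise rather than guess.
* The `hc_average` classification basis labels subject edges absent from
  the HC average as unclassified; their counts are excluded from the class
  totals (and hence from `fn_total` as defined here).
* The trisection operates on edge-level average lengths, not pooled
  streamline-level lengths; with heavy within-edge length dispersion the
  two differ.
* The functional-network arm uses a single fixed sparsity rather than an
  area-under-curve sweep across thresholds.
* EDSS is generated and analyzed as a continuous covariate although it is
  ordinal with 0.5 steps; the Spearman fallback mitigates this in
  correlations.
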