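# Methods

## Overview

`neuroflex` quantifies how often brain regions change functional-community
membership over the course of a resting-state scan ("neural flexibility")
and tests whether that quantity differs between clinical groups and predicts
symptom severity.  The chain is:

1. sliding-window Pearson correlations over parcellated ROI time series,
   thresholded by within-window FDR;
2. a temporal multilayer network (each node coupled to itself in adjacent
   windows) partitioned by generalized Louvain maximization of multilayer
   modularity, repeated across seeds;
3. node flexibility `f_i = n_i / (W - 1)` averaged over repetitions and
   aggregated to functional systems and the whole brain;
4. covariate-adjusted OLS group contrasts with family-wise BH-FDR;
5. gradient-boosted-tree models with importance-ranked top-N feature search
   under repeated k-fold cross-validation plus independent-test evaluation.

A synthetic cohort generator stands in for clinical resting-state data so
that the full chain is testable and reproducible offline.

## Dynamic connectivity

Windows are half-open index ranges `[s, s + width)` with `width = 30`
volumes and step 1 by default, the common convention for resting-state
dynamic connectivity at a TR of about 2 s.  Within each window, all
R(R-1)/2 region pairs are tested against zero correlation with the exact-t
reference (`t = r sqrt((n-2)/(1-r^2))`, df `n - 2`, two-sided) and the
Benjamini-Hochberg step-up rule is applied *within the window* across all
pairs (34,716 pairs for a 264-node parcellation) at q < 0.05.  Non-retained
entries are zeroed; retained entries keep their correlation value.

Significant *negative* correlations are zeroed by default
(`negatives="zero"`): the Newman-Girvan intralayer null model compares
observed weight against a strength-product expectation and is designed for
nonnegative weights, so retaining negative edges changes the meaning of
modularity.  A `retain` option keeps them for sensitivity analyses.

Columns that are constant within a window have undefined correlations;
their edges are treated as non-retained rather than raising, so degenerate
synthetic inputs do not kill a cohort run.

## Multilayer modularity and generalized Louvain

The quality of a partition g of all R x W node-layer copies is

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma k_is k_js / 2m_s) d_sr
                               + d_ij C_jsr ] d(g_is, g_jr)

with ordinal coupling `C_jsr = omega` for |s - r| = 1, per-layer strengths
`k_is` and totals `2m_s` computed on the thresholded weighted layers, and
`2mu` the total node-layer strength including coupling.  A layer with zero
total weight contributes no intralayer term but keeps its coupling, so
over-thresholded windows degrade gracefully.  With W = 1 the score reduces
to single-layer Newman-Girvan modularity at resolution gamma.

Defaults are `gamma = 1`, `omega = 1` (both exposed in every interface):
gamma = 1 is the canonical resolution, and omega = 1 places interlayer
persistence on the same scale as a strong intralayer edge, which keeps
community labels identifiable across windows without freezing them.

Optimization is the two-phase greedy scheme over node-layer copies: sweeps
in seeded random order move each copy to the neighbouring community with
the largest strictly positive modularity gain until a full sweep makes no
move; communities are then aggregated into super-nodes (summing intralayer
and coupling weights) and the phases repeat until a full cycle improves Q
by less than 1e-10.  Ties are broken by the first-encountered candidate and
the sweep order is reshuffled with the run seed on every pass, so a run is
fully determined by its seed.  The move phase is implemented as a numba
kernel over the sparse modularity matrix (the dominant first level uses the
dense per-layer block structure directly); aggregation uses a counting-sort
CSR build that leaves duplicate entries in place, because the sweep sums
them anyway.  The returned quality is re-evaluated on the original matrix
and equals `multilayer_modularity(net, labels)` exactly.

Because the heuristic is greedy and seeded, detection is repeated (100
repetitions by default, matching common practice) and all flexibility
metrics are averaged across repetitions at the node level before any
spatial aggregation (the aggregation order is immaterial for means but is
fixed for reporting).

## Flexibility

For one repetition, node flexibility is the number of adjacent-window label
changes divided by W - 1 possible changes; whole-brain and system values
are unweighted means over the member nodes.  Stability is reported as
1 - flexibility at every level.  Flexibility is invariant to community
relabeling within a repetition, which the suite asserts property-wise.

## Group statistics

Each feature is regressed on a 0/1 group indicator (reference = control)
plus age and mean framewise displacement as continuous covariates and sex
and site as indicators; covariates that do not vary in the analysed subset
are dropped (they carry no information and would only produce rank
deficiency).  The reported effect is the group coefficient with its
two-sided t-test on residual degrees of freedom.  The whole-brain test is
reported at raw p; the 14 system features, the R node features and the
three medication contrasts (medicated vs unmedicated patients, unmedicated
vs controls, medicated vs controls) are each corrected as one BH family.
Rank-deficient designs, non-varying group indicators and zero residual
variance raise a degenerate-model error rather than returning nonsense.

## Predictive models

Gradient-boosted trees (XGBoost; 100 trees, depth 3, learning rate 0.3,
`hist` method, single thread, seeded) are fit once on the full training
cohort; features are ranked by share of total split gain, ties broken by
column order.  For each candidate prefix size N the top-N features are
evaluated with ten repeats of (stratified) ten-fold CV; the curve records
the pooled out-of-fold metric (accuracy / R^2) averaged over repeats and
the smallest N attaining the maximum is selected.  Sensitivity treats the
patient group as positive; AUC is computed from predicted scores by rank
statistics with ties averaged.  Independent-test metrics come from a model
fit on the training cohort only.

The default protocol computes the ranking on all training rows before
cross-validating the prefix curve, which lets the ranking see all training
labels: the CV curve is therefore optimistically biased as a generalization
estimate, and the independent-test numbers are the honest ones.  A nested
variant (`nested=True`) re-ranks inside every training fold.  The default
training recipe excludes female and medicated-patient subjects; both
exclusions are configurable.

## Synthetic cohorts

Each subject's R-region series follows a hidden-state model: K = 3 module
layouts (deterministic, genuinely distinct partitions of R = 50 regions
into 4 modules), with rows drawn i.i.d. given the state from a zero-mean
multivariate normal whose correlation is `rho_in = 0.6` within modules and
`rho_out = 0.05` between.  At each of the T - 1 boundaries the state is
redrawn uniformly from the other K - 1 states with a per-subject switching
probability: the planted analogue of flexibility.  Group means are 0.10
(controls), 0.04 (unmedicated patients) and 0.09 (medicated patients),
encoding the studied ordering "controls > medicated > unmedicated"; small
additive effects of centred age, motion and site perturb the subject-level
rate, and severity is `50 + 150 * (-rate) + N(0, 4)`, so higher severity
accompanies lower switching.  `rho_in = 0.6` makes within-module window
correlations comfortably exceed the FDR threshold at window width 30 while
leaving realistic sampling noise; T = 120 volumes matches a short clinical
resting-state run.

What the generator does *not* emulate: hemodynamic autocorrelation, scanner
noise spectra, head-motion artefacts (mean FD is drawn, not derived),
site-specific severity scales, or spatially graded module boundaries.
Passing tests therefore demonstrate that the *procedures* recover planted
dynamic structure under the model's assumptions, not that any clinical
effect size is reproduced.

Determinism: a single master seed drives a `SeedSequence` tree (cohort-level
covariates plus one spawned stream per subject), so cohorts are bit-for-bit
reproducible and subjects are mutually independent.

## Numerical choices and degenerate inputs

- |r| = 1 maps to p = 0 (the t statistic diverges); correlations are clipped
  to [-1, 1] before testing.
- BH q-values are the monotone step-up adjusted values clipped to [0, 1];
  the implementation is checked exactly against the literal step-up
  definition and against statsmodels.
- Louvain moves require strictly positive gain; quality is asserted
  non-decreasing across phases at run time.
- Empty networks (all layers zero, omega = 0) raise an undefined-quality
  error; zero repetition counts, K = 0, T = 0 and invalid rates raise
  configuration errors.
- Severity and covariate draws clamp to plausible ranges (age 7-18 y,
  FD 0.03-0.30 mm); switching rates clamp to [0, 1].

## Problem sizes in the shipped checks

The parameter-recovery suite uses cohorts of 40 + 40 subjects (R = 50,
T = 120, planted rates 0.10 vs 0.04, 20 detection repetitions, 20 replicate
cohorts) for power, and 100 smaller null cohorts (15 + 15 subjects, R = 24,
T = 80, equal rates, 6 repetitions) for type-I-error calibration — the
null check is size-invariant, so the smaller cohorts trade no validity for
speed.  The reproduction script (`scripts/acceptance.py`) analyses one
100-subject training cohort and one 50-subject independent-test cohort at
the default study conditions with 20 detection repetitions per subject.

## Known limitations

- Greedy Louvain finds local optima; only well-separated structure is
  guaranteed (and tested) to reach the exhaustive-search optimum.
- gamma and omega are fixed defaults, not tuned; conclusions about absolute
  flexibility levels depend on them (flexibility -> 0 as omega grows).
- The severity scale is a single synthetic scale; cross-site clinical-scale
  harmonization is out of scope.
- No consensus clustering across repetitions: metrics, not partitions, are
  averaged.
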