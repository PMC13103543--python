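# Methods

## Overview

`dfcstates` implements a sliding-window dynamic functional connectivity
(dFC) state analysis for a small brain network — the reference use case is
the 21-node frontoparietal network (FPN) sampled at TR = 2 s — together
with the multisite harmonization, group statistics, and a synthetic cohort
generator that plants known state dynamics so every stage can be validated
end to end without access to clinical data.

The analysis chain is:

1. **Windowed connectivity.** Each subject's T x N ROI matrix is segmented
   into overlapping rectangular windows (default 22 TR advanced by 1 TR;
   230 retained volumes give 209 windows). Within each window the Pearson
   correlation of every node pair is computed, clamped to
   [-1 + eps, 1 - eps] (eps = 1e-7), and Fisher r-to-z transformed; the
   upper-triangular entries (row-major, i < j, node order = input column
   order) form the window's edge vector (E = N(N-1)/2 = 210 for N = 21).
   A window with any undefined correlation (zero-variance node) is flagged
   invalid and excluded downstream; window slots are never silently
   dropped.
2. **Harmonization.** Parametric empirical-Bayes location/scale batch
   adjustment (the classic ComBat formulation) with site as batch and age
   (standardized) and sex (0/1) as protected covariates. By default each
   windowed edge vector is one observation carrying its subject's site; a
   subject-level variant (adjust window means, shift each subject's
   windows by the fitted delta) is configuration-selectable because the
   appropriate observation unit is genuinely ambiguous. The EB fixed point
   for the shrunken batch scale runs to a relative tolerance of 1e-6
   (max 1000 iterations). Degenerate cases: a single site returns the
   input unchanged with a warning; a zero-variance batch/feature cell
   falls back to location-only adjustment.
3. **State identification.** Exemplar windows — strict local maxima of the
   across-edge variance signal within each subject (endpoints excluded;
   global argmax as fallback so at least one exemplar exists) — are pooled
   over subjects and clustered by best-of-replicates Lloyd k-means
   (default 500 seeded restarts, up to 500 sweeps, squared Euclidean
   distance). The winning centroids initialize a single second-stage Lloyd
   pass over *all* pooled valid windows. Each replicate draws its initial
   centroids from its own substream of the master seed, so results are
   exactly reproducible and the best WCSS is non-increasing in the number
   of replicates. Empty clusters are re-seeded at the point farthest from
   its assigned centroid. Every valid window is then assigned to the
   nearest final centroid, ties broken to the lowest state id.
4. **Temporal metrics.** Per subject: fractional occupancy, mean dwell
   time in window units (the final censored run counts; unvisited states
   are missing, never zero), total transitions, and the k x k matrix of
   ordered pairwise transition counts (self-transitions excluded by
   construction). Per-state mean connectivity can be restricted to any
   named node subset (e.g. a DMN subset, or the non-FPN complement) for
   control analyses. Where invalid windows create gaps, a transition
   across the gap is counted only if the flanking labels differ.
5. **Statistics.** Between groups: Welch's t with Satterthwaite df (exact
   t distribution, no normal approximation), Hedges g
   (J = 1 - 3/(4N - 9); reported as a magnitude, direction carried by t's
   sign, first group minus second), and Benjamini-Hochberg FDR within
   explicit families (the k-occupancy + k-dwell + transitions family, and
   the k(k-1) pairwise-transition family). Within subjects: one-way
   repeated-measures ANOVA on state-wise mean FC with the
   Greenhouse-Geisser epsilon estimated from the sample covariance of
   conditions, followed by paired post-hoc t-tests (BH within the pair
   family; pairwise-complete subjects). Covariate-adjusted group effects
   come from OLS on group + age + sex + mean framewise displacement +
   site dummies (largest site as reference) with normal-theory 95% CIs.
   Exploratory stratified comparisons test each patient stratum
   (medication or episode status) against the full control group,
   unadjusted and adjusted, FDR within each stratified family; patients
   with missing stratum labels stay in the primary analysis.

## State labeling convention

k-means state indices are arbitrary, so centroid rows are reordered by a
fixed convention before reporting: states sorted by ascending centroid
mean z are labeled [2, 1, 3] for k = 3 — the hypoconnected state is
"State 2", the moderate state "State 1", the hyperconnected state
"State 3" — making states comparable across runs and matching the common
reporting order for this network. Other k keep ascending order.

## Model selection

The WCSS-vs-k curve is fitted over a configurable range with warm starts
(k+1 additionally initialized from k's solution plus a split at the point
farthest from its centroid), keeping the curve non-increasing up to
replicate noise. The knee suggestion is the maximum ratio of successive
WCSS drops (equivalently the largest second difference of log drops).
A raw second difference was rejected: when isotropic within-state noise
carries most of the variance — as it does for Fisher-z windows at L = 22,
where the per-edge sampling sd is 1/sqrt(L-3) ≈ 0.23 against state-mean
spacing of ~0.09 — the WCSS curve is nearly flat and the large k = 1 → 2
drop masks the true inflection, while the drop ratio still spikes at the
planted k. The suggestion is advisory; `k` is fixed at 3 by default.

## Synthetic cohort generator

The generator emulates the structure the pipeline must recover, not raw
BOLD physiology:

- **Regimes.** k = 3 zero-mean multivariate Gaussian regimes whose
  correlation matrices are Monte-Carlo calibrated (≥ 10^4 windows of the
  target length through the full observation model, independent noise
  included) so the expected windowed mean edge z hits the targets 0.198
  (moderate), 0.106 (hypoconnected) and 0.288 (hyperconnected) to within
  ±0.02 — the published per-state FC-strength levels. A small symmetric
  jitter (sd 0.04) on the off-diagonals, followed by eigenvalue clipping
  and re-normalization, gives each regime a distinct pattern beyond its
  mean.
- **Dynamics.** A Markov chain over regimes at time-point resolution with
  a minimum segment length (default 10 TR) so 22-TR windows are
  regime-dominated rather than fully mixed; sliding windows smear fast
  switches, and observed dwell times (several windows and up) imply slow
  dynamics. Defaults: self-transitions 0.90/0.93/0.90 for controls and
  0.90/0.97/0.90 for patients (the elevated hypoconnected self-transition
  produces the patient phenotype: higher occupancy and dwell in the
  hypoconnected state and fewer transitions overall), with off-diagonal
  mass favoring the hypoconnected state (0.65) so its occupancy dominates
  as observed. Segment duration is the minimum segment plus a geometric
  tail with continue-probability equal to the self-transition.
- **Sites.** Site effects are applied to the *signal* as a site-specific
  common-signal gain (raises all pairwise correlations — an additive shift
  on edge z) plus site-specific white noise (attenuates correlations — a
  multiplicative compression). A literal offset/scale of the signal would
  be invisible: correlation is invariant to per-node affine maps. Sites
  are allocated stratified within group, so every site sees both groups
  and site adjustment cannot absorb the group effect — matching how
  multi-site clinical studies recruit. Covariates (age, sex, framewise
  displacement, HAMD, illness duration, medication/episode availability)
  are drawn to resemble the published cohort demographics.
- **Window-level regime blobs.** For clustering-recovery experiments a
  companion generator draws edge vectors directly from Gaussian regime
  blobs (centroid = target mean z plus a fixed zero-mean pattern, per-edge
  noise sd 1/sqrt(L-3), window-level Markov switching). This isolates the
  clustering question from window smearing at regime boundaries, which
  the time-series path would otherwise dominate (mean regime runs of
  ~20-40 TR against 22-TR windows put most windows astride a boundary).

What the generator does *not* model: hemodynamic convolution,
autocorrelated BOLD noise, motion artifacts, scanner drift, or spatial
structure beyond the regime correlation matrices. Passing tests therefore
demonstrate that the pipeline recovers planted covariance-regime dynamics
under Gaussian observations — not that it is robust to every property of
real fMRI.

## Numerical choices

- Fisher clamp epsilon 1e-7 (configurable within (0, 1e-3]); clamping is
  symmetric.
- Lloyd convergence: stable partition, or squared centroid shift below
  1e-10 of the mean squared data norm; WCSS recomputed at the final
  assignment.
- Nearest-centroid ties break to the lowest state id; exemplar plateaus
  take the first argmax.
- Population (ddof = 0) variance for the exemplar signal; sample
  (ddof = 1) variance everywhere in the statistics.
- GG epsilon from the double-centered sample covariance of conditions
  (the Greenhouse-Geisser estimator, not Huynh-Feldt), bounded in
  [1/(k-1), 1]; identical conditions return F = 0, epsilon = 1.
- Hedges correction J = 1 - 3/(4N - 9); the alternative
  J' = 1 - 3/(4(N-2) - 1) differs below reporting precision at these
  sample sizes.
- The sex chi-square uses the Yates continuity correction by default.
- All randomness flows from a single master seed via `SeedSequence`
  substreams; identical seeds reproduce state sequences byte for byte.

## Problem sizes used in the validation suite

The packaged tests run the pipeline at 100 subjects per arm (230 volumes,
21 nodes) for the end-to-end effect-recovery check, 50 replicates of
100-vs-100 null cohorts for the specificity check (stage-1 restarts
reduced to 10-20 there, which is ample at the planted separation), 100
subjects of window-level regime blobs for clustering recovery (full 500
restarts), and a 6000-window subsample for the elbow scan. These sizes
were chosen as the smallest that give stable verdicts for each property.

## Known limitations

- Rectangular window weighting only; no tapered or adaptive windows, no
  HMM-style switching models.
- The nonparametric ComBat variant is not implemented.
- Dwell times take the simple uncensored mean of run lengths; a subject's
  final truncated run biases dwell slightly downward for sticky states.
- With invalid windows removed, artificial adjacencies can add or hide
  transitions; gap positions are recorded but no correction is applied.
- The elbow knee is a heuristic; it is reported as a suggestion and the
  analysis fixes k explicitly.
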