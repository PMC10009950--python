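# Methods

This note documents the statistical model, the estimation choices, the
synthetic-data generator and the known limitations of `atnseq`.

## ATN classification

Each subject is rated in three binary categories.  Abnormality directions
are fixed by biology and not configurable:

| category | marker | abnormal | default cutoff |
|---|---|---|---|
| A | CSF Aβ42/Aβ40 ratio | below | 0.09 |
| T | CSF p-tau181 (pg/ml) | above | 57 |
| N (aHV mode) | adjusted hippocampal volume (μl) | below | mixture-estimated; fixed fallback 2821.1 |
| N (ttau mode) | CSF total tau (pg/ml) | above | 470 |

A value exactly at its cutoff classifies **normal**.  Strict inequality is a
convention (no authority fixes the boundary case); it is covered by a unit
test so an alternative is a one-line change.  Subjects missing any required
marker are excluded from classification and listed — never imputed.

**Hippocampal-volume adjustment.**  Raw hippocampal volume is regressed on
mean-centered age, sex (0 = male, 1 = female), education, total
intracranial volume and WMH load by OLS; the adjusted value is the residual
plus the grand mean, so it stays interpretable in μl.  The model is fit on
all subjects with complete data by default; `adjust_on: atn_negative`
restricts the fit to CSF-biomarker-negative subjects (screened with the
fixed A/T cutoffs) for users who prefer a normative reference group.
Adjustment is idempotent and its residuals are orthogonal to every
covariate column (tested).

**Mixture cutoff.**  A two-component univariate Gaussian mixture is fit by
EM (5 seeded restarts, tolerance 1e-8, ≤ 500 iterations; deterministic
given the seed).  The cutoff is the equal-posterior point strictly between
the component means, solved from the quadratic in the log-density
difference with a bracketing fallback.  The fit is rejected as degenerate
when (a) the component means are closer than 0.5 pooled SD, or (b) one
component dominates the whole interval between the means so no
equal-posterior point exists; callers fall back to the fixed cutoff.  Note
that EM on genuinely unimodal data does not *always* collapse to
near-coincident components, so degeneracy detection is a guard, not a
bimodality test.  The mixture is fit on covariate-**adjusted** volumes by
default (a fixed-cutoff configuration is available), since dichotomization
is meant to reflect atrophy rather than head size or age.

**Youden cutoff.**  Given a labelled reference, candidate thresholds are
midpoints between adjacent distinct sorted values; the threshold maximizing
J = sensitivity + specificity − 1 is returned, ties broken toward higher
specificity.

## Candidate sequences

Two sets are compared.  The 24-permutation set contains every ordering of
the four AD-continuum groups {A−T−N−, A+T−N−, A+T+N−, A+T+N+}; the
amyloid-cascade ordering is named `ACH` and listed first, the 23
alternatives `P01`–`P23` in lexicographic order of state indices, with
aliases `AP1`/`AP2` bound to the two transient-increase permutations
(A+T−N− → A+T+N− → A−T−N− → A+T+N+ and A+T−N− → A−T−N− → A+T+N− → A+T+N+).
The 6-path set contains the three-step conversions from A−T−N− to A+T+N+,
named by category conversion order (ACH/ATN, ANT, TAN, TNA, NAT, NTA); each
step flips exactly one category.  Group labels are ASCII (`A-T-N-`)
internally, pretty-printed with the typographic minus.

## Constrained monotone GLM

Under difference coding the monotonicity constraints are coordinate bounds
(β₂, β₃, β₄ ≤ 0), so the exact minimizer is found by enumerating the 8
active-constraint patterns: clamp a subset of the three differences to
zero, solve OLS on the reduced design, keep the feasible solution with
minimal SSE.  This is deterministic, exact at this dimension, and cheap; it
is vectorized over outcome columns for voxel-wise use (one pseudo-inverse
per pattern, shared across all voxels).  Covariate coefficients are
unconstrained and fit jointly within each candidate model.  Correctness is
tested against two independent oracles: scipy's bounded least squares on
every random instance, and pool-adjacent-violators (weighted, decreasing)
on group means for the covariate-free case.

**BIC.**  BIC = n·ln(SSE/n) + k·ln(n) with k = 4 mean-structure
coefficients + covariates + 1 (residual variance).  k counts all four mean
coefficients regardless of which constraints are active, so model
complexity is constant across sequences and — at fixed n — the BIC ranking
reduces to the SSE ranking (asserted in tests).  SSE = 0 returns a −∞
sentinel with a warning.  In the 24-permutation comparison every sequence
uses the same subjects; in the 6-path comparison each path is fit on the
subjects of its own four states, so n may differ across paths and BICs are
compared as computed.  Ties (ΔBIC < 1e-9) are broken by canonical set order
and flagged.

**Trend test.**  The ROI/voxel test statistic is the t ratio of a centered
linear sequence-position regressor (positions 1–4) in an OLS fit with
covariates; p is one-sided for decline.  This is this package's
operationalization of a "decline along the sequence" test; published
per-ROI statistics from other implementations are not claimed to be
numerically reproduced, and reported log-p values here are −log₁₀ p.
The one-sided p is exactly Uniform(0,1) under Gaussian null data (verified
by simulation, KS < 0.05 at 1000 draws; type-I error within (0.03, 0.07)
at α = 0.05 over 2000 voxel simulations).

## Evidence maps and summaries

Voxel-wise analyses are restricted to a gray-matter mask (mean value
across subjects ≥ 0.05 by default).  Statistics are computed within the
mask; written maps set out-of-mask voxels to 0 (−log₁₀ p) or −1/NaN
(winner/ΔBIC) with a companion mask.  FDR control is Benjamini–Hochberg
within the mask, per tested sequence (not pooled across sequences).
Winner percentages partition the mask exactly (each voxel one winner, the
recorded tie-break applies).  ROI summaries fit the comparison on the
summed in-ROI volume (or on a supplied per-subject scalar, e.g. an atlas
volume) and report the reference sequence's share of ROI voxels from the
winner map.  Braak composites aggregate per-subject ROI volumes into
stage I/II (entorhinal + hippocampus), III/IV (limbic, insular, temporal)
and V/VI (remaining cortex); the default constituent lists are a coarse,
configurable approximation of atlas-based stage masks, not a claim of
identical membership.

## Synthetic data

The generator's defaults are the study conditions:

* **Group sizes** follow the reference cohort profile (143/41/29/14/45/23/
  61/81, total 437), so rare groups (e.g. A−T+N+) stay rare.
* **Markers** are drawn from the Gaussian component dictated by the
  subject's group flags: Aβ ratio N(0.110, 0.012²) vs N(0.060, 0.013²);
  p-tau N(41, 10²) vs N(90, 30²); total tau N(300, 100²) vs N(650, 250²);
  hippocampal volume N(3140, 180²) vs N(2580, 170²) μl before covariate
  effects.  p-tau and t-tau share a within-subject correlation of 0.7
  (strongly correlated tau markers underrepresent discordant groups, as in
  real cohorts).  t-tau follows the subject's **N** flag by default so
  classification round-trips in ttau mode; `ttau_component="t"` instead
  ties it to tau status, which is what observed group means show.
* **Covariates** confound volume: per-group age means/SDs rise across later
  groups; hippocampal volume loses 10 μl/year of age and varies with sex,
  TICV (0.8 μl/ml) and WMH (−5 μl/ml); voxel values lose 0.004 units/year
  with smaller TICV/WMH effects.  Covariate adjustment is therefore
  exercised non-trivially.
* **Voxels** sit on a 24×24×24 grid at 2 mm by default (small enough for
  fast tests, large enough for masks and smoothing).  A voxel's value is
  baseline 0.5 (0.01 outside the GM box, below the mask threshold) + the
  planted region offset at the subject's position along the region's
  sequence + covariate effects + N(0, 0.1²) noise, optionally smoothed.
  Region profiles are monotone (non-increasing offsets), biphasic (rise at
  position 2, minimum at position 4 — the transient amyloid-related
  expansion pattern), null, or custom (unrestricted; overlapping regions
  add, allowing composite truths such as amyloid-gated atrophy plus
  elevated volume in non-AD groups).  Subjects whose group is outside a
  region's sequence sit at baseline; consequently a decline planted over
  the AD-continuum groups alone is monotone-compatible with *every*
  conversion path, and discriminating the 6 paths requires a composed truth
  (see `examples/voxel_evidence_maps.py`).
* **Smoothing** uses a Gaussian kernel with σ = FWHM/(2√(2 ln 2)) per axis,
  with edge renormalization by the smoothed all-ones image, so constants
  are preserved and FWHM 0 is the identity.  An interior impulse
  reproduces the analytic 3-D Gaussian peak within 1%.

Every output is a pure function of (spec, seed).  What the generator does
**not** emulate: realistic anatomy or atlas-shaped regions, scanner/site
effects, non-Gaussian noise, spatial noise correlation (other than explicit
smoothing), longitudinal change, and missing-data mechanisms.  Passing
recovery tests therefore show that the estimator is correct under its own
assumptions — not that those assumptions hold in any particular MRI cohort.

## Problem sizes used in tests and the acceptance script

Recovery experiments use 20 subjects per group, a 10×10×10 grid with a 216-
voxel planted region, per-step decline of 1 residual SD, and seeds 1–10;
calibration uses 2000 simulated voxels; oracle comparisons use 100 random
instances with ≤ 60 subjects and 5 covariates.  These sizes were chosen as
the smallest that make the statistical criteria stable across seeds.

## Numerical choices

* Constraint feasibility tolerance 1e-10; BIC tie threshold 1e-9 with
  canonical-order tie-break.
* Grid congruence requires identical shape and affine agreement within
  1e-4 mm; masks read from images binarize at > 0.5.
* Output maps default to 32-bit float storage.
* Collinear covariates raise an error naming the removable columns;
  rank-deficient designs are rejected rather than silently pseudo-inverted.
* Minimum subjects per sequence position: 3 (configurable); sequences
  failing it are dropped from comparisons with a warning.

## Known limitations

* Order-restricted inference (chi-bar-square) is out of scope; the BIC
  comparison treats model complexity as constant across sequences, which
  ignores the effective dimension reduction when constraints bind.  An
  optional sensitivity mode counting only inactive-constraint coefficients
  was considered and deliberately omitted to keep comparisons transparent.
* Cross-path BIC comparisons mix different subject subsets (different n);
  this mirrors the intended use but means the comparison is not a
  likelihood-ratio between nested models.
* The mixture-cutoff degeneracy rule (0.5 pooled SD) cannot certify
  unimodality; genuinely unimodal data occasionally yields a well-separated
  two-component fit.
* No cluster-extent or permutation-based inference for the voxel maps.
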