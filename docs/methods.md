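# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of the methods documentation of mature
scientific libraries: what is computed, under which assumptions, and what
the synthetic validation does and does not establish.

## The microstate model

Resting-state EEG is modeled as a sequence of *microstates*: brief
(~40-100 ms) periods during which the scalp potential topography stays
quasi-stable while only its overall strength (and possibly its sign)
varies. The analysis chain is the classical one:

1. **GFP peaks.** Global field power at time t is the population standard
   deviation of the potentials across the N electrodes (divisor N). GFP
   peaks mark moments of maximal field strength and topographic
   stability; only the scalp maps at GFP peaks enter clustering and
   backfitting.
2. **Template discovery.** Peak maps are clustered with a
   polarity-invariant ("modified") k-means: a map belongs to the template
   with the highest absolute spatial correlation, and each template is
   re-estimated as the first principal direction (leading eigenvector of
   the cross-product matrix) of its assigned maps, renormalized to unit
   GFP. A signed mean is ill-defined when polarity is irrelevant; the
   principal direction is its sign-indeterminate analogue. Goodness of
   fit is the explained variance
   `EV = 100 * sum_i (GFP_i |r_i|)^2 / sum_i GFP_i^2` and the residual
   dispersion `W(k) = sum_i (1 - r_i^2) GFP_i^2`, an orientation-invariant
   within-cluster sum that is non-increasing in k.
3. **Model selection.** The Krzanowski-Lai criterion is applied to W(k)
   over k = 1..12 with feature dimension p = number of electrodes:
   `DIFF(k) = (k-1)^{2/p} W(k-1) - k^{2/p} W(k)`,
   `KL(k) = |DIFF(k)| / |DIFF(k+1)|`. The KL curve's first maximum sits
   at the boundary of the evaluable range, where the initial steep drop
   of W makes KL large by construction; following the "second KL
   maximum" convention we discard it and select the largest *interior*
   local maximum. When no interior local maximum exists (near-geometric
   W curves make KL essentially flat) the global maximum is used and the
   result is flagged.
4. **Two-level clustering.** Templates are first extracted per subject,
   then the pooled individual templates are re-clustered with the same
   algorithm ("meta-clustering") into condition-level or global
   templates. The template count is forced equal across subjects: the
   per-subject KL choices are collapsed to their mode (ties to the
   smaller k) before meta-clustering.
5. **Condition comparison.** Global dissimilarity between maps u, v is
   `GD = sqrt((1/N) sum_i (u_i/GFP_u - v_i/GFP_v)^2)`. For
   average-referenced maps `GD^2 = 2(1 - r)` exactly, with r the spatial
   (Pearson) correlation across electrodes. The permutation TANOVA
   compares paired groups of subject maps: the statistic is the GD
   between the two condition mean maps (each mean re-referenced and
   renormalized), the null swaps condition labels within subject pairs,
   and p-values use the add-one estimator (1 + #{perm >= obs})/(1 + B)
   so p is never 0. Because template polarity is arbitrary, every map is
   sign-aligned to the first group's mean before averaging; without this
   step random sign flips dominate the GD.
6. **Backfitting and metrics.** At every GFP peak the winning template
   maximizes |r| (winner-take-all, ties to the lower canonical label and
   flagged). Each sample takes the label of its nearest peak (interval
   boundaries at midpoints between consecutive peaks; edges extend to
   the recording bounds), and consecutive same-label intervals merge
   into segments. Per template: mean duration (ms), occurrence
   (segments/s), coverage (% of analyzed time, summing to 100 exactly).
   Transitions are counted between consecutive distinct segments and
   row-normalized; directional predominance of the ordered pair (X, Y)
   is `100 (P(X->Y) - P(Y->X))` percentage points, positive when the net
   flow is X to Y, and antisymmetric by construction. No minimum-segment
   smoothing is applied by default.
7. **Group statistics.** Microstate metrics are compared across
   conditions with the aligned rank transform (ART) ANOVA: for each
   effect, the data are aligned (within-cell residual plus the target
   effect's own marginal estimate, all other effects' cell/marginal-mean
   estimates subtracted), midranked, and submitted to a factorial ANOVA
   on the full crossing of the design's factors with a single residual
   error stratum. For the 27-subject, 2-condition, 4-template design
   this yields denominator df 216 - 8 = 208; adding a two-level Side
   factor gives 200; the 6-pair predominance designs give 312 and 300.
   Contrasts follow ART-C: the contrast factors are fused into one
   combined cell factor, the data re-aligned and re-ranked for it, and
   pooled-variance t-tests between cells are Bonferroni-corrected within
   each family. Clinical covariates (outcome, aetiology) enter as
   additional between-subject factors in the crossing. A plain Pearson
   chi-square (no continuity correction) is provided for contingency
   comparisons of clinical characteristics.

## Reference and preprocessing conventions

All analysis operates on **average-referenced** data; readers re-reference
on load. This makes GFP reference-free and the GD/correlation identity
exact. The default preprocessing is a zero-phase 1-40 Hz Butterworth
band-pass; artifact rejection is deliberately out of scope and left to the
user. Peak detection uses strict local maxima (a plateau's first sample),
no smoothing, and a 10 ms minimum separation by default, keeping the
larger of two close peaks; these detector settings are package
conventions, configurable per call.

## The synthetic generator

The generator plants exactly the structure the analysis assumes, so every
stage has a closed-loop recovery test:

* run labels follow a user-supplied first-order chain with zero diagonal
  (default uniform off-diagonal, i.e. no directional asymmetry);
* run lengths are geometric with per-template means (default 70 ms,
  mid-range of the 40-100 ms band); a fixed-length option exists for
  hand-checkable fixtures;
* each run carries a random sign (polarity irrelevance) and a rectified
  10 Hz amplitude envelope anchored at the run start, peak 10 uV -- the
  alpha-dominant eyes-closed regime. Anchoring puts a GFP peak at every
  run onset, making run boundaries detectable in principle;
* spatially white Gaussian electrode noise, scaled by the same envelope
  (so SNR is stationary) with SD `noise_sigma` relative to the unit-GFP
  template norm; 0.3 is the standard validation condition;
* default templates are four analytic dipolar patterns (two diagonal
  gradients, an anterior-posterior gradient, a fronto-central pattern)
  matching the canonical A-D shapes; additional templates are seeded
  smooth random fields kept below |corr| 0.8 pairwise.

What the generator does **not** emulate: 1/f background activity, ocular
and muscle artifacts, volume-conduction-realistic noise correlations,
non-stationary amplitude dynamics, or imperfectly stable topographies
within a state. Passing recovery tests therefore demonstrates the
correctness and internal consistency of the implementation under the
model's own assumptions -- not robustness to every property of clinical
EEG.

### Known resolution limit

With a 50 ms envelope period, runs much shorter than the inter-peak
spacing may contain no detectable GFP peak; such runs are absorbed by
their neighbours and mean durations bias upward. The 10 ms default peak
separation amplifies this by suppressing run-onset peaks that fall close
to a preceding peak. The duration/predominance recovery experiment
therefore disables peak thinning (`min_separation_ms=0`): resolving
segments near the 40 ms end of the band requires the detector's full
temporal resolution. Even so, sub-10 ms runs (a nontrivial mass under
geometric lengths at a 40 ms mean) remain intrinsically invisible, which
is why recovered durations carry a residual upward bias of a few
milliseconds. Real microstate segmentations share this limit.

## Numerical choices

* Clustering restarts default to 50 (validation experiments use 5-10 for
  batch sweeps); restarts alternate between data-map and random-direction
  initializations -- with few maps the map-pair seeds alone can miss the
  global optimum. Convergence: relative EV change below 1e-6, cap 300
  iterations; empty clusters are re-seeded with the worst-fitted map.
* Assignment ties go to the lower template index; canonical labeling is
  greedy one-to-one matching against the built-in A-D reference maps,
  highest |corr| first, extras labeled E, F, ... in residual order.
* Ranks are midranks throughout; Bonferroni adjustment is min(1, m p).
* The degenerate inputs policy: zero-GFP maps raise errors wherever a
  correlation or GD is undefined; templates with no segments report NaN
  duration, zero occurrence and coverage; transition rows with no exits
  give NaN probabilities and missing predominance.

## Validation experiment sizes

The standard conditions, chosen once as realistic for the target study
design: 19-channel 10/20 montage, 256 Hz, 10-minute recordings, noise
0.3, 20 seeded runs for template/count recovery, 3 recordings for metric
recovery, 500 null replicates (type-I) and 100 effect replicates (power)
for the 27-subject ART designs with a 20% B/D duration reduction at 10%
multiplicative noise, and 50 seeded instances of at most 8 maps for the
brute-force clustering oracle.

## Limitations

* TANOVA is implemented at the template level (one map per subject,
  condition and template), not as a sample-wise spatio-temporal test.
* ART covariate handling (between-subject factor in the full crossing)
  is one of several published variants; with heavily unbalanced
  covariates the single-error-stratum F-test is an approximation.
* The EDF writer is minimal (16-bit, one data record, no annotations)
  and intended for synthetic exports and fixtures, not clinical archival.
* No artifact rejection, ICA, or source modeling is provided.
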