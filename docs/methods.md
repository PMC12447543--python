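# Methods

This note documents the statistical procedures, the synthetic-study
generative model, the numerical conventions, and the design decisions that
were genuinely open.

## Fixation preprocessing

Fixation events arrive as a tab-separated report (one row per fixation,
columns documented in `gazersa.fixations.REPORT_COLUMNS`).  Coordinates are
0-based with x = column, y = row, origin top-left; real-valued positions
are rounded half-away-from-zero to pixel indices.  Trial exclusions are
applied sequentially, and an excluded trial is attributed to the first rule
it violates:

1. the trial did not begin with a central fixation;
2. every fixation fell outside the image extent;
3. fewer than three total fixations;
4. fixation durations summing to less than 1000 ms.

Rules 1-2 are reported as percentages of all trials, rules 3-4 of the
trials remaining after the earlier rules, matching how sequential exclusion
cascades are conventionally reported.  Participants with fewer than 18
usable trials are then removed.  Two asymmetries are deliberate: the
*trial*-level off-image rule fires only when the participant looked
exclusively off-image, whereas individual off-image fixations are silently
dropped from density maps; and the fixation-count rule uses the full event
list, since the report does not say whether off-image events were removed
before counting.

**Density maps.** The first fixation of each trial is dropped (it is the
forced center start).  Remaining in-image fixations add 1 at their rounded
pixel; the count image is convolved with an isotropic Gaussian of
sd `sigma_px` (default 7.21 px on the full 1000×1000 grid) and min-max
rescaled to [0, 1].  The −6 dB low-pass cutoff sometimes quoted for this
filter is stored as metadata only: the cutoff-to-sigma convention is not
reproducible from a cutoff value alone, so the sigma is the operative
parameter.  "Circular boundary" is interpreted as a circularly symmetric
(isotropic) kernel with zero-padded edges — wrap-around convolution would
bleed gaze mass between opposite image edges, which is physically wrong.
Smoothing is separable with the kernel truncated at 8.5σ (tail mass below
1e-15), which the tests verify against a dense 2-D convolution to 1e-8.
A constant smoothed map rescales to all zeros by convention; a trial with
zero countable fixations is an error, not an empty map.

## RSMs and representational similarity

An RSM is the item×item Pearson-correlation matrix of response vectors
(flattened density maps, or voxel patterns with ventral/dorsal subdivisions
appended before correlating).  Zero-variance vectors raise an error naming
the item rather than propagating NaNs.

Representational similarity uses only the strictly lower triangle
(the unit diagonal carries no information and would distort ranks), with
Spearman rank correlation and average ranks for ties.  Per participant and
ROI, each of the fMRI subjects' RSMs is first restricted to exactly the
scenes that participant viewed; the per-subject rhos are then averaged
arithmetically (no Fisher-z — plain averaging is the stated convention this
package follows, and at |rho| < 0.4 the difference is negligible).  RSMs
are never averaged across fMRI subjects before correlating: a mean RSM can
misrepresent the shared geometry, and the test suite includes a
counterexample where mean-RSM-first disagrees with the per-subject path.

**Salience control.** "Controlling for" a salience RSM is implemented as a
*partial* (both sides residualized) rank correlation: gaze and fMRI lower
triangles are rank-transformed, residualized on the nuisance ranks by least
squares with intercept, and the residuals Pearson-correlated.  A
semi-partial variant was considered and rejected as the default because the
salience confound operates on the gaze side and the fMRI side (early visual
cortex encodes the same low-level features), so symmetric removal is the
conservative choice.  If the gaze triangle is fully explained by the
nuisance, the partial rho is defined as 0.

**Noise ceiling.** Per data source, a leave-one-out construction over
subjects' RSM lower triangles: the upper bound averages each subject's
Spearman rho against the mean triangle including that subject, the lower
bound against the mean excluding it.  The combined ceiling is the product
of the gaze and fMRI bounds — measurement noise in the two sources
attenuates the observable correlation multiplicatively.  The gaze ceiling
is computed per age group over the scenes common to the group's
participants.  Note the include-self upper bound converges to zero only
like 1/sqrt(n subjects) for pure noise; the lower bound is the unbiased
null-centered one.

## Group inference

The central model is `rho ~ age * ROI + (1 | participant)` with age as a
between-subject and ROI as a within-subject factor, every participant
contributing one rho per ROI.  Because the within design is complete, the
model is fitted by the exact classical split-plot decomposition in two
error strata — subjects-within-groups for age, the subject×ROI residual for
ROI and the interaction — with Type-III sums of squares under sum-to-zero
contrasts (computed as OLS drop tests, so unequal group sizes are handled
correctly).  On balanced data this is algebraically identical to the REML
random-intercept fit; the closed form is preferred because it is
deterministic and optimizer-free, and the test suite verifies equivalence
against an independent textbook decomposition and against
`pingouin.mixed_anova` to 1e-6.  Denominator dfs follow the classical
convention (with 93 infants and 3 ROIs: F(1, 91) for age, F(2, 182) for
ROI and the interaction).  Variance components derive from expected mean
squares, truncated at zero.

Estimated marginal means are the unweighted cell means; their variance
combines the two strata, Var = (MS_subj + (b−1)·MSE_w)/(b·n_g), with
Satterthwaite degrees of freedom.  Post hoc ROI contrasts within an age
group cancel the random intercept (variance 2·MSE_w/n_g, within-stratum
df) and are Holm-corrected *within each age group* — the family is the set
of ROI contrasts for one group.  Between-age contrasts at a fixed ROI mix
both strata and use Satterthwaite df.  Adults are fitted in a separate
ROI-only model (one-group repeated measures, error df (N−1)(b−1)).

**Family-wise error.** `simulate_fwer` estimates, under a global null, the
probability of at least one false rejection *per Holm family* (reported as
the largest per-family rate), because that is the guarantee the Holm
procedure provides.  The pooled probability of a rejection anywhere in a
replicate — across both age-group families — is returned alongside as
`any_rejection_rate`; it is expected to approach 1−(1−α)² ≈ 0.098 and is
not bounded by α, since the two families are corrected separately.

**Power.** `simulate_power` plants a doubly-centered interaction pattern
with root-mean-square effect f (Cohen's f relative to the total within-cell
SD, fixed at 1) and reports the rejection rate of the interaction F test.
The split of unit variance between the subject intercept and the residual
is the `within_subject_correlation` parameter (default 0.5) and is reported
with every result rather than hard-coded: interaction power at fixed f
rises steeply with this correlation, so a power figure is meaningful only
conditional on it.

## Synthetic-study generative model

The generator emulates the study conditions end to end:

- **Scenes.** Each scene carries L (default 3) independent feature maps:
  Gaussian-smoothed standardized white-noise fields, exponentiated and
  normalized to probability maps.  The smoothing length scale per level is
  the operational definition of "abstraction level" and must be strictly
  increasing.  Per level, a coarse 12×12 block-average of the map
  (D = 144) is the scene's embedding for voxel readout.
- **Gaze.** An age-group profile holds mixture weights over the levels;
  fixations are i.i.d. samples from the weighted mixture of the scene's
  maps, preceded by a synthetic center-start fixation (the one
  preprocessing drops).  Durations are log-normal with mean
  total-look / fixation-count (defaults near observed per-trial values:
  ~3.0-3.6 s total looking over ~9-10 fixations for infants, ~4.3 s over
  ~16 for adults); durations only feed the exclusion rules, never the
  RSMs.
- **Voxels.** An ROI profile holds level loadings, a voxel count and a
  noise sd.  Per fMRI subject and level, a random orthonormal basis
  (columns orthogonal to the constant vector) maps the standardized
  embedding to voxel space; patterns are the loading-weighted sum plus
  Gaussian noise.  The orthogonal construction makes the noise-free
  pattern RSM *exactly* equal to the embedding RSM, giving the tests a
  closed-form oracle, and different subject seeds share geometry but not
  voxel responses.  It requires n_voxels ≥ D+1 = 145.
- **Salience.** The level-1 map doubles as the salience nuisance, so "gaze
  driven purely by salience" makes the salience-partialed similarity a
  planted null.

**Demo configuration** (30 scenes, 64×64 maps, 20 participants per group,
200 voxels, 8 fMRI subjects): young infants weight the levels (1, 0, 0),
older infants (0.5, 0.5, 0), adults (0.45, 0.45, 0.1); the three ROIs each
load one level; each participant views every scene once.  Feature scales
are 8/10/13 px with density-map smoothing at half the finest scale (4 px).
The scales sit close together by design: level geometries dissociate
because the fields are *independent*, not because the scales differ, while
measurement reliability under sparse fixation sampling (~9 events/trial)
falls with decreasing scale — widely separated scales would therefore turn
equal mixture weights into unequal measured similarity, misrepresenting an
equal-weight gaze policy.  With near-equal scales the demo reproduces the
intended qualitative structure (young: low ≫ mid ≈ high ≈ 0; old/adult:
low ≈ mid > high ≈ 0) with combined noise ceilings of roughly 0.2-0.45.

**What the generator does not emulate.** Natural-image statistics, saccade
dynamics and oculomotor biases (center bias beyond the dropped first
fixation, saccade amplitude distributions), hemodynamics, inter-scene
semantic similarity, and attention-holding (looking-time) effects.  Passing
tests therefore certify the *pipeline* — that planted representational
structure of known shape is recovered and tested correctly — not that real
infant gaze has any particular structure.

## Problem sizes and numerical conventions

- Reduced scale throughout the test suite: 64×64 (or 32×32) maps, 8-30
  scenes, up to 20 participants per group, 150-200 voxels, chosen so the
  full suite and the Monte-Carlo harnesses run comfortably on one CPU.
- Monte-Carlo harnesses: 2000 replicates for the null FWER estimate
  (binomial SE ≈ 0.005), 500 for the null-calibration KS check, 100
  replicate studies for pattern recovery.
- Spearman ties get average ranks; RSM symmetry, unit diagonal and entry
  bounds are asserted at construction to 1e-12; restrict-then-build equals
  build-then-restrict to 1e-12.
- Density-vector decimation before the large Pearson correlations is not
  performed; at full 10^6-pixel scale the separable convolution and
  `numpy.corrcoef` remain the dominant but tractable costs.

## Known limitations

- The split-plot fit requires a complete within-subject design (every kept
  participant contributes every ROI); participants who lack an ROI must be
  dropped upstream.
- Type-III between-group tests with more than two unbalanced groups follow
  the unweighted-means convention and are cross-checked only for the
  two-group and balanced cases.
- The noise-ceiling construction assumes the leave-one-out scheme; other
  ceiling estimators (e.g. split-half) are not implemented.
- `simulate_power` speaks about the planted interaction pattern only; power
  for main effects or specific contrasts would need their own harness.
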