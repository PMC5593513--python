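# Methods

## The connectivity index

The central statistic is a within-network connectivity index (CI). Given a
spatial pattern X(v) over n in-mask voxels and a run Y(v, t) of m volumes,
each volume is fit across voxels by ordinary least squares,

    Y(v, t) = X(v) β(t) + ε(v, t),    σ(t) = SD_v(ε(v, t)),    η(t) = β(t)/σ(t),

and CI = Var_t(η(t)) with n−1 normalization. η(t) measures how strongly the
pattern as a whole is expressed in volume t relative to everything the
pattern does not explain, so its temporal power indexes co-activation
(functional integration) of the network rather than overall signal amplitude.

Choices that the formulation leaves open, fixed here:

- **Run normalization.** Before regression, every in-mask voxel series is
  divided by a single pooled scalar: the sample SD of all in-mask voxel-time
  samples after removing each voxel's temporal mean. A per-voxel scalar would
  make the operation a per-voxel standardization and change the spatial GLM;
  the pooled scalar is a pure global rescaling whose only role is to make
  runs comparable. CI is exactly invariant to it (and to any global rescaling
  of the data) — the invariance is asserted in the tests rather than assumed.
- **Intercept.** The spatial GLM includes an intercept so that per-volume
  global offsets do not leak into β(t). `include_intercept=False` gives the
  literal no-offset model for sensitivity analyses.
- **σ(t)** is the sample SD (ddof 1) of the cross-voxel residuals. Any
  df-correction constant is common to all volumes and cancels in every CI
  comparison. The (XᵀX)^{-1/2} factor that would make η a proper t statistic
  is likewise constant over t and is deliberately not applied.
- **Degenerate volumes** (residual SD numerically zero, i.e. a volume exactly
  proportional to the pattern) are flagged, dropped from the variance with a
  warning, and CI requires at least 10 defined η values.

Scale laws, asserted exactly: CI(cY, X) = CI(Y, X); CI(Y, cX) = CI(Y, X)/c².
Cross-run CI ratios are therefore invariant to a common pattern rescaling.

## Dual regression

Stage 1 is the same spatial GLM; the resulting β(t) series is z-scored (mean
removed, unit SD, so coefficients are comparable across runs) and used as the
predictor of a per-voxel temporal regression with intercept. The stage-2
coefficient map localizes which voxels carry the pattern's co-activation.
With several group patterns, joint entry in stage 1 (multivariate spatial
fit) is supported; separate single-pattern analyses are the default, matching
how learning and consolidated patterns are analyzed independently.

Group inference replaces parametric mixed-effects modeling with sign-flip
permutation: the observed paired one-sample t map is converted to Z, clusters
are formed at Z = 2.3 (two-sided), each cluster's mass is Σ(|Z| − threshold),
and corrected p values compare observed masses against the permutation
distribution of the image-wise maximum mass ((1 + #{null ≥ obs})/(P + 1)).
This is exact under exchangeability at any problem size and needs no
smoothness estimation. The repeated-measures interaction across resting
conditions is run as a paired contrast of per-subject difference maps
(differences of differences), which is the exact interaction contrast for a
2×2 within-subject design.

## Seed-based connectivity

ROIs are closed-ball spheres (default radius 6 mm) around mm-space centers;
voxel membership is by voxel-center distance through the image affine, with
0-based indices (a 6 mm sphere on a 2 mm isotropic grid contains exactly 123
voxels — the frozen lattice-enumeration oracle that pins the convention).
Registration through subject space is out of scope; masks are built directly
on the analysis grid.

The subject-level model per voxel: ROI mean series, its temporal derivative
(first difference, zero-padded first sample), white-matter mean, CSF mean,
global mean, six motion parameters, intercept. The connectivity value is the
ROI coefficient. The map is exactly invariant to adding any linear
combination of the nuisance regressors to the data (tested to 1e-8), which is
the operational meaning of "nuisance removal". Group maps regress paired
condition differences on each subject's overnight behavioral gain
(permutation of gain labels, cluster mass correction at Z = 2.7); a constant
gain vector degenerates to the paired mean contrast and is flagged. The ROI
family is controlled by Bonferroni, alpha/12 for the canonical 12-seed set.
The ΔFC scalar correlated with gains is a regression coefficient (consistent
with the GLM formulation) rather than a correlation.

The shipped `default_roi_table()` carries twelve sensorimotor labels with
synthetic MNI-plausible placeholder coordinates, for interface realism only.

## Temporal dynamics

Hypnogram-driven epoch selection takes maximal same-stage runs strictly
longer than 50 volumes ("more than 50" read as strict; the boundary is
pinned by a test). Movement-artifact volumes always break segments. Epochs
are concatenated per condition and both conditions truncated to
min(available MSL, available CTL, 600) volumes. Windows of 100 volumes slide
in 50-volume steps: floor((T − w)/s) + 1 windows, 11 for the canonical
600/100/50 design; partial tails are discarded (the 600 → 11 arithmetic
confirms no partial windows). Because the spatial regression is per-volume,
η(t) is computed once on the concatenated series and each window statistic
is the variance of its η values; a window spanning the whole series equals
the full-series CI exactly. Windows are allowed to straddle epoch seams, as
the concatenate-then-window procedure implies. Longest-segment ties break to
the earliest start. The window-size robustness analysis contrasts CI over
the first n versus last n volumes for n = 50…300.

## Task GLM

The task regressor is a boxcar whose per-block height is the block's
performance speed normalized to unit mean weight (so equal speeds reproduce
the unweighted design), with fractional TR overlap at block edges, convolved
with a canonical double-gamma HRF (response gamma shape 6, undershoot shape
16, both scale 1 s, undershoot ratio 1/6 — field-standard constants; the
kernel is peak-normalized to 1 and is zero at t = 0). Voxelwise OLS with six
mean-centered motion confounds gives effect and variance maps; the group
stage is a voxelwise paired t on effect maps converted to Z (a deliberate
replacement of parametric mixed-effects estimation at desk scale). Patterns
are voxels with Z > 3.5, retaining their Z values as weights by default
(binarization available — both behaviors are tested). Activation volumes are
suprathreshold counts times voxel volume, reported in cm³ for total,
cortical and subcortical masks.

## Behavioral scoring

Speed is the mean inter-key interval for correct responses; intervals
spanning an incorrect press are discarded (only correct→correct consecutive
pairs enter speed and variability). Variability is the sample SD (ddof 1) of
those intervals. Accuracy is percent incorrect presses; a sequence-level
variant (percent fully-correct 5-press groups) is also provided since both
readings of "accuracy" are in use. For the chord control task the response
time is the earliest of the four finger presses. The overnight gain is
mean(speed, last three S1 blocks) − mean(speed, first three S2 blocks),
positive = faster after sleep, also expressed as percent of end-training
speed.

Correctness against the cyclic sequence 4-1-3-2-4 needs a resynchronization
rule (not fully determined by the task description): an expected pointer
advances on a match; on a mismatch the press is incorrect and the pointer
re-anchors just past the nearest forward occurrence of the pressed key
within one cycle, else stays. The rule is deterministic, local, and
reproducible by hand on toy logs, which the tests do.

## Statistics

`rm_anova2` implements the two-factor fully-within-subject decomposition,
each effect tested against its subject-by-effect interaction (df identities
(a−1), (b−1), (a−1)(b−1) over df×(n−1)); no sphericity correction is
applied, matching designs reported with uncorrected df. It is cross-checked
against an independent implementation (statsmodels `AnovaRM`) in the tests.
Power for the paired two-sided t uses the noncentral t distribution with
noncentrality (mean/SD)·√n; it is verified against Monte-Carlo rejection
rates. Follow-up paired t tests are reported without multiplicity
correction, a documented caveat.

## Synthetic data

The generator emulates the study design: two conditions (sequence learning
vs. rate-matched chord control), sessions RS1–RS3, S1, S2 and an EEG-scored
sleep run, for a cohort of subjects. The signal model is additive:
baseline + Σ_p a_p(t)·X_p(v) + nuisance + i.i.d. Gaussian noise — the
simplest model under which the CI has an analyzable ground truth. In
stochastic mode a_p(t) = envelope(t)·z(t) with z a unit-variance AR(1)
latent (lag-1 correlation 0.5), so the envelope directly controls the SD of
the pattern's co-activation, the quantity CI estimates; deterministic mode
uses the envelope verbatim, giving machine-precision reconstruction oracles
on noiseless runs. Nuisance comprises a global AR(1) signal, linear drift
with random voxel loadings, a motion-coupled component generated as a linear
mixture of the emitted motion traces (so the seed-connectivity model can
demonstrably remove it), and WM/CSF compartment signals on concentric-shell
toy tissue masks.

Defaults are the study conditions: TR 2.16 s, 600-volume sleep series,
150-volume resting runs, 14 blocks of 60 presses per session, sequence
4-1-3-2-4, 2% key error probability, an exponentially decaying learning
curve (plateau 0.30 s, span 0.20 s, time constant 3 blocks) with a planted
overnight gain, and a 1/3 s chord rhythm for the control task. The cohort
couples each subject's sleep coupling gain g_i and behavioral gain b_i
through a bivariate Gaussian with exact population correlation (default
0.72), so correlation recovery is a parameter-recovery test. The default
analysis grid is 20³ (12³ in the heavier recovery suites) rather than scanner
resolution — chosen so the full pipeline runs at desk cost; all estimators
are resolution-agnostic.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: spatial autocorrelation and physiological noise
spectra, hemodynamic convolution of the coupling processes, registration and
motion-correction residuals, EEG scoring uncertainty, and non-Gaussian
behavioral timing. Recovery results demonstrate correctness of the
estimators under the stated model, not robustness to scanner artifacts.

## Numerical conventions

Least squares throughout uses `numpy.linalg.lstsq`/normal equations with
explicit rank checks that name collinear columns. t→Z conversion goes
through the upper tail symmetrically and clips at |Z| = 38 to avoid
underflow. Sample statistics use ddof 1 unless stated. Permutation p values
include the identity term ((1 + k)/(P + 1)) and are therefore never zero.
Degenerate inputs (constant runs, constant patterns, zero-variance stage-1
series, empty masks, missing design cells) raise errors that list the
offending pieces rather than propagating NaNs.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations use 12³ grids with 150–600
volume runs, 12–16 subjects for group analyses, 200 subjects for scalar
correlation recovery, 200 replicates for null-calibration suites, and
500-permutation cluster inference. These sizes were chosen so the complete
validation runs in seconds while keeping every recovery margin wide (e.g.
3·SE tolerances, ±0.1 on recovered correlations).

## Known limitations

- Group inference is permutation-based; parametric mixed-effects (FLAME-style
  variance weighting) and Gaussian-random-field cluster correction are not
  implemented.
- No Greenhouse–Geisser sphericity correction in the repeated-measures ANOVA.
- The voxelwise repeated-measures ANOVA across three resting conditions is
  realized as paired differences-of-differences with permutation, which is
  exact for 2×2 contrasts but not a full three-level error decomposition.
- Preprocessing (slice timing, motion correction, registration, smoothing,
  high-pass filtering) is out of scope; inputs are assumed preprocessed, and
  the generator produces data in that state.
- ICA extraction of control networks is out of scope; control patterns are
  accepted as externally supplied maps and the CI machinery applies
  unchanged.
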