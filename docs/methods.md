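# Methods

## Model

For one subject, the dimension-reduced BOLD data at vertex `v` of a cortical
surface mesh are modeled as

    y(v) = A s(v) + e(v),      e(v) ~ N(0, ν I)
    s(v) = μ0(v) + δ(v),       δ(v) ~ N(0, diag(σ0²(v)))

where `s(v)` is the Q-vector of subject-level independent-component (IC)
values, one component per resting-state network, `A` is the subject's
mixing matrix in the reduced time dimension, and `ν` is the residual
Gaussian noise variance. The population prior — the *template* — consists of
the mean maps `μ0` and the vertex-wise between-subject variances `σ0²`,
estimated empirically from a disjoint template cohort. Because prior and
likelihood are Gaussian, the vertex-wise posterior of `s(v)` is Gaussian in
closed form conditional on `(A, ν)`; those two parameters are estimated per
subject by EM.

Assumptions worth keeping in mind:

- Deviations `δ(v)` are independent across vertices and components
  (diagonal `Σ0`, no spatial process on the deviations).
- Noise is isotropic in the reduced space (scalar `ν`). The reduction makes
  this reasonable even when the raw noise is not white.
- The same `A` applies at every vertex — the defining assumption of a
  spatial ICA decomposition.

## Empirical prior (template)

Each template subject's run is split into two contiguous halves
("pseudo-sessions") and dual regression is applied to each half against the
group IC maps, giving noisy point estimates `s_ij` (subject `i`, session
`j`). Then, per IC and vertex:

- prior mean: grand average of the `s_ij` over subjects and sessions;
- total variance: across-subject variance computed per session, averaged
  over the two sessions (unbiased `n−1` denominator);
- within-subject (noise) variance: half the across-subject variance of the
  session difference `s_i2 − s_i1`;
- between-subject variance: total minus within, clamped at zero.

The clamp is required because the difference of two noisy variance
estimates can be negative, and the EM model needs a non-negative prior
variance. Stage-1 dual-regression time courses are variance-normalized
before stage 2 (standard practice; makes map magnitudes comparable across
subjects); this normalization is a flag and can be disabled.

Template subjects are excluded from all downstream analyses; the pipeline
helpers take explicit disjoint index sets.

## Subject fit

The run is centered per vertex and projected onto its top `Tr` left
singular directions; `Tr = Q + 5` by default (capped at `T − 1`), giving
headroom above the signal rank for noise estimation. The initial `ν` is the
discarded singular-value energy averaged over the elements of the data
matrix; the initial mixing matrix is the projection of the subject's
variance-normalized dual-regression time courses into the reduced space.

EM then alternates:

- E-step: exact vertex-wise Gaussian posterior moments given `(A, ν)`.
  Vertices whose prior variance is clamped at zero are treated as hard
  constraints (the component is fixed at `μ0` and carries zero posterior
  variance) rather than inverted.
- M-step: closed-form maximum-likelihood updates of `A` and `ν` from the
  posterior first and second moments.

Convergence is the maximum relative change of `A` (Frobenius) and `ν`
falling below `tol` (default 1e-3, `max_iter` 100). The recorded
`loglik_trace` is the evidence lower bound evaluated after each E-step;
since the E-step posterior is exact this equals the marginal log-likelihood
of the current parameters, the quantity EM provably never decreases — the
expected complete-data log-likelihood alone carries no such guarantee, so
ascent is asserted on this trace. Hitting `max_iter` returns
`converged=False` rather than raising; non-finite parameters abort with
diagnostics.

The reported per-IC uncertainty is the marginal posterior SD (square root
of the diagonal of the vertex posterior covariance); "standard error maps"
are read as exactly this quantity.

Scaling: the library functions operate on the data as given and apply no
per-run standardization. The synthetic cohorts share one physical scale by
construction, and dividing each run by its own total SD would inject
artificial between-subject scale variance into the pseudo-session variance
decomposition. For real data with arbitrary per-run scaling, standardize
before calling `estimate_template`/`fit_subject` — consistently for the
template and the analysis cohort.

The pipeline wrapper applies a small floor (`1e-3` of the largest `σ0²`)
to the template variance before fitting, so posteriors are proper
everywhere and downstream t-maps are defined; informative vertices are
unaffected. The unfloored zero-variance path remains fully supported and
tested at the library level.

## Inference and cohort statistics

- t-maps: posterior mean over posterior SD, elementwise.
- Engagement: one-sided Bayesian test of `P(s ≤ γ)` from the Gaussian
  posterior, with Bonferroni correction over the in-mask vertices *within
  each IC* (family size `m = V_mask`); default `γ = 0`, `α = 0.05`.
  Engagement means credibly exceeding `γ`, hence one-sided. The per-IC
  family matches the per-IC binary masks the test produces; consequently
  family-wise error is controlled per IC, not jointly over all `Q` masks.
- Winner-takes-all parcellation: per-vertex argmax over ICs of the
  (unthresholded) t-score, ties to the lowest IC index, label 0 outside
  the analysis mask. The group parcellation applies the same kernel to the
  group maps.
- Connectivity strength: mean t-score within the engagement mask, weighted
  by midthickness vertex area. Empty masks yield flagged-undefined (NaN)
  strengths, excluded listwise per IC.
- Age association: partial Spearman — rank age and strength (average ranks
  for ties), residualize both rank vectors on an intercept plus sex and
  motion, correlate the residuals; two-sided p from the t approximation
  with `N − 2 − K` degrees of freedom. At cohort sizes of 30+ this is
  indistinguishable from exact permutation-based evaluations at the 0.05
  level. The motion covariate is the outlier-frame count inside the
  retained block. Uncorrected p-values are reported per IC alongside
  Bonferroni-corrected ones.
- Frequency map: per-vertex modal label across subjects' parcellations and
  the percentage of subjects carrying it; modal ties to the lowest label.

## Censoring and QC

DVARS is the root-mean-square across vertices of the frame-to-frame
intensity difference (frame 0 set to 0). A frame is an outlier when its
DVARS exceeds Q75 + 1.5·IQR of the whole session (linear-interpolation
quantiles; strict inequality, so a constant series yields no flags). The
retained block is the contiguous window of the target length with the
fewest outliers (earliest start on ties, found by exhaustive cumulative-sum
scan); a subject is excluded when strictly more than
`floor(0.10 × block_length)` in-block frames are flagged — more than 160
frames of a 1600-frame (10-minute) block at the reference acquisition.
Note the outlier rule is session-relative: it presumes corrupted frames
are a minority, and degrades once roughly a quarter of frames are
corrupted (the 75th percentile then sits inside the corrupted mass).

tSNR per subject and vertex is |temporal mean| / temporal SD; the cohort
map is `10·log10` of the across-subject arithmetic mean of linear SNRs.
Zero-variance vertices propagate NaN and are reported, never dropped.
Synthetic runs emulate demeaned, denoised BOLD, so their absolute dB level
is far below scanner values; the dB arithmetic is validated on constructed
inputs with known SNR.

Surface smoothing is iterated graph diffusion `x ← x − τ L x` with the
combinatorial Laplacian `L` and `τ = 0.5/deg_max`, which preserves the map
sum exactly, keeps non-negative inputs non-negative and fixes constants.
The step count is calibrated so the accumulated per-coordinate random-walk
variance matches `σ² = FWHM²/(8 ln 2)` in edge-length units; an FWHM below
one edge length is the identity. Masked-out vertices are untouched and
diffusion cannot cross the mask boundary, so disconnected mask components
smooth independently.

## Synthetic cohorts

The generator produces exactly the structure the model assumes, plus
controlled violations (motion spikes, age effect):

- Mesh: triangulated jittered Fibonacci sphere (default radius 50 mm) or a
  unit-spacing square grid; vertex areas from incident-triangle thirds.
- Group maps: geodesic Gaussian blobs (amplitude 3 in arbitrary BOLD
  units) at greedily farthest-separated centers, width one third of the
  typical center separation — the simplest topography giving distinct,
  limitedly overlapping networks.
- Between-subject SD: 0.3 × |group map| plus a 0.05 floor; deviations are
  vertex-independent Gaussians (an optional smoothing parameter exists but
  defaults off, matching the model).
- Time courses: temporally smoothed Gaussian processes, orthogonalized and
  scaled to unit variance — emulating the near-independent unit-scale time
  courses an ICA decomposition implies.
- Age effect: a multiplicative amplitude factor `1 + β(age − 41)` on the
  subject's mixing columns, ages uniform on 37–45 weeks PMA. Amplitude,
  not topography, because the cohort statistic of interest is within-
  network strength. The study-condition slope is β = 0.08/week (≈ ±30%
  amplitude across the age range).
- Noise: i.i.d. Gaussian, study-condition SD 3.0 against blob amplitude 3
  — a regime where dual regression is visibly noisy and the Bayesian maps
  measurably cleaner.
- Motion: per-subject corrupted-frame fraction uniform on 0–8%, arranged
  in geometric bursts (mean 4 frames); corrupted frames get a global
  intensity jump of 2.5 × the clean-data RMS with random sign — large
  enough that isolated spikes always trip the session-relative DVARS rule,
  mild enough that the few spikes tolerated inside a retained block do not
  dominate a fit.

What the generator does not emulate: hemodynamics, physiological noise
spectra, spatial noise correlation, registration error, non-stationary
amplitude, topography change with age. Passing tests therefore demonstrate
the estimators' correctness and calibration under the model (plus spikes),
not robustness to everything real neonatal fMRI contains.

## Problem sizes and reproducibility

The bundled analyses and checks run on meshes of 250–400 vertices, 3–4
networks, 300-frame runs and cohorts of about 100 subjects (35 template +
80 analysis), with a retained-block fraction of 0.7 mirroring the
best-10-of-14 minutes acquisition geometry. These sizes keep every stage's
estimation problem well-posed (T ≫ Tr ≥ Q, N large enough for stable
variance estimates) while the full suite completes in minutes; all
generators and fits are deterministic given their seeds.

## Known limitations

- The session-relative outlier rule fails when corruption is pervasive
  (see above); the generator's motion levels stay below that regime.
- Between-subject variance recovery is unbiased only when subjects share a
  common amplitude scale; an age effect adds genuine amplitude dispersion
  that the decomposition correctly books as between-subject variance but
  that is not part of the generative map variance.
- The diffusion smoother approximates a geodesic Gaussian; its effective
  kernel is accurate to within the mesh's irregularity, not exact.
- Dual regression inside the template stage inherits the usual cross-talk
  bias when subject maps deviate strongly from the group maps.
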