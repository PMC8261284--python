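# Methods

`viscereb` analyses directed (effective) connectivity in a four-region
"visual–cerebellum" network — primary visual cortex (PV), left and right
secondary visual cortex (SV_L, SV_R), cerebellum (C) — from resting-state
BOLD time series, and ships a synthetic-cohort generator so the entire
chain is testable without any imaging download.  This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not show.

## Generative model (synthetic cohorts)

Latent neural activity follows a continuous-time linear stochastic system

    dx/dt = A x + w(t),        w white with SD `innov_sd` per sqrt(s),

integrated by Euler–Maruyama at `dt = 0.1 s` from a stationary initial
draw.  `A` is the 4×4 coupling matrix: off-diagonal entry (i, j) is the
influence of region j on region i in 1/s; self-connections are
parameterized as `a_ii = −0.5·exp(θ_i)` so they are negative by
construction.  Stability (all eigenvalue real parts < 0, margin 0.01) is
enforced on every realized matrix.

Observed BOLD: each ROI channel is the convolution of its neural state
with a canonical double-gamma hemodynamic kernel (positive lobe peaking at
6 s, undershoot at 16 s, 1:6 amplitude ratio, 32-s support), sampled at
TR = 2 s for 180 volumes.  Each of the 50 voxels per ROI is a positive
loading (1 ± 0.2) times the ROI signal, plus a mixture of nine nuisance
series (six smooth motion-like random walks, three AR(1) global/WM/CSF
signals) with per-voxel coefficients, a per-voxel linear drift, a baseline
of 100 scanner units, and white noise (SD 0.8, i.e. voxel-level contrast
to noise near 1).

Group templates.  Couplings were chosen to be hierarchical and
asymmetric, as cortical visual pathways are: strong feedforward
PV→SV (0.28 1/s), weak feedback SV→PV and interhemispheric SV↔SV (0.03),
moderate PV→C (0.10) and weak C→PV (0.02).  Controls have exactly zero
coupling between the cerebellum and either secondary visual cortex;
patients have all twelve couplings positive, with C→SV_L, SV_L→C and
SV_R→C elevated above the control value by the group effect (default
0.15 1/s) and C→SV_R at 0.03.  Patient cerebellar self-connections are
slightly stronger (−0.48 vs −0.41 1/s); self-rates are deliberately slow,
both because slow intrinsic timescales dominate resting-state BOLD and
because the identifiability analysis below shows slow dynamics are where
couplings are best estimated at TR = 2 s.

Between-subject variability is Gaussian jitter on the non-zero template
entries (SD 0.16 1/s) and on the self log-scalings (SD 0.10), redrawn on
stability failure (≤100 redraws, then the SD halves).  The jitter SD was
fixed at design time from the identifiability analysis: subject-level
estimation error at T = 170 is bounded below by ≈0.09–0.13 1/s (spectral
Cramér–Rao), so between-subject structure narrower than that cannot be
resolved; 0.16 matches the broad subject scatter that resting-state
coupling estimates show in practice.

Clinical scores are linear in planted couplings plus noise, standardized
against the generator's own template and jitter scales so the marginal
moments match the study population table (JOA 11.8 ± 1.5; ETDRS letters
75.9 ± 3.8 OD / 76.1 ± 3.2 OS pre-op; recoveries 2.10 ± 3.1 / 2.12 ± 3.2;
post ≡ pre + recovery exactly).  Pre-operative acuity of both eyes tracks
the cerebellar self parameter, left/right-eye recovery track C→SV_L /
C→SV_R, and the motor score tracks a seven-parameter cerebellum-centred
combination; default link strength is R² = 0.25 per score.  All scores are
continuous (no integer rounding of the discrete clinical scales).

Every random quantity derives from a master seed through fixed affine
per-subject offsets; regenerating a cohort from its stored configuration
is bit-identical.

## Temporal preprocessing

Fixed order, recorded in provenance: drop the first 10 volumes → remove a
per-channel least-squares line → zero-phase 4th-order Butterworth filter
(a 0–0.08 Hz band is realized as a low-pass at 0.08 Hz; DC and drift are
handled by the detrend) → regress out the nine nuisance covariates plus
intercept, with the regressors themselves detrended and filtered
identically so the residual cannot re-acquire out-of-band frequencies →
summarize each ROI by the first eigenvariate (leading left singular
vector of the demeaned time × voxel matrix, unit variance, sign aligned
with the across-voxel mean course).  Two temporal-SNR definitions are
provided: the conventional mean/SD of the raw series, and the
signal-SD/noise-SD ratio of a cleaned/residual decomposition; reports
label which was used.  Group tSNR comparisons use Welch's unequal-variance
t-test throughout (27 vs 11 subjects are unbalanced).

## Subject-level estimation

The inversion is an explicitly simplified linear-Gaussian surrogate for a
full variational stochastic model inversion.  The latent model above is
discretized exactly at TR: transition `Φ = expm(A·TR)`, process noise
`Q_d = Σ − Φ Σ Φ'` with `A Σ + Σ A' + q I = 0` (no Euler bias at
TR = 2 s).  The hemodynamic kernel acts as a fixed, known FIR observation
kernel of 16 TR-wide bin integrals of the double-gamma function (the taps
sum to the analytic kernel integral exactly); hemodynamic parameters are
not estimated.  Observation noise is white with a single variance r.

The likelihood is the exact Gaussian state-space likelihood, computed by
a Kalman filter on the lag-stacked (64-dimensional) state.  The filter
freezes its gain once the covariance recursion converges (relative
tolerance 1e-10), which is numerically indistinguishable from the full
recursion; the implementation is pinned against a brute-force
joint-Gaussian oracle (dense block-Toeplitz covariance) to 1e-6 in tests.

Priors: independent Gaussians, zero mean, variance 1/16 for off-diagonal
couplings and 1/64 for self log-scalings; the two log noise variances
carry weak log-normal priors (SD 2 in log space) centred on a
moment-based split of the observed variance.

Optimization is two-stage: (1) the Whittle (spectral) approximation of
the log-joint, whose analytic gradients make it cheap, is maximized from
the prior mean; (2) the exact Kalman log-joint is then polished by
L-BFGS-B (finite-difference gradients, step 1e-5, up to 80 iterations,
convergence when the projected gradient falls below 2e-4).  The joint
optimization over the 16 couplings and the two log noise variances
replaced interleaved hyperparameter updates because the quasi-Newton path
converges in fewer likelihood evaluations to the same estimand; a single
start suffices in practice (the objective proved well-behaved from the
prior mean, and a moment-matched starting point occasionally landed in
line-search pathologies), with multi-start available via
`InvertOptions.n_starts`.  Unstable iterates are rejected by a penalty at
eigenvalue real parts above −1e-4.

The Laplace posterior covariance uses the spectral (Whittle) Fisher
information — the expected negative Hessian — plus the prior precision,
marginalized over the noise hyperparameters by Schur complement and
floored to symmetric positive definite (eigenvalue floor 1e-8 × trace/16).
Tests confirm it matches finite-difference Hessians averaged over
realizations.  The free energy is the Laplace evidence over the 16
couplings with the noise variances at point estimates.

### Identifiability at desk scale

A spectral Cramér–Rao analysis of this design (T = 170, TR = 2 s, HRF
observation) shows the per-coupling likelihood SE is bounded below by
about 0.09–0.13 1/s for any stable all-positive coupling configuration:
slower networks are more identifiable at this sampling rate, but making
every coupling large (to ease group-level detection) forces faster
self-rates for stability, which inflates the SE in near-exact proportion.
Consequences, measured end-to-end and reported honestly:

- Pooled subject-level recovery of the off-diagonal couplings reaches
  r ≈ 0.73–0.78 (sign accuracy ≈ 0.97–0.99 for |a| ≥ 0.2).  The error SD
  sits at the information bound; differential prior shrinkage costs a few
  further points of correlation.
- Group-level retention of *all twelve* patient couplings at posterior
  probability > 0.95 requires group-level z ≈ 4 for the weakest coupling,
  which no stable all-positive default satisfies: the joint patient-side
  criterion fails in essentially every cohort, although the control-side
  structure (pruning all four cerebellum↔SV connections) is recovered
  essentially always, and most patient couplings individually exceed the
  0.95 rule.

## Group level

Subjects' Gaussian posteriors enter a hierarchical model
`θ_s ~ N(design·β, diag(D))`, estimated by EM on the marginal likelihood
of the posterior means with each subject's posterior covariance as
observation noise; D carries a weak exponential hyperprior (strength 2
pseudo-subjects at scale 1/16) so it cannot collapse at n = 11.  The
default design is intercept-only per group, mirroring per-group analyses;
a two-column joint design is available.  Subject vectors enter unmodified
(no grand-mean removal).  With the between-subject variance forced to
zero and a flat β prior, the fit reduces exactly to precision-weighted
fusion (tested to 1e-10).

Model reduction is the closed-form Gaussian evidence identity in
precision space (reduced prior variances floored at 1e-8); it is pinned
against a conjugate linear-model oracle to 1e-6.  Greedy pruning removes
one parameter at a time while the evidence improves (parameters never
return; ≤16 iterations), records a Bayesian model average over visited
reductions, and per-parameter posterior probabilities use the evidence
on/off comparison `Pp = 1/(1 + exp(−ΔF_keep))`, with the study's
significance rule Pp > 0.95.  Greedy search agreed with exhaustive 2^8
enumeration in ≥95% of random instances in tests.

Frequentist contrasts are Welch t-tests per coupling (uncorrected by
default, Benjamini–Hochberg available); clinical correlations are Pearson
r with two-sided p and scatter data for the figure analogues.

## Prediction (SVR with permutation FWE)

Linear ε-SVR (C = 1, ε = 0.1, pinned numerically) over the 16 coupling
features.  In each leave-one-out fold the model is trained on all
features (z-scored with training-fold statistics only), features are
ranked by |weight| (ties to the lower index), the top fraction is kept
(`k = max(1, round(fraction·16))`, banker's rounding — note
round(0.45·16) = 7, the seven-feature model), a new model is refit on the
kept set and evaluated on the held-out subject.  Fractions sweep
5%–100% in 5% steps; skill per fraction is the Pearson correlation of
held-out predictions with labels.  Significance: labels are shuffled once
per permutation (shared across all 20 fraction models, which is what
makes the maximal-statistic correction valid), the grid re-runs, and the
max-over-fractions |r| forms the null; `p_FWE = (1 + #{null ≥ r_obs}) /
(n_perm + 1)`, significant at p_FWE < 0.05; the best fraction is the
smallest p, ties to the sparser model.  The sensitivity map is the mean
signed weight per feature across folds, zero when unselected.

The inner solver is a hand-written SMO on the ε-SVR dual
(maximal-violating-pair selection with exact per-pair line search over
the L1 segments), compiled with numba because the permutation analyses
need on the order of 10^5–10^6 fits on one CPU; predictions match
sklearn/libsvm to <1e-3 in tests.  The LOOCV/permutation grids run the
solver with a fixed deterministic budget (100·n updates, KKT tolerance
1e-5) applied identically to observed and shuffled labels, so the
permutation test remains exchangeable; the fraction sweep walks the
feature count downward with rank-one kernel downdates and warm starts.

Measured behavior at the study's size (n = 27): the null max-|r| has a
95th percentile near 0.6 — LOOCV predictions under the null carry the
well-known negative-correlation artifact, which the absolute value folds
into the upper tail — while a planted signal of total R² = 0.5 yields
observed r ≈ 0.45–0.65.  FWE-corrected detection therefore succeeds in
only ~25% of replicates; family-wise error control itself holds
(false-positive rate ≈ 0 in 200 null datasets).  This is a property of
the published procedure at this sample size, not of the implementation.

## Problem sizes used by the test suite

Monte-Carlo sizes are the package's own choices for a single-CPU run:
greedy-vs-exhaustive uses 100 instances; group-difference power uses 50
cohorts at generator level (subject-level estimation noise is exercised
separately by the recovery test); FWE control uses 200 null datasets of
12 subjects with 200 permutations; prediction power uses 30 replicates
with 100 permutations; the end-to-end structure test runs 3 full default
cohorts (pass bar 80% as stated, which over 3 cohorts demands 3/3).  Unit fixtures use shortened scans
(70–90 volumes, 8–12 voxels per ROI) where the property under test does
not depend on the full acquisition.

## Known limitations

- The inversion is a linear-Gaussian surrogate: no hemodynamic-parameter
  estimation, no nonlinear (Balloon-type) states, no modulatory inputs.
  Coupling magnitudes are interpretable relative to the surrogate, not as
  fits of a biophysical hemodynamic model.
- The generator produces no spatial structure (no realistic geometry,
  slice-timing or motion artifacts beyond additive nuisance regressors),
  so passing tests demonstrate statistical correctness of the temporal
  chain, not robustness to spatial confounds of real acquisitions.
- Preprocessed series are band-limited while the observation model
  assumes white noise; the mismatch mildly biases timescale estimates
  (absorbed by the self-connections and noise variances) and is part of
  why exact-likelihood estimates do not beat the spectral approximation.
- The bias term of the SVR is recovered from the KKT interval midpoint;
  in heavily degenerate fits the interval can be wide, making per-fold
  predictions sensitive at the 1e-2 level (visible only as solver-level
  wiggle in LOOCV correlations).
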