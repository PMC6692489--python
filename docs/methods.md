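# Methods

This note records the models implemented by `edadecode`, the numerical
choices behind them, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model

A skin conductance recording is treated as the sum of a slowly varying
tonic level, a phasic component composed of discrete skin conductance
responses (SCRs), and measurement noise. The phasic physiology — sweat
release into the duct, diffusion to the stratum corneum, evaporation — is a
cascade of two first-order systems with rise and decay time constants
`tau_r` and `tau_d`:

    dx1/dt = -x1/tau_r + u/tau_r
    dx2/dt =  x1/tau_d - x2/tau_d

where `u(t)` is the sudomotor drive and `x2` the phasic conductance. With
an empty duct at t = 0, a unit impulse produces the unit-area kernel
`h(t) = (exp(-t/tau_r) - exp(-t/tau_d)) / (tau_r - tau_d)`. The drive is a
finite sum of weighted delta functions on a uniform grid of spacing
`T_u = 0.25 s`; observations are sampled at `T_y = 0.5 s`. Stacking the
exact state-space solution gives the linear model `y = A_tau*y0 + B_tau@u`
with `a_k = exp(-k*T_y/tau_d)` and `B_tau[k, i] = h(k*T_y - t_i)` for grid
times `t_i = (i-1)*T_u` preceding the k-th observation. The grid-time
convention `t_i = (i-1)*T_u` (first slot at zero) is the one that
reproduces the row structure of the observation operator exactly (row k has
`N - k*T_y/T_u` trailing zeros); the same convention is used by the
simulator and the solver, so it cancels in any round trip. `y0` is taken as
the first sample of the phasic series — its source is otherwise
unidentified, and at realistic noise levels the choice only perturbs the
first few observations.

Box constraints `0.1 <= tau_r <= 1.4` and `1.5 <= tau_d <= 6` (seconds)
keep the kernel identifiable and physiologically plausible; they also make
`tau_r != tau_d` structural.

## Tonic/phasic separation

The decomposition solves a convex quadratic program in the style of cvxEDA:
the tonic part is a cubic B-spline with knots every 10 s plus an offset and
linear drift, penalized in ℓ₂ on the spline coefficients with smoothness
weight 0.001 (the deliberately small setting that favors clean phasic
extraction over maximal tonic smoothness); the phasic part is a
nonnegative driver convolved with a *fixed nominal* kernel (rise 0.7 s,
decay 3.0 s — literature constants; subject-specific constants are
estimated downstream, keeping the stages independent), with an ℓ₁ penalty
(weight 8e-4, the cvxEDA default) that is linear on the feasible set. The
program is solved with L-BFGS-B on the smooth objective under the bound
constraints; convergence failures raise rather than degrade silently, and
all regularization weights actually used are echoed in the result for
auditability. Phasic dips below -1e-6 µS are clipped to zero with a logged
count; the residual `input - tonic - phasic` is always reported, never
dropped.

Known limitation: low-frequency energy can migrate between the spline
tonic and the SCR tails. On simulated recordings this biases a
subsequently estimated `tau_d` upward by 10–25% even when the phasic
correlation with ground truth exceeds 0.99. The validation study therefore
characterizes the deconvolution on phasic signals directly (the same
protocol used for the study that motivated this package); full-pipeline
time constants inherit this extra uncertainty.

## Deconvolution by coordinate descent

The estimation problem is

    min_{tau, u >= 0, tau in box}  J = 1/2*||y - A_tau*y0 - B_tau@u||^2
                                       + lam*||u||_p^p,   p = 0.5

split into two sub-problems solved alternately until the relative change
of J falls below 1e-6 (at most 20 outer iterations):

* **Sparse recovery (u-step).** Iteratively reweighted least squares of
  the FOCUSS family: with weights `w_i = |u_i|^(1-p/2)` the reweighted
  ridge solution is `u = W^2 B^T (B W^2 B^T + lam I)^{-1} y`, negative
  entries are projected to zero (the "+" variant) and zeroed atoms leave
  the active set permanently. Two schedules are used: FOCUSS+ grows `lam`
  geometrically (factor 1.3) from `1e-3*||B^T y||_inf` up to a cap of
  `1e-2*||B^T y||_inf` and serves as the initializer; GCV-FOCUSS+ then
  re-selects `lam` at every step by golden-section minimization of the
  generalized cross-validation score
  `GCV(lam) = M*||y - H_lam y||^2 / trace(I - H_lam)^2` over
  `log10(lam) in [-8, 2]`, with the influence matrix evaluated exactly
  through the SVD of the reweighted design. The cap on the FOCUSS+
  schedule matters: a much larger cap prunes genuine impulses that can
  never re-enter the active set, while a much smaller one leaves dozens of
  noise-fitting atoms; the chosen scale reproduces the intended behavior
  of slight under-detection, missing only impulses comparable to the noise
  floor.
* **System identification (tau-step).** With `u` fixed, `tau` is fitted by
  trust-region-reflective bounded nonlinear least squares (an
  interior-point-style solver for box constraints) on the exact residual;
  only the nonzero impulse columns are evaluated.

Because GCV re-selects `lam` between outer iterations, the penalized
objective is not automatically monotone; an explicit guard reverts any
outer step that would raise J and stops that restart, so the recorded
objective path is non-increasing by construction without altering any
accepted iterate.

The subject's time constants are estimated on a 180 s calibration window
starting 30 s into the signal (onset transients skipped; window and offset
are configurable, and the whole signal is used when it is shorter). Ten
random `tau` draws from the box initialize independent coordinate
descents; the winner is the restart with the smallest final penalized
objective J. Selecting on raw squared error instead systematically favors
a degenerate solution — `tau_r` collapsing toward its lower bound, whose
needle-like kernel fits measurement noise with many spurious impulses —
whereas J prices those extra atoms. The winning `tau` is then fixed and a
single FOCUSS+/GCV-FOCUSS+ pass runs over the full signal; finally all
impulses below the amplitude floor (0.01 in drive units, configurable) are
zeroed, and the reconstruction, R² = 1 - RSS/TSS, final `lam` and
per-restart summaries are reported. R² is undefined (reported as missing)
for constant or all-zero inputs.

## Arousal state-space model

Impulse occurrences are reduced to per-bin indicators `s_j` (bin width
`T_u`; a bin is 1 if at least one nonzero impulse falls in it). Arousal
follows a Gaussian random walk `z_j = z_{j-1} + eps_j`,
`eps_j ~ N(0, sigma_eps^2)`, and events are Bernoulli with
`p_j = sigmoid(alpha + z_j)`. `alpha = log(p0/(1-p0))` is fixed from the
baseline bin probability `p0`, by default the subject's own event fraction
(`sum(s)/J`); it is not re-estimated inside EM.

* **Forward filter.** Prediction carries the walk
  (`var_pred = var_prev + sigma_eps^2`); the update solves the implicit
  mode equation `z = z_pred + var_pred*(s_j - sigmoid(alpha+z))` by
  Newton's method (tolerance 1e-10, at most 50 steps, with a bracketed
  bisection fallback; the map is strictly monotone so the root is unique),
  and the variance update uses the Bernoulli information
  `p(1-p)` at the converged mode. The initial filter variance is
  `var0 = sigma_eps^2`, the common convention when the walk's own step
  size is the only scale available.
* **Smoother.** Fixed-interval recursion with gain
  `A_j = var_filt_j / var_pred_{j+1}`; terminal values copy the filter.
  Probability trajectories and their confidence bands are the sigmoid
  images of `z ± 1.96*sd`.
* **EM.** The M-step maximizes the expected complete-data Gaussian
  likelihood of the walk using smoothed means, variances and lag-one
  covariances `cov_{j,j-1|J} = A_{j-1}*var_smooth_j`, giving

      sigma_eps^2 <- [2*(S1 - S2) + 2*var_1|J + 1.5*z_1|J^2
                      - (var_J|J + z_J|J^2)] / (J+1)
      z0 <- z_1|J / 2

  with `S1 = sum_{j>=2}(var_j|J + z_j|J^2)` and
  `S2 = sum_{j>=2}(cov_{j,j-1|J} + z_j|J*z_{j-1|J})`; the closed form is
  verified in the tests against a numerical maximizer of the same expected
  log-likelihood. Convergence requires the largest absolute parameter
  change to reach 1e-8 (default cap 5000 iterations; non-convergence is
  flagged, not hidden, and with sparse event sequences the variance
  parameter can approach this tolerance slowly). Non-positive variance
  updates are floored at 1e-12 and flagged. The filter/smoother/EM inner
  loops are numba-compiled; a full EM fit on 2400 bins takes on the order
  of a second.
* **HAI.** After EM, `z_j ~ N(z_j|J, var_j|J)` and
  `HAI_j = Pr(z_j > z_T) = 1 - Phi((z_T - z_j|J)/sd_j|J)`, with `z_T` the
  median smoothed state — an approximation of the subject's "normal"
  arousal between stressed and relaxed extremes. Zero-variance bins
  degrade to a step indicator. The 90% level often drawn on HAI plots is
  presentation only and drives no computation.

A property worth noting: with Bernoulli observations the smoothing gain
does *not* vanish as `sigma_eps^2` grows — the filtered variance itself
grows like `1/(p(1-p))` as updates saturate — so the gain decays only
gradually (measured 0.87 → 0.46 as `sigma_eps^2` goes 0.05 → 5). The
accuracy of the Gaussian mode approximation is also regime-dependent: in
the model's operating regime (sparse events, small steps) filter and
smoother means sit within ~0.01 of the exact dense-grid posterior, while
in high-traffic regimes (event rate ~0.5, `sigma_eps^2` ~ 0.3) the
accumulated mode-vs-mean skew can reach ~0.05.

## Synthetic data

The simulator generates exactly what the model class describes, with
ground truth returned alongside every recording:

* impulse trains: grid-aligned, minimum separation 4 s (so individual SCRs
  are resolvable at the default kernel widths), amplitudes uniform in
  [0.05, 1.0] drive units;
* phasic signals: exact linear-model observations, no discretization
  error;
* noise: white Gaussian, rescaled so the realized clean-phasic-to-noise
  power ratio equals the requested SNR in dB exactly (25 dB for the
  validation study);
* tonic drift: a cubic B-spline with random-walk coefficients (10 s knots,
  0.05 µS steps, 2 µS baseline);
* arousal sequences: the random walk and Bernoulli emissions of the state
  model itself (defaults `sigma_eps2 = 0.005`, `p0 = 0.05`, 2400 bins).

Six bundled subject-level presets (`SUBJECT_PRESETS`: rise constants
0.60–1.40 s, decay constants 1.51–3.02 s, 8–35 impulses per 6 minutes)
span the physiological box, including a near-degenerate preset with
`tau_r ≈ tau_d` where the kernel is hardest to identify.

What the simulations do not emulate: motion artifacts and nonstationary
noise, device quantization, drifting time constants, SCR shape deviations
from the bi-exponential ideal, and any coupling between arousal and
impulse *amplitudes* (only occurrence rates carry arousal information in
this model). Passing the synthetic studies therefore demonstrates correct
and well-conditioned estimation under the model class, not robustness to
real-world artifact load.

## Validation experiments and problem sizes

* **Time-constant recovery / reconstruction.** For each preset: five
  independent 6-minute signals at 25 dB SNR (720 observations, 1440 grid
  slots each), full random-restart deconvolution. Per-preset medians of
  the worst relative tau error are within 10% for at least five of the six
  presets (the near-degenerate preset is the usual exception, as expected
  from its flat objective), and median reconstruction R² exceeds 0.98 for
  every preset — typically 0.993–0.996 against an SNR-imposed ceiling of
  about 0.997. Per-run impulse-count errors stay within 3, on the
  under-detection side. The whole study runs in about half a minute on one
  CPU.
* **Oracle agreement.** The kernel matches 4th-order Runge–Kutta
  integration of the ODE cascade to < 1e-6; IRLS sparse recovery matches
  exhaustive support enumeration on noiseless 2-sparse problems (grids up
  to 24 slots); filter and smoother means match an exact dense-grid
  forward–backward posterior (step 1e-3) to well under 0.02 mean error in
  the operating regime.
* **EM recovery.** Twenty simulated sequences of 2400 bins at
  `sigma_eps2 = 0.005`, `p0 = 0.05`: the median estimate lands within a
  factor of two of the truth (typically within ~20%); individual
  sequences scatter more widely, as expected for a variance parameter of
  a latent walk observed through ~120 binary events.
* **Invariants.** Objective monotonicity of the coordinate descent,
  smoothed-variance ≤ filtered-variance, HAI = 0.5 exactly at the
  threshold, the 1e-8 EM stopping rule, byte-identical pipeline outputs
  under a fixed seed, linearity/causality of the forward model, and scale
  equivariance of the deconvolution (amplitudes scale with the signal;
  time constants do not).

## Other numerical choices

* Ridge sub-solves use whichever Gram matrix (data- or coefficient-side)
  is smaller; singular systems receive a logged diagonal jitter.
* The GCV influence trace is computed exactly via SVD at all problem sizes
  this tool encounters (M ≤ 2000).
* Restart ties are broken by the earliest restart index; all randomness
  flows from one integer seed, so every pipeline output is a pure function
  of (input, config, seed).
* Degenerate inputs are handled explicitly: all-zero phasic returns an
  empty train with missing R²; constant binary sequences are rejected by
  EM; `sigma_eps2 = 0` is legal for filtering (frozen state) but floored
  in EM.
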