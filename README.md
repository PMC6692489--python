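# edadecode

Decoding sympathetic arousal from skin conductance recordings.

Skin conductance (electrodermal activity, EDA) is driven by sympathetic
nerve fibers innervating the eccrine sweat glands: every burst of sudomotor
activity produces one skin conductance response (SCR), a transient rise in
conductance riding on a slowly drifting tonic baseline. Because the *rate*
of these neural impulses tracks psychological arousal, a wearable EDA
channel can serve as a peripheral window onto an unobserved, emotion-related
brain state — for example as the feedback signal of a closed-loop
neurostimulation system, or simply for quantifying stress in behavioral
experiments.

`edadecode` implements the full decoding chain:

1. **Tonic/phasic separation** — a cvxEDA-style convex program: cubic
   B-spline tonic (10 s knots, ℓ₂-penalized coefficients, smoothness weight
   0.001) plus a nonnegative-driver convolution model for the phasic part.
2. **Sparse deconvolution with physiology estimation** — the phasic signal
   is modeled as
   `y = A_τ y₀ + B_τ u + ν`, where `u ≥ 0` is a sparse impulse train on a
   0.25 s grid and the SCR kernel
   `h(t) = (e^{−t/τ_r} − e^{−t/τ_d})/(τ_r − τ_d)` carries subject-specific
   rise/decay time constants (0.1 ≤ τ_r ≤ 1.4 s, 1.5 ≤ τ_d ≤ 6 s). The
   non-convex problem
   `min_{τ,u} ½‖y − A_τ y₀ − B_τ u‖² + λ‖u‖_p^p` is solved by two-step
   coordinate descent: FOCUSS+/GCV-FOCUSS+ iteratively reweighted least
   squares for `u` (λ chosen per step by generalized cross-validation),
   alternated with box-constrained nonlinear least squares for `τ`, from
   multiple random `τ` restarts. Impulses below 0.01 are discarded.
3. **Latent arousal state estimation** — impulse occurrences are binned
   (`s_j ∈ {0,1}` per 0.25 s bin) and linked to a latent random walk
   `z_j = z_{j−1} + ε_j`, `ε_j ∼ N(0, σ_ε²)`, through a Bernoulli
   observation model `p_j = 1/(1 + e^{−(α + z_j)})` with `α = logit(p₀)`
   fixed from the subject's baseline impulse rate. An approximate Gaussian
   forward filter (Newton-solved mode updates), a fixed-interval smoother
   and EM estimation of `(σ_ε², z₀)` yield the smoothed state `z_{j|J}` and
   the **High Arousal Index** `HAI_j = Pr(z_j > z_T)`, with `z_T` the
   subject's median smoothed state.

All three stages are exposed both as functions and as scikit-learn style
estimators (`TonicPhasicDecomposer`, `ScrDeconvolver`, `ArousalEstimator`)
with `fit`/`transform`, `get_params`/`set_params` and trailing-underscore
results, plus a `edadecode` command-line tool with `decompose`,
`deconvolve`, `arousal`, `simulate` and `pipeline` subcommands.

## Worked example

```python
import numpy as np
from edadecode import (SimulationSpec, ArousalSpec, SCRParameters,
                       simulate_recording, simulate_arousal_process,
                       deconvolve, em_fit, hai)

# -- stage 1: deconvolve a synthetic phasic signal (25 dB SNR)
spec = SimulationSpec(duration=360.0, scr_params=SCRParameters(0.681, 2.591),
                      n_impulses=20, snr_db=25.0, seed=11)
rec, truth = simulate_recording(spec)
phasic = truth["phasic"] + truth["noise"]
res = deconvolve(phasic, obs_interval=0.5, seed=11)
print(f"tau_r = {res.params.tau_r:.3f} s (true 0.681)")
print(f"tau_d = {res.params.tau_d:.3f} s (true 2.591)")
print(f"impulses = {res.nnz} (true {truth['train'].nnz}), "
      f"R^2 = {res.r_squared:.4f}")

# -- stage 2: track latent arousal from binary impulse occurrences
aspec = SimulationSpec(seed=3, arousal=ArousalSpec(sigma_eps2=0.005,
                                                   p0=0.05, n_bins=2400))
z_true, p_true, events = simulate_arousal_process(aspec)
fit = em_fit(events)
h = hai(fit.smoothed)
print(f"sigma_eps^2 = {fit.params.sigma_eps2:.4f} (true 0.005), "
      f"EM iterations = {fit.n_iter}, converged = {fit.converged}")
print(f"corr(z_smooth, true z) = "
      f"{np.corrcoef(fit.smoothed.z_smooth, z_true)[0, 1]:.3f}")
print(f"HAI > 0.9 in {(h.hai > 0.9).mean():.1%} of bins")
```

prints

```
tau_r = 0.676 s (true 0.681)
tau_d = 2.572 s (true 2.591)
impulses = 19 (true 20), R^2 = 0.9946
sigma_eps^2 = 0.0082 (true 0.005), EM iterations = 941, converged = True
corr(z_smooth, true z) = 0.974
HAI > 0.9 in 40.1% of bins
```

The deconvolution recovers the subject's SCR time constants within about
1% here and finds 19 of the 20 planted impulses (the missed one is
comparable to the noise floor); the reconstruction explains 99.5% of the
signal variance. The state-space stage recovers the process-noise variance
to well within a factor of two and the smoothed arousal trajectory follows
the simulated ground truth closely; the HAI flags the bins where the state
sits credibly above its median.

Reading real recordings: `read_recording("file.csv", column_spec={"time":
"t_s", "conductance": "EDA"})` accepts any uniformly sampled two-column
delimited export (e.g., from wrist-worn EDA devices).

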