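"""Ground-truthed synthetic data for every pipeline stage.

Emulates: sparse sudomotor impulse trains convolved with the bi-exponential
SCR kernel, additive cubic-spline tonic drift, Gaussian measurement noise at
a stated SNR (power ratio of clean phasic to noise, in dB), and latent
arousal random walks emitting Bernoulli impulse events.

Six bundled subject-level parameter presets (rise/decay time constants and
impulse counts spanning the physiological ranges) drive the package's
parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline

from .forward_model import ImpulseTrain, SCRParameters, simulate_exact
from .io import Recording

__all__ = [
    "TonicSpec",
    "ArousalSpec",
    "SimulationSpec",
    "SUBJECT_PRESETS",
    "gen_impulse_train",
    "simulate_recording",
    "simulate_arousal_process",
]

#: Representative per-subject (tau_r, tau_d, impulse count) configurations.
SUBJECT_PRESETS: tuple[dict, ...] = (
    {"tau_r": 0.681, "tau_d": 2.591, "n_impulses": 20},
    {"tau_r": 1.398, "tau_d": 1.568, "n_impulses": 17},
    {"tau_r": 1.159, "tau_d": 1.505, "n_impulses": 14},
    {"tau_r": 0.965, "tau_d": 1.880, "n_impulses": 8},
    {"tau_r": 0.604, "tau_d": 3.018, "n_impulses": 35},
    {"tau_r": 0.663, "tau_d": 2.617, "n_impulses": 28},
)


@dataclass
class TonicSpec:
    """Cubic-spline tonic drift: slow thermoregulatory baseline."""

    knot_spacing: float = 10.0     # s
    coeff_scale: float = 0.05      # uS random-walk step between knots
    baseline: float = 2.0          # uS


@dataclass
class ArousalSpec:
    """Latent random walk emitting Bernoulli impulse events."""

    sigma_eps2: float = 0.005
    z0: float = 0.0
    p0: float = 0.05
    n_bins: int = 2400


@dataclass
class SimulationSpec:
    """Everything needed to generate one ground-truthed recording."""

    duration: float = 360.0        # s
    obs_interval: float = 0.5      # T_y, s
    grid_interval: float = 0.25    # T_u, s
    scr_params: SCRParameters = field(
        default_factory=lambda: SCRParameters(0.7, 3.0))
    n_impulses: int = 20
    amplitude_range: tuple = (0.05, 1.0)
    min_separation: float = 4.0    # s
    snr_db: float = 25.0           # math.inf disables noise
    tonic: TonicSpec = field(default_factory=TonicSpec)
    arousal: ArousalSpec = field(default_factory=ArousalSpec)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_impulses < 0:
            raise ValueError("n_impulses must be nonnegative")
        if self.n_impulses * self.min_separation > self.duration:
            raise ValueError("impulse separation constraint is infeasible")
        if not (math.isfinite(self.snr_db) or math.isinf(self.snr_db)):
            raise ValueError("snr_db must be finite or +inf")
        if self.amplitude_range[0] > self.amplitude_range[1]:
            raise ValueError("amplitude_range must be (min, max)")

    @property
    def n_obs(self) -> int:
        return int(round(self.duration / self.obs_interval))

    @property
    def n_grid(self) -> int:
        ratio = int(round(self.obs_interval / self.grid_interval))
        return self.n_obs * ratio


def gen_impulse_train(spec: SimulationSpec,
                      rng: Optional[np.random.Generator] = None
                      ) -> ImpulseTrain:
    """Grid-aligned impulses with a minimum pairwise separation.

    Candidate grid slots are visited in random order and accepted greedily
    when far enough from everything already accepted; amplitudes are uniform
    in ``amplitude_range``.  Deterministic under the spec's seed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_grid = spec.n_grid
    amps = np.zeros(n_grid)
    if spec.n_impulses == 0:
        return ImpulseTrain(amps, spec.grid_interval)
    min_gap = int(math.ceil(spec.min_separation / spec.grid_interval - 1e-9))
    order = rng.permutation(n_grid)
    chosen: list[int] = []
    for idx in order:
        if all(abs(idx - c) >= min_gap for c in chosen):
            chosen.append(int(idx))
            if len(chosen) == spec.n_impulses:
                break
    if len(chosen) < spec.n_impulses:
        raise ValueError("could not place impulses with the requested "
                         "minimum separation")
    lo, hi = spec.amplitude_range
    amps[np.sort(chosen)] = rng.uniform(lo, hi, size=spec.n_impulses)
    return ImpulseTrain(amps, spec.grid_interval)


def _tonic_drift(spec: SimulationSpec, t: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Slow cubic B-spline drift with random-walk coefficients."""
    ts = spec.tonic
    k = 3
    inner = np.arange(0.0, spec.duration + ts.knot_spacing, ts.knot_spacing)
    knots = np.concatenate([
        np.full(k, inner[0]), inner, np.full(k, inner[-1])
    ])
    n_coef = len(knots) - k - 1
    coefs = ts.baseline + ts.coeff_scale * np.cumsum(
        rng.standard_normal(n_coef))
    return BSpline(knots, coefs, k, extrapolate=False)(np.clip(
        t, inner[0], inner[-1]))


def simulate_recording(spec: SimulationSpec,
                       subject_id: str = "synthetic") -> tuple[Recording, dict]:
    """One recording = spline tonic + exact phasic + scaled Gaussian noise.

    The noise realization is rescaled so that the realized power ratio of
    clean phasic to noise equals ``snr_db`` exactly.  Returns the recording
    and a truth bundle (train, phasic, tonic, noise).
    """
    rng = np.random.default_rng(spec.seed)
    train = gen_impulse_train(spec, rng)
    phasic = simulate_exact(spec.scr_params, train, y0=0.0,
                            n_obs=spec.n_obs, obs_interval=spec.obs_interval)
    if math.isinf(spec.snr_db):
        noise = np.zeros_like(phasic)
    else:
        p_sig = float(phasic @ phasic)
        if p_sig == 0.0:
            raise ValueError("SNR is undefined for an all-zero phasic signal")
        raw = rng.standard_normal(phasic.size)
        target = p_sig / 10.0 ** (spec.snr_db / 10.0)
        noise = raw * math.sqrt(target / float(raw @ raw))
    t = np.arange(1, spec.n_obs + 1) * spec.obs_interval
    tonic = _tonic_drift(spec, t, rng)
    samples = tonic + phasic + noise
    rec = Recording(subject_id=subject_id, samples=samples,
                    sampling_interval=spec.obs_interval,
                    start_time=float(t[0]))
    truth = {
        "train": train,
        "phasic": phasic,
        "tonic": tonic,
        "noise": noise,
        "times": t,
        "scr_params": spec.scr_params,
        "snr_db": spec.snr_db,
    }
    return rec, truth


def simulate_arousal_process(spec: SimulationSpec
                             ) -> tuple[np.ndarray, np.ndarray, "BinarySequence"]:
    """Latent random walk, sigmoid probabilities, Bernoulli events."""
    from .arousal import BinarySequence, compute_alpha

    ar = spec.arousal
    if ar.n_bins < 2:
        raise ValueError("need at least two bins")
    rng = np.random.default_rng(spec.seed)
    steps = rng.normal(0.0, math.sqrt(ar.sigma_eps2), size=ar.n_bins)
    z = ar.z0 + np.cumsum(steps)
    alpha = compute_alpha(ar.p0)
    p = 1.0 / (1.0 + np.exp(-(alpha + z)))
    s = (rng.random(ar.n_bins) < p).astype(np.int8)
    return z, p, BinarySequence(s, spec.grid_interval)
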