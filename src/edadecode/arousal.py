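"""Latent sympathetic arousal from binary impulse occurrences.

The time axis is divided into bins of width T_u; bin j carries s_j = 1 if at
least one sudomotor impulse fell in it.  Arousal z_j follows a Gaussian
random walk,

    z_j = z_{j-1} + eps_j,   eps_j ~ N(0, sigma_eps^2),

and impulse occurrence is Bernoulli with a sigmoid link,

    p_j = 1 / (1 + exp(-(alpha + z_j))),

where alpha = logit(p0) is fixed from the subject's baseline bin probability
p0.  Estimation combines an approximate Gaussian forward filter (the implicit
posterior-mode update is solved by Newton's method), a fixed-interval
backward smoother, and EM for (sigma_eps^2, z0).  The High Arousal Index is
HAI_j = Pr(z_j > z_T) under the smoothed Gaussian posterior with z_T the
median smoothed state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from numba import njit
from scipy.stats import norm

from .forward_model import ImpulseTrain

__all__ = [
    "BinarySequence",
    "ArousalParams",
    "FilteredState",
    "SmoothedState",
    "HAISeries",
    "EMResult",
    "bin_impulses",
    "compute_alpha",
    "forward_filter",
    "backward_smooth",
    "em_fit",
    "hai",
]

logger = logging.getLogger(__name__)

_SIGMA2_FLOOR = 1e-12


@dataclass
class BinarySequence:
    """Per-bin impulse occurrence indicators."""

    s: np.ndarray
    bin_interval: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s)
        if self.s.ndim != 1 or self.s.size < 2:
            raise ValueError("need a 1-D sequence with J >= 2 bins")
        if not np.all(np.isin(self.s, (0, 1))):
            raise ValueError("sequence entries must be 0 or 1")
        if self.bin_interval <= 0:
            raise ValueError("bin_interval must be positive")
        self.s = self.s.astype(np.int8)

    def __len__(self) -> int:
        return self.s.size


@dataclass
class ArousalParams:
    """Parameters of the random-walk/Bernoulli observation model."""

    alpha: float
    sigma_eps2: float
    z0: float
    p0: float

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        # sigma_eps2 == 0 is the degenerate frozen-state model; it is legal
        # for filtering/smoothing, while EM floors its updates above zero.
        if self.sigma_eps2 < 0:
            raise ValueError("sigma_eps2 must be nonnegative")

    @classmethod
    def from_p0(cls, p0: float, sigma_eps2: float,
                z0: float = 0.0) -> "ArousalParams":
        return cls(alpha=compute_alpha(p0), sigma_eps2=sigma_eps2,
                   z0=z0, p0=p0)


@dataclass
class FilteredState:
    z_pred: np.ndarray
    var_pred: np.ndarray
    z_filt: np.ndarray
    var_filt: np.ndarray


@dataclass
class SmoothedState:
    z_smooth: np.ndarray
    var_smooth: np.ndarray
    gain: np.ndarray            # A_j; last entry unused (terminal condition)
    p_smooth: np.ndarray
    p_lower: np.ndarray
    p_upper: np.ndarray
    alpha: float


@dataclass
class HAISeries:
    hai: np.ndarray
    z_threshold: float


@dataclass
class EMResult:
    params: ArousalParams
    smoothed: SmoothedState
    filtered: FilteredState
    n_iter: int
    converged: bool
    delta_final: float
    param_path: list = field(default_factory=list, repr=False)


def bin_impulses(impulses: ImpulseTrain, bin_interval: float,
                 duration: float) -> BinarySequence:
    """Mark each bin [j*T, (j+1)*T) that contains >= 1 nonzero impulse."""
    if bin_interval <= 0:
        raise ValueError("bin_interval must be positive")
    n_bins = int(math.ceil(duration / bin_interval - 1e-9))
    t_nz, _ = impulses.nonzero()
    if t_nz.size and t_nz.max() >= duration:
        raise ValueError("impulse beyond the requested duration")
    s = np.zeros(n_bins, dtype=np.int8)
    if t_nz.size:
        idx = np.floor(t_nz / bin_interval + 1e-9).astype(int)
        s[idx] = 1
    return BinarySequence(s, bin_interval)


def compute_alpha(p0: float) -> float:
    """Baseline log-odds alpha = log(p0 / (1 - p0))."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    return math.log(p0 / (1.0 - p0))


# ---------------------------------------------------------------------------
# Jitted recursions
# ---------------------------------------------------------------------------

@njit(cache=True)
def _update_root(zpr: float, vpr: float, s: float, alpha: float) -> float:
    """Solve z = zpr + vpr*(s - sigmoid(alpha + z)).

    The map is a strictly increasing fixed-point equation, so the root is
    unique.  Newton from the prediction, with a bracketed bisection fallback.
    """
    z = zpr
    ok = False
    for _ in range(50):
        pz = 1.0 / (1.0 + math.exp(-(alpha + z)))
        f = z - zpr - vpr * (s - pz)
        fp = 1.0 + vpr * pz * (1.0 - pz)
        dz = f / fp
        z -= dz
        if abs(dz) < 1e-10:
            ok = True
            break
    if ok and np.isfinite(z):
        return z
    # bisection on a bracket of half-width |s - p(zpr)| * vpr + 1
    p0 = 1.0 / (1.0 + math.exp(-(alpha + zpr)))
    half = vpr * abs(s - p0) + 1.0
    lo = zpr - half
    hi = zpr + half
    for _ in range(60):
        flo = lo - zpr - vpr * (s - 1.0 / (1.0 + math.exp(-(alpha + lo))))
        fhi = hi - zpr - vpr * (s - 1.0 / (1.0 + math.exp(-(alpha + hi))))
        if flo * fhi <= 0.0:
            break
        lo -= half
        hi += half
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = mid - zpr - vpr * (s - 1.0 / (1.0 + math.exp(-(alpha + mid))))
        if fm > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def _filter_core(s, alpha, sigma_eps2, z0, var0):
    J = s.shape[0]
    z_pred = np.empty(J)
    var_pred = np.empty(J)
    z_filt = np.empty(J)
    var_filt = np.empty(J)
    zp = z0
    vp = var0
    for j in range(J):
        zpr = zp
        vpr = vp + sigma_eps2
        if vpr > 0.0:
            z = _update_root(zpr, vpr, float(s[j]), alpha)
            pz = 1.0 / (1.0 + math.exp(-(alpha + z)))
            vf = 1.0 / (1.0 / vpr + pz * (1.0 - pz))
        else:
            z = zpr
            vf = 0.0
        z_pred[j] = zpr
        var_pred[j] = vpr
        z_filt[j] = z
        var_filt[j] = vf
        zp = z
        vp = vf
    return z_pred, var_pred, z_filt, var_filt


@njit(cache=True)
def _smooth_core(z_pred, var_pred, z_filt, var_filt):
    J = z_filt.shape[0]
    z_sm = np.empty(J)
    var_sm = np.empty(J)
    gain = np.zeros(J)
    z_sm[J - 1] = z_filt[J - 1]
    var_sm[J - 1] = var_filt[J - 1]
    for j in range(J - 2, -1, -1):
        vp_next = var_pred[j + 1]
        A = var_filt[j] / vp_next if vp_next > 0.0 else 0.0
        gain[j] = A
        z_sm[j] = z_filt[j] + A * (z_sm[j + 1] - z_pred[j + 1])
        var_sm[j] = var_filt[j] + A * A * (var_sm[j + 1] - vp_next)
    return z_sm, var_sm, gain


# ---------------------------------------------------------------------------
# Public filter / smoother / EM
# ---------------------------------------------------------------------------

def _as_binary_array(s: Union[BinarySequence, np.ndarray]) -> np.ndarray:
    if isinstance(s, BinarySequence):
        return s.s.astype(np.float64)
    arr = np.asarray(s)
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError("sequence entries must be 0 or 1")
    return arr.astype(np.float64)


def forward_filter(s: Union[BinarySequence, np.ndarray],
                   params: ArousalParams, var0: float) -> FilteredState:
    """Approximate Gaussian forward filter over the binary sequence.

    Prediction carries the random walk (variance grows by sigma_eps^2 per
    bin); the update solves the implicit posterior-mode equation by Newton's
    method and evaluates the variance update at the converged mode.
    """
    if var0 < 0:
        raise ValueError("var0 must be nonnegative")
    arr = _as_binary_array(s)
    zp, vp, zf, vf = _filter_core(
        arr, params.alpha, params.sigma_eps2, params.z0, float(var0)
    )
    if np.any(~np.isfinite(zf)):
        raise RuntimeError("forward filter diverged; check parameters")
    return FilteredState(z_pred=zp, var_pred=vp, z_filt=zf, var_filt=vf)


def backward_smooth(filt: FilteredState,
                    params: ArousalParams) -> SmoothedState:
    """Fixed-interval smoother; also maps states through the sigmoid.

    Confidence limits on the occurrence probability are the sigmoid images of
    z +/- 1.96 sigma.
    """
    z_sm, var_sm, gain = _smooth_core(
        filt.z_pred, filt.var_pred, filt.z_filt, filt.var_filt
    )
    a = params.alpha
    sd = np.sqrt(np.maximum(var_sm, 0.0))
    p_sm = 1.0 / (1.0 + np.exp(-(a + z_sm)))
    p_lo = 1.0 / (1.0 + np.exp(-(a + z_sm - 1.96 * sd)))
    p_hi = 1.0 / (1.0 + np.exp(-(a + z_sm + 1.96 * sd)))
    return SmoothedState(z_smooth=z_sm, var_smooth=var_sm, gain=gain,
                         p_smooth=p_sm, p_lower=p_lo, p_upper=p_hi, alpha=a)


def _m_step(smoothed: SmoothedState) -> tuple[float, float]:
    """Closed-form M-step from the complete-data Gaussian likelihood.

    Uses smoothed means/variances and lag-one covariances
    sigma_{j,j-1|J} = A_{j-1} sigma^2_{j|J}; the initial state estimate is
    z0 = z_{1|J} / 2.
    """
    zs = smoothed.z_smooth
    vs = smoothed.var_smooth
    A = smoothed.gain
    J = zs.size
    cov = A[:-1] * vs[1:]
    s1 = float(np.sum(vs[1:] + zs[1:] ** 2))
    s2 = float(np.sum(cov + zs[1:] * zs[:-1]))
    num = (2.0 * (s1 - s2) + 2.0 * vs[0] + 1.5 * zs[0] ** 2
           - (vs[-1] + zs[-1] ** 2))
    sigma2 = num / (J + 1)
    z0 = zs[0] / 2.0
    return sigma2, z0


def em_fit(
    s: Union[BinarySequence, np.ndarray],
    p0: Optional[float] = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    sigma_eps2_init: float = 0.01,
) -> EMResult:
    """EM estimation of (sigma_eps^2, z0) with alpha fixed from p0.

    The E-step runs the forward filter (z_{0|0} = z0, var0 = sigma_eps^2)
    and the backward smoother; the M-step applies the closed-form updates.
    Convergence requires the largest absolute parameter change to drop to
    ``tol`` (1e-8 by default).
    """
    arr = _as_binary_array(s)
    if arr.min() == arr.max():
        raise ValueError("degenerate sequence: needs both 0s and 1s")
    if p0 is None:
        p0 = float(arr.mean())
    alpha = compute_alpha(p0)
    sigma2 = float(sigma_eps2_init)
    z0 = 0.0
    path: list[tuple[float, float, float]] = []
    converged = False
    delta = math.inf
    n_iter = 0
    flagged_floor = False
    for n_iter in range(1, max_iter + 1):
        zp, vp, zf, vf = _filter_core(arr, alpha, sigma2, z0, sigma2)
        z_sm, var_sm, gain = _smooth_core(zp, vp, zf, vf)
        stub = SmoothedState(z_sm, var_sm, gain, None, None, None, alpha)
        sigma2_new, z0_new = _m_step(stub)
        if sigma2_new <= 0:
            sigma2_new = _SIGMA2_FLOOR
            if not flagged_floor:
                logger.warning("sigma_eps2 update non-positive; floored")
                flagged_floor = True
        delta = max(abs(sigma2_new - sigma2), abs(z0_new - z0))
        sigma2, z0 = sigma2_new, z0_new
        path.append((sigma2, z0, delta))
        if delta <= tol:
            converged = True
            break
        if n_iter % 500 == 0:
            logger.debug("EM iter %d: sigma_eps2=%.6g z0=%.6g delta=%.3g",
                         n_iter, sigma2, z0, delta)
    if not converged:
        logger.warning("EM did not converge in %d iterations "
                       "(last delta %.3g)", max_iter, delta)
    params = ArousalParams(alpha=alpha, sigma_eps2=sigma2, z0=z0, p0=p0)
    filt = forward_filter(arr, params, var0=sigma2)
    smoothed = backward_smooth(filt, params)
    return EMResult(params=params, smoothed=smoothed, filtered=filt,
                    n_iter=n_iter, converged=converged, delta_final=delta,
                    param_path=path)


def hai(smoothed: SmoothedState,
        z_threshold: Union[float, str] = "median") -> HAISeries:
    """High Arousal Index: Pr(z_j > z_T) under the smoothed posterior.

    With ``z_threshold="median"`` the threshold is the median smoothed state,
    approximating normal arousal between the stressed and relaxed extremes.
    Zero-variance bins degrade to a step indicator (0.5 exactly at the
    threshold).
    """
    z = smoothed.z_smooth
    sd = np.sqrt(np.maximum(smoothed.var_smooth, 0.0))
    z_t = float(np.median(z)) if isinstance(z_threshold, str) else float(
        z_threshold)
    out = np.empty_like(z)
    pos = sd > 0
    out[pos] = norm.sf((z_t - z[pos]) / sd[pos])
    if np.any(~pos):
        logger.info("zero smoothed variance in %d bins; HAI degraded to a "
                    "step indicator there", int(np.sum(~pos)))
        zz = z[~pos]
        out[~pos] = np.where(zz > z_t, 1.0, np.where(zz < z_t, 0.0, 0.5))
    return HAISeries(hai=out, z_threshold=z_t)
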