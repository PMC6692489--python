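"""Independent reference implementations used only to check the package.

Each oracle deliberately avoids the code path it validates: the SCR kernel
is checked against Runge-Kutta integration of the underlying ODEs, sparse
recovery against exhaustive support enumeration, and the Gaussian
approximate filter/smoother against an exact forward-backward pass on a
dense state grid.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import nnls
from scipy.signal import fftconvolve


def rk4_kernel(tau_r: float, tau_d: float, t_end: float,
               step: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """SCR impulse response by RK4 integration of the two-state cascade.

    A unit-area impulse at t=0 is equivalent to the initial condition
    x1(0+) = 1/tau_r, x2(0+) = 0; thereafter the system is homogeneous.
    """
    n = int(round(t_end / step))
    ts = np.arange(n + 1) * step
    x = np.array([1.0 / tau_r, 0.0])
    A = np.array([[-1.0 / tau_r, 0.0], [1.0 / tau_d, -1.0 / tau_d]])
    out = np.empty(n + 1)
    out[0] = x[1]
    for i in range(n):
        k1 = A @ x
        k2 = A @ (x + 0.5 * step * k1)
        k3 = A @ (x + 0.5 * step * k2)
        k4 = A @ (x + step * k3)
        x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = x[1]
    return ts, out


def best_support_exhaustive(B: np.ndarray, y: np.ndarray,
                            k: int) -> tuple[tuple, np.ndarray]:
    """Best k-sparse nonnegative support by brute-force enumeration."""
    n = B.shape[1]
    best = (np.inf, None, None)
    for support in combinations(range(n), k):
        cols = list(support)
        coef, resid = nnls(B[:, cols], y)
        if resid < best[0]:
            best = (resid, tuple(cols), coef)
    return best[1], best[2]


def grid_posterior(s, alpha: float, sigma_eps2: float, z0: float,
                   var0: float, lo: float = -6.0, hi: float = 6.0,
                   step: float = 1e-3):
    """Exact forward-backward posterior of the discretized state-space model.

    The random-walk transition is a Gaussian convolution on a dense z grid;
    returns (filtered means, smoothed means).
    """
    z = np.arange(lo, hi + step, step)
    sd = np.sqrt(sigma_eps2)
    ker_x = np.arange(-5 * sd, 5 * sd + step, step)
    ker = np.exp(-0.5 * (ker_x / sd) ** 2)
    ker /= ker.sum()
    p = 1.0 / (1.0 + np.exp(-(alpha + z)))
    s = np.asarray(s)

    v1 = var0 + sigma_eps2
    a = np.exp(-0.5 * (z - z0) ** 2 / v1)
    fwd = []
    for sj in s:
        a = a * (p if sj else 1.0 - p)
        a = a / a.sum()
        fwd.append(a)
        a = fftconvolve(a, ker, mode="same")
    b = np.ones_like(z)
    bwd = [None] * len(s)
    for j in range(len(s) - 1, -1, -1):
        bwd[j] = b
        b = fftconvolve(b * (p if s[j] else 1.0 - p), ker, mode="same")
        b = b / b.max()
    filt_means = np.array([f @ z / f.sum() for f in fwd])
    sm_means = np.empty(len(s))
    for j in range(len(s)):
        post = fwd[j] * bwd[j]
        sm_means[j] = post @ z / post.sum()
    return filt_means, sm_means
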