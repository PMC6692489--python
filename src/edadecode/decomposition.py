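"""Tonic/phasic separation of skin conductance via a convex program.

The recording is modelled as

    y_SC = (tonic: cubic B-spline on knots every ``knot_spacing`` s
            + offset and linear drift)
         + (phasic: nonnegative driver convolved with a fixed nominal
            bi-exponential SCR kernel)
         + residual,

and separated by minimizing

    1/2 ||y - K q - B l - D d||^2 + driver_weight * 1^T q
        + 1/2 smoothness_weight * ||l||^2,     q >= 0,

a convex quadratic program with an l1 (linear, since q >= 0) sparsity term
on the driver and an l2 penalty on the spline coefficients.  The nominal
kernel uses fixed literature constants (rise 0.7 s, decay 3.0 s); the
subject-specific time constants are estimated later by the deconvolution
stage, so stage independence is preserved.  Solved with L-BFGS-B on the
smooth objective with bound constraints (the l1 term is linear on the
feasible set, hence smooth there).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import toeplitz
from scipy.optimize import minimize

from .forward_model import SCRParameters, impulse_response
from .io import Recording

__all__ = ["Decomposition", "decompose"]

logger = logging.getLogger(__name__)

_NEG_TOL = 1e-6  # uS; phasic dips beyond this are clipped (and counted)


@dataclass
class Decomposition:
    """Additive split of a recording: input = tonic + phasic + residual."""

    phasic: np.ndarray
    tonic: np.ndarray
    residual: np.ndarray
    driver: np.ndarray
    smoothness_weight: float
    objective: float
    n_clipped: int
    solver_status: str
    regularization: dict

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residual))


def _spline_basis(t: np.ndarray, duration: float,
                  knot_spacing: float) -> np.ndarray:
    k = 3
    inner = np.arange(0.0, duration + knot_spacing, knot_spacing)
    knots = np.concatenate([np.full(k, inner[0]), inner,
                            np.full(k, inner[-1])])
    x = np.clip(t, inner[0], np.nextafter(inner[-1], -np.inf))
    return BSpline.design_matrix(x, knots, k).toarray()


def decompose(
    recording: Union[Recording, np.ndarray],
    smoothness_weight: float = 0.001,
    knot_spacing: float = 10.0,
    driver_weight: float = 8e-4,
    kernel: SCRParameters = None,
    sampling_interval: Optional[float] = None,
) -> Decomposition:
    """Split a recording into tonic and phasic components.

    Parameters
    ----------
    recording : Recording or 1-D array (requires ``sampling_interval``).
    smoothness_weight : l2 penalty on the spline coefficients; larger values
        give a smoother tonic curve.
    knot_spacing : spline knot spacing in seconds.
    driver_weight : l1 penalty on the nonnegative phasic driver.
    kernel : nominal SCR kernel parameters (default rise 0.7 s, decay 3.0 s).

    Raises
    ------
    ValueError for recordings shorter than two knot spacings or with
    negative samples; RuntimeError if the solver reports a non-optimal
    status.
    """
    if isinstance(recording, Recording):
        y = recording.samples
        dt = recording.sampling_interval
    else:
        y = np.asarray(recording, dtype=float)
        if sampling_interval is None:
            raise ValueError("sampling_interval required for array input")
        dt = float(sampling_interval)
    if np.any(y < 0):
        raise ValueError("conductance samples must be nonnegative")
    n = y.size
    duration = n * dt
    if duration < 2 * knot_spacing:
        raise ValueError("recording shorter than two knot spacings")
    kernel = kernel or SCRParameters(0.7, 3.0)

    t = np.arange(n) * dt
    h = impulse_response(kernel, t) * dt
    K = toeplitz(h, np.zeros(n))
    S = _spline_basis(t, duration, knot_spacing)
    D = np.column_stack([np.ones(n), t / t[-1] if t[-1] > 0 else t])
    A = np.hstack([K, S, D])
    n_q, n_l = n, S.shape[1]

    lin = np.zeros(A.shape[1])
    lin[:n_q] = driver_weight
    reg = np.zeros(A.shape[1])
    reg[n_q:n_q + n_l] = smoothness_weight

    def fun(x: np.ndarray):
        r = A @ x - y
        f = 0.5 * float(r @ r) + float(lin @ x) + 0.5 * float(reg @ x ** 2)
        g = A.T @ r + lin + reg * x
        return f, g

    x0 = np.zeros(A.shape[1])
    x0[-2] = float(y.mean())
    bounds = [(0.0, None)] * n_q + [(None, None)] * (n_l + 2)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 40000, "maxfun": 200000,
                            "ftol": 1e-14, "gtol": 1e-9})
    if not res.success and "ROUNDING" not in str(res.message).upper():
        raise RuntimeError(f"decomposition solver failed: {res.message}")

    x = res.x
    q = x[:n_q]
    tonic = S @ x[n_q:n_q + n_l] + D @ x[n_q + n_l:]
    phasic = K @ q
    n_clipped = int(np.sum(phasic < -_NEG_TOL))
    if n_clipped:
        logger.info("clipped %d phasic samples below -%g uS",
                    n_clipped, _NEG_TOL)
    phasic = np.maximum(phasic, 0.0)
    residual = y - tonic - phasic
    return Decomposition(
        phasic=phasic,
        tonic=tonic,
        residual=residual,
        driver=np.maximum(q, 0.0),
        smoothness_weight=smoothness_weight,
        objective=float(res.fun),
        n_clipped=n_clipped,
        solver_status=str(res.message),
        regularization={
            "smoothness_weight": smoothness_weight,
            "driver_weight": driver_weight,
            "knot_spacing_s": knot_spacing,
            "kernel_rise_s": kernel.tau_r,
            "kernel_decay_s": kernel.tau_d,
        },
    )
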