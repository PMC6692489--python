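"""Bi-exponential forward model of the phasic skin conductance signal.

Sweat release into the duct and its subsequent diffusion and evaporation are
modelled as a cascade of two first-order systems,

    dx1/dt = -x1/tau_r + u/tau_r        (diffusion)
    dx2/dt =  x1/tau_d - x2/tau_d       (evaporation)

where ``u`` is the sparse train of sudomotor nerve impulses, ``x2`` is the
phasic skin conductance and ``tau_r``/``tau_d`` are the rise and decay time
constants of a single skin conductance response (SCR).  With x1(0) = 0 the
cascade has the unit-area impulse response

    h(t) = (exp(-t/tau_r) - exp(-t/tau_d)) / (tau_r - tau_d),   t >= 0.

Impulses live on a uniform grid of spacing ``T_u``; observations are taken on
a coarser uniform grid of spacing ``T_y`` (an integer multiple of ``T_u``).
Stacking the observations gives the linear model

    y = A_tau * y0 + B_tau @ u

with ``a_k = exp(-k T_y / tau_d)`` carrying the initial condition ``y0`` and
``B_tau[k, i] = h(k T_y - t_i)`` for grid times ``t_i = (i - 1) T_u`` that
precede the k-th observation (zero otherwise), so row k has exactly
``N - k T_y / T_u`` trailing zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TAU_R_BOUNDS",
    "TAU_D_BOUNDS",
    "SCRParameters",
    "ImpulseTrain",
    "SystemMatrices",
    "impulse_response",
    "build_system_matrices",
    "simulate_exact",
]

#: Physiologically plausible box constraints on the SCR time constants (s).
TAU_R_BOUNDS = (0.1, 1.4)
TAU_D_BOUNDS = (1.5, 6.0)


@dataclass(frozen=True)
class SCRParameters:
    """Rise and decay time constants (seconds) of a single SCR.

    The box constraints keep the parameters identifiable and physiologically
    plausible; they also guarantee tau_r != tau_d so the kernel formula is
    never degenerate.
    """

    tau_r: float
    tau_d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau_r) and np.isfinite(self.tau_d)):
            raise ValueError("SCR time constants must be finite")
        if not TAU_R_BOUNDS[0] <= self.tau_r <= TAU_R_BOUNDS[1]:
            raise ValueError(
                f"tau_r={self.tau_r} outside bounds {TAU_R_BOUNDS}"
            )
        if not TAU_D_BOUNDS[0] <= self.tau_d <= TAU_D_BOUNDS[1]:
            raise ValueError(
                f"tau_d={self.tau_d} outside bounds {TAU_D_BOUNDS}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.tau_r, self.tau_d], dtype=float)


@dataclass
class ImpulseTrain:
    """Sparse nonnegative impulse amplitudes on a uniform time grid.

    Grid point ``i`` (0-based) sits at time ``t0 + i * grid_interval``; with
    the default ``t0 = 0`` this is the (i-1)T_u convention of the linear
    observation model.
    """

    amplitudes: np.ndarray
    grid_interval: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1:
            raise ValueError("amplitudes must be a 1-D vector")
        if self.grid_interval <= 0:
            raise ValueError("grid_interval must be positive")
        if np.any(~np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    def __len__(self) -> int:
        return self.amplitudes.size

    @property
    def times(self) -> np.ndarray:
        """Grid times for every slot (including zero-amplitude ones)."""
        return self.t0 + np.arange(self.amplitudes.size) * self.grid_interval

    @property
    def nnz(self) -> int:
        """Number of nonzero impulses (sparsity is reported, not enforced)."""
        return int(np.count_nonzero(self.amplitudes))

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, amplitudes) of the nonzero impulses."""
        idx = np.flatnonzero(self.amplitudes)
        return self.times[idx], self.amplitudes[idx]


@dataclass
class SystemMatrices:
    """Discrete observation operator y = A y0 + B u."""

    A: np.ndarray          # (M,) decay coefficients a_k = exp(-k T_y / tau_d)
    B: np.ndarray          # (M, N) kernel matrix
    y0: float              # initial phasic value (uS)
    obs_interval: float    # T_y (s)
    grid_interval: float   # T_u (s)
    params: SCRParameters = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return self.A.size

    @property
    def n_grid(self) -> int:
        return self.B.shape[1]

    def observe(self, u: np.ndarray) -> np.ndarray:
        """Noiseless observations for impulse amplitudes ``u``."""
        u = np.asarray(u, dtype=float)
        if u.size != self.n_grid:
            raise ValueError(
                f"impulse vector has length {u.size}, expected {self.n_grid}"
            )
        return self.A * self.y0 + self.B @ u


def impulse_response(params: SCRParameters, t) -> np.ndarray:
    """Unit-area SCR kernel h(t) of the diffusion/evaporation cascade.

    h(0) = 0, h(t) > 0 for t > 0, h -> 0 as t -> inf, and the total area is
    exactly 1 for any valid parameters (the cascade has unit DC gain).

    Raises
    ------
    ValueError
        If any ``t`` is negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("impulse response is only defined for t >= 0")
    h = (np.exp(-t_arr / params.tau_r) - np.exp(-t_arr / params.tau_d)) / (
        params.tau_r - params.tau_d
    )
    return h if t_arr.shape else float(h)


def _check_grid(obs_interval: float, grid_interval: float) -> int:
    if obs_interval <= 0 or grid_interval <= 0:
        raise ValueError("sampling intervals must be positive")
    ratio = obs_interval / grid_interval
    r = int(round(ratio))
    if r < 1 or abs(ratio - r) > 1e-9:
        raise ValueError(
            f"obs_interval={obs_interval} must be an integer multiple of "
            f"grid_interval={grid_interval}"
        )
    return r


def build_system_matrices(
    params: SCRParameters,
    y0: float,
    n_obs: int,
    n_grid: int,
    obs_interval: float = 0.5,
    grid_interval: float = 0.25,
) -> SystemMatrices:
    """Assemble the discrete observation operator (A, B).

    Observation k (1-based) is taken at time k*T_y; impulse slot i (1-based)
    sits at t_i = (i-1)*T_u.  B[k, i] = h(k*T_y - t_i) when t_i < k*T_y and 0
    otherwise, so row k has exactly N - k*T_y/T_u trailing zeros.
    """
    r = _check_grid(obs_interval, grid_interval)
    if n_obs < 1 or n_grid < 1:
        raise ValueError("n_obs and n_grid must be positive")
    if n_obs * r > n_grid:
        raise ValueError(
            f"need n_grid >= n_obs * (T_y/T_u) = {n_obs * r}, got {n_grid}"
        )
    obs_times = np.arange(1, n_obs + 1) * obs_interval
    grid_times = np.arange(n_grid) * grid_interval
    lag = obs_times[:, None] - grid_times[None, :]
    mask = lag > 0
    B = np.zeros((n_obs, n_grid))
    B[mask] = impulse_response(params, lag[mask])
    A = np.exp(-obs_times / params.tau_d)
    return SystemMatrices(
        A=A, B=B, y0=float(y0), obs_interval=obs_interval,
        grid_interval=grid_interval, params=params,
    )


def simulate_exact(
    params: SCRParameters,
    train: ImpulseTrain,
    y0: float,
    n_obs: int,
    obs_interval: float = 0.5,
) -> np.ndarray:
    """Noiseless phasic series A*y0 + B@u for an impulse train.

    Only the nonzero impulse columns are evaluated, so this is cheap even for
    long grids.  Output is nonnegative whenever y0 >= 0 and u >= 0.
    """
    r = _check_grid(obs_interval, train.grid_interval)
    if n_obs * r > len(train):
        raise ValueError(
            f"impulse train of length {len(train)} too short for "
            f"{n_obs} observations at T_y/T_u = {r}"
        )
    obs_times = np.arange(1, n_obs + 1) * obs_interval
    y = float(y0) * np.exp(-obs_times / params.tau_d)
    t_nz, a_nz = train.nonzero()
    if t_nz.size:
        lag = obs_times[:, None] - t_nz[None, :]
        mask = lag > 0
        H = np.zeros_like(lag)
        H[mask] = impulse_response(params, lag[mask])
        y = y + H @ a_nz
    return y
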