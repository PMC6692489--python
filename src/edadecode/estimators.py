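"""scikit-learn style estimators wrapping the pipeline stages.

Each estimator validates input in ``fit``, exposes hyperparameters through
``get_params``/``set_params`` and stores results in trailing-underscore
attributes, so the stages compose with sklearn tooling.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import arousal as _arousal
from .decomposition import decompose
from .deconvolution import DeconvolutionConfig, deconvolve
from .forward_model import SCRParameters

__all__ = ["TonicPhasicDecomposer", "ScrDeconvolver", "ArousalEstimator"]


def _as_signal(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("expected a single 1-D signal")
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite values")
    return arr


class TonicPhasicDecomposer(TransformerMixin, BaseEstimator):
    """Convex tonic/phasic separation of a skin conductance signal.

    ``fit`` decomposes the given signal and stores ``tonic_``, ``phasic_``,
    ``residual_`` and ``objective_``; ``transform`` is stateless and returns
    the phasic component of whatever signal it is given, so the step chains
    into downstream deconvolution.
    """

    def __init__(self, sampling_interval: float = 0.5,
                 smoothness_weight: float = 0.001,
                 knot_spacing: float = 10.0,
                 driver_weight: float = 8e-4,
                 kernel_rise: float = 0.7,
                 kernel_decay: float = 3.0):
        self.sampling_interval = sampling_interval
        self.smoothness_weight = smoothness_weight
        self.knot_spacing = knot_spacing
        self.driver_weight = driver_weight
        self.kernel_rise = kernel_rise
        self.kernel_decay = kernel_decay

    def _decompose(self, X):
        return decompose(
            _as_signal(X),
            smoothness_weight=self.smoothness_weight,
            knot_spacing=self.knot_spacing,
            driver_weight=self.driver_weight,
            kernel=SCRParameters(self.kernel_rise, self.kernel_decay),
            sampling_interval=self.sampling_interval,
        )

    def fit(self, X, y=None):
        result = self._decompose(X)
        self.decomposition_ = result
        self.tonic_ = result.tonic
        self.phasic_ = result.phasic
        self.residual_ = result.residual
        self.objective_ = result.objective
        return self

    def transform(self, X):
        return self._decompose(X).phasic


class ScrDeconvolver(BaseEstimator):
    """Coordinate-descent sparse deconvolution with tau estimation.

    ``fit`` recovers the impulse train and per-subject SCR time constants
    from a phasic signal, storing ``impulses_``, ``tau_r_``, ``tau_d_``,
    ``r_squared_``, ``reconstruction_`` and the per-restart summary.
    """

    def __init__(self, obs_interval: float = 0.5,
                 grid_interval: float = 0.25,
                 p_norm: float = 0.5,
                 amplitude_floor: float = 0.01,
                 n_restarts: int = 10,
                 cd_tol: float = 1e-6,
                 cd_max_iter: int = 20,
                 segment_seconds: float = 180.0,
                 segment_start_seconds: float = 30.0,
                 random_state: Optional[int] = None):
        self.obs_interval = obs_interval
        self.grid_interval = grid_interval
        self.p_norm = p_norm
        self.amplitude_floor = amplitude_floor
        self.n_restarts = n_restarts
        self.cd_tol = cd_tol
        self.cd_max_iter = cd_max_iter
        self.segment_seconds = segment_seconds
        self.segment_start_seconds = segment_start_seconds
        self.random_state = random_state

    def _config(self) -> DeconvolutionConfig:
        return DeconvolutionConfig(
            p_norm=self.p_norm,
            amplitude_floor=self.amplitude_floor,
            n_restarts=self.n_restarts,
            cd_tol=self.cd_tol,
            cd_max_iter=self.cd_max_iter,
            segment_seconds=self.segment_seconds,
            segment_start_seconds=self.segment_start_seconds,
            grid_interval=self.grid_interval,
        )

    def fit(self, X, y=None):
        signal = _as_signal(X)
        result = deconvolve(signal, obs_interval=self.obs_interval,
                            config=self._config(), seed=self.random_state)
        self.result_ = result
        self.impulses_ = result.impulses
        self.tau_r_ = result.params.tau_r
        self.tau_d_ = result.params.tau_d
        self.r_squared_ = result.r_squared
        self.reconstruction_ = result.reconstruction
        self.objective_ = result.objective
        self.lambda_ = result.lambda_final
        self.n_iter_ = result.iterations
        return self

    def predict(self, X=None):
        """Reconstruction of the fitted signal."""
        check_is_fitted(self, "result_")
        return self.reconstruction_


class ArousalEstimator(BaseEstimator):
    """EM-fitted random-walk arousal model over a binary event sequence.

    ``fit`` takes a {0,1} sequence, estimates the process-noise variance and
    initial state by EM, and stores the smoothed state trajectory, occurrence
    probabilities and the High Arousal Index.
    """

    def __init__(self, p0: Optional[float] = None, tol: float = 1e-8,
                 max_iter: int = 5000,
                 z_threshold: Union[float, str] = "median"):
        self.p0 = p0
        self.tol = tol
        self.max_iter = max_iter
        self.z_threshold = z_threshold

    def fit(self, X, y=None):
        s = np.asarray(X).ravel()
        result = _arousal.em_fit(s, p0=self.p0, tol=self.tol,
                                 max_iter=self.max_iter)
        hai_series = _arousal.hai(result.smoothed, self.z_threshold)
        self.em_result_ = result
        self.alpha_ = result.params.alpha
        self.sigma_eps2_ = result.params.sigma_eps2
        self.z0_ = result.params.z0
        self.z_smooth_ = result.smoothed.z_smooth
        self.var_smooth_ = result.smoothed.var_smooth
        self.p_smooth_ = result.smoothed.p_smooth
        self.hai_ = hai_series.hai
        self.z_threshold_ = hai_series.z_threshold
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def predict_proba(self, X=None):
        """Smoothed per-bin impulse occurrence probabilities."""
        check_is_fitted(self, "em_result_")
        return self.p_smooth_
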