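"""Structured configuration with overridable numeric defaults.

One nested mapping (YAML on disk) drives the whole pipeline; every numeric
default of the package is overridable here.  Validation runs before any
computation.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config"]

DEFAULT_CONFIG: dict = {
    "input": {
        "path": None,
        "time_column": "time",
        "conductance_column": "conductance",
    },
    "simulation": None,  # dict of SimulationSpec overrides enables simulation
    "decomposition": {
        "smoothness_weight": 0.001,
        "knot_spacing_s": 10.0,
        "driver_weight": 8e-4,
        "kernel_rise_s": 0.7,
        "kernel_decay_s": 3.0,
    },
    "deconvolution": {
        "p_norm": 0.5,
        "amplitude_floor": 0.01,
        "n_restarts": 10,
        "cd_tol": 1e-6,
        "cd_max_iter": 20,
        "obs_interval_s": 0.5,
        "grid_interval_s": 0.25,
        "segment_seconds": 180.0,
        "segment_start_s": 30.0,
        "tau_r_bounds": [0.1, 1.4],
        "tau_d_bounds": [1.5, 6.0],
    },
    "arousal": {
        "bin_interval_s": 0.25,
        "p0": None,
        "tol": 1e-8,
        "max_iter": 5000,
        "z_threshold": "median",
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Optional[Mapping] = None) -> dict:
    """Merge defaults <- file <- overrides, then validate."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    """Raise ValueError on inconsistent settings before any computation."""
    dec = cfg["deconvolution"]
    rlo, rhi = dec["tau_r_bounds"]
    dlo, dhi = dec["tau_d_bounds"]
    if not (rlo < rhi and dlo < dhi):
        raise ValueError("tau bounds are inverted")
    if not 0 < dec["p_norm"] <= 1:
        raise ValueError("p_norm must lie in (0, 1]")
    ratio = dec["obs_interval_s"] / dec["grid_interval_s"]
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("obs_interval_s must be an integer multiple of "
                         "grid_interval_s")
    if dec["amplitude_floor"] < 0:
        raise ValueError("amplitude_floor must be nonnegative")
    ar = cfg["arousal"]
    if ar["p0"] is not None and not 0 < ar["p0"] < 1:
        raise ValueError("arousal p0 must lie in (0, 1)")
    if cfg["decomposition"]["smoothness_weight"] < 0:
        raise ValueError("smoothness_weight must be nonnegative")
    if cfg.get("simulation") is None and not cfg["input"].get("path"):
        # allowed when the caller supplies a Recording programmatically
        pass
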