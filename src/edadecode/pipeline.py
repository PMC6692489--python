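"""End-to-end orchestration: decompose -> deconvolve -> bin -> EM -> HAI.

All intermediate and final series are written as CSV; scalar summaries
(tau, sigma_eps^2, z0, alpha, R^2, iteration counts, convergence status and
the regularization weights actually used) land in one flat JSON document.
Outputs are a pure function of (input, config, seed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .arousal import EMResult, HAISeries, bin_impulses, em_fit, hai
from .config import load_config, validate_config
from .decomposition import Decomposition, decompose
from .deconvolution import DeconvolutionConfig, DeconvolutionResult, deconvolve
from .forward_model import SCRParameters
from .io import Recording, read_recording, write_series
from .simulate import SimulationSpec, simulate_recording

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    recording: Recording
    decomposition: Decomposition
    deconvolution: DeconvolutionResult
    em: EMResult
    hai: HAISeries
    summary: dict


def _json_safe(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def _resample(y: np.ndarray, dt_in: float, dt_out: float) -> np.ndarray:
    if abs(dt_in - dt_out) < 1e-12:
        return y
    t_in = np.arange(y.size) * dt_in
    t_out = np.arange(0.0, t_in[-1] + 1e-12, dt_out)
    return np.interp(t_out, t_in, y)


def _build_deconv_config(dec: Mapping) -> DeconvolutionConfig:
    return DeconvolutionConfig(
        p_norm=dec["p_norm"],
        amplitude_floor=dec["amplitude_floor"],
        n_restarts=dec["n_restarts"],
        cd_tol=dec["cd_tol"],
        cd_max_iter=dec["cd_max_iter"],
        segment_seconds=dec["segment_seconds"],
        segment_start_seconds=dec["segment_start_s"],
        grid_interval=dec["grid_interval_s"],
        tau_bounds=(tuple(dec["tau_r_bounds"]), tuple(dec["tau_d_bounds"])),
    )


def run_pipeline(
    config: Union[Mapping, str, Path, None] = None,
    out_dir: Union[str, Path, None] = None,
    seed: Optional[int] = None,
    recording: Optional[Recording] = None,
) -> PipelineResult:
    """Run every stage on a recording named by the config (or given directly).

    The config either points at an input CSV, contains a ``simulation``
    section, or the caller passes a ``Recording``.  Stage errors propagate
    with the failing stage named.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(overrides=config)
    validate_config(cfg)

    if recording is None:
        if cfg.get("simulation") is not None:
            sim = dict(cfg["simulation"])
            sim.setdefault("seed", seed)
            if "scr_params" in sim and not isinstance(
                    sim["scr_params"], SCRParameters):
                sim["scr_params"] = SCRParameters(*sim["scr_params"])
            spec = SimulationSpec(**sim)
            recording, _ = simulate_recording(spec)
        elif cfg["input"]["path"]:
            recording = read_recording(
                cfg["input"]["path"],
                column_spec={
                    "time": cfg["input"]["time_column"],
                    "conductance": cfg["input"]["conductance_column"],
                },
            )
        else:
            raise ValueError("config names neither an input recording nor a "
                             "simulation spec")

    dcfg = cfg["decomposition"]
    try:
        decomp = decompose(
            recording,
            smoothness_weight=dcfg["smoothness_weight"],
            knot_spacing=dcfg["knot_spacing_s"],
            driver_weight=dcfg["driver_weight"],
            kernel=SCRParameters(dcfg["kernel_rise_s"], dcfg["kernel_decay_s"]),
        )
    except Exception as exc:
        raise RuntimeError(f"decomposition stage failed: {exc}") from exc

    vcfg = cfg["deconvolution"]
    t_y = vcfg["obs_interval_s"]
    phasic = _resample(decomp.phasic, recording.sampling_interval, t_y)
    try:
        deconv = deconvolve(phasic, obs_interval=t_y,
                            config=_build_deconv_config(vcfg), seed=seed)
    except Exception as exc:
        raise RuntimeError(f"deconvolution stage failed: {exc}") from exc

    acfg = cfg["arousal"]
    duration = deconv.impulses.amplitudes.size * vcfg["grid_interval_s"]
    try:
        seq = bin_impulses(deconv.impulses, acfg["bin_interval_s"], duration)
        em = em_fit(seq, p0=acfg["p0"], tol=acfg["tol"],
                    max_iter=acfg["max_iter"])
        hai_series = hai(em.smoothed, acfg["z_threshold"])
    except Exception as exc:
        raise RuntimeError(f"arousal stage failed: {exc}") from exc

    summary = {
        "subject_id": recording.subject_id,
        "seed": seed,
        "tau_r_s": deconv.params.tau_r,
        "tau_d_s": deconv.params.tau_d,
        "r_squared": _json_safe(deconv.r_squared),
        "objective": deconv.objective,
        "lambda_final": deconv.lambda_final,
        "n_impulses": deconv.nnz,
        "cd_iterations": deconv.iterations,
        "decomposition_objective": decomp.objective,
        "decomposition_regularization": decomp.regularization,
        "alpha": em.params.alpha,
        "sigma_eps2": em.params.sigma_eps2,
        "z0": em.params.z0,
        "p0": em.params.p0,
        "z_threshold": hai_series.z_threshold,
        "em_iterations": em.n_iter,
        "em_converged": em.converged,
    }

    result = PipelineResult(recording=recording, decomposition=decomp,
                            deconvolution=deconv, em=em, hai=hai_series,
                            summary=summary)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), t_y, acfg["bin_interval_s"])
    return result


def _write_outputs(res: PipelineResult, out_dir: Path, t_y: float,
                   bin_interval: float) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = res.recording
    write_series(out_dir / "decomposition.csv", {
        "time_s": rec.times,
        "input_uS": rec.samples,
        "tonic_uS": res.decomposition.tonic,
        "phasic_uS": res.decomposition.phasic,
        "residual_uS": res.decomposition.residual,
    })
    t_imp, a_imp = res.deconvolution.impulses.nonzero()
    write_series(out_dir / "impulses.csv",
                 {"time_s": t_imp, "amplitude": a_imp})
    m = res.deconvolution.reconstruction.size
    write_series(out_dir / "reconstruction.csv", {
        "time_s": np.arange(1, m + 1) * t_y,
        "reconstruction_uS": res.deconvolution.reconstruction,
    })
    sm = res.em.smoothed
    j = np.arange(sm.z_smooth.size)
    s_arr = np.zeros(sm.z_smooth.size, dtype=int)
    idx = np.floor(t_imp / bin_interval + 1e-9).astype(int)
    s_arr[idx[idx < s_arr.size]] = 1
    write_series(out_dir / "arousal.csv", {
        "bin": j,
        "time_s": j * bin_interval,
        "s": s_arr,
        "z_smooth": sm.z_smooth,
        "var_smooth": sm.var_smooth,
        "p_smooth": sm.p_smooth,
        "p_lower": sm.p_lower,
        "p_upper": sm.p_upper,
        "hai": res.hai.hai,
    })
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
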