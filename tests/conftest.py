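"""Shared fixtures: the heavy recovery studies run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from edadecode.deconvolution import DeconvolutionConfig, deconvolve
from edadecode.experiments import (
    em_recovery_study,
    tau_recovery_study,
)
from edadecode.forward_model import SCRParameters
from edadecode.pipeline import run_pipeline
from edadecode.simulate import SimulationSpec, gen_impulse_train
from edadecode.forward_model import simulate_exact

STUDY_SEED = 1


@pytest.fixture(scope="session")
def tau_study():
    """Six-preset x five-seed deconvolution recovery study at 25 dB SNR."""
    return tau_recovery_study(base_seed=STUDY_SEED)


@pytest.fixture(scope="session")
def em_study():
    """EM process-noise recovery over 20 simulated sequences (J=2400)."""
    return em_recovery_study(base_seed=STUDY_SEED, n_runs=20)


@pytest.fixture(scope="session")
def short_noisy_fixture():
    """A 150 s noisy phasic signal with known truth, for fast solver tests."""
    spec = SimulationSpec(duration=150.0, n_impulses=10, seed=11,
                          scr_params=SCRParameters(0.7, 3.0))
    rng = np.random.default_rng(11)
    train = gen_impulse_train(spec, rng)
    phasic = simulate_exact(spec.scr_params, train, 0.0, spec.n_obs,
                            spec.obs_interval)
    raw = rng.standard_normal(phasic.size)
    noise = raw * np.sqrt(float(phasic @ phasic) /
                          (float(raw @ raw) * 10 ** 2.5))
    return {"spec": spec, "train": train, "phasic": phasic, "noise": noise,
            "noisy": phasic + noise}


@pytest.fixture(scope="session")
def short_deconvolution(short_noisy_fixture):
    """Deconvolution of the short fixture with a reduced restart budget."""
    cfg = DeconvolutionConfig(n_restarts=4)
    res = deconvolve(short_noisy_fixture["noisy"], 0.5, config=cfg, seed=11)
    return res


@pytest.fixture(scope="session")
def pipeline_pair(tmp_path_factory):
    """The full pipeline run twice with one seed, for determinism checks."""
    cfg = {
        "simulation": {"duration": 240.0, "n_impulses": 14, "seed": 1},
        "deconvolution": {"n_restarts": 4},
    }
    outs = []
    for tag in ("a", "b"):
        out_dir = tmp_path_factory.mktemp(f"pipe_{tag}")
        res = run_pipeline(cfg, out_dir=out_dir, seed=1)
        outs.append((res, out_dir))
    return outs
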