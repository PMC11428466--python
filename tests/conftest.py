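import numpy as np
import pytest

from righting.io import default_morphometrics
from righting.kinematics import GroundPlane
from righting.pipeline import AnalysisConfig, analyze_trial
from righting.synthetic import (
    SyntheticTrialConfig,
    body_mesh_anatomical,
    simulate_trial,
)


@pytest.fixture(scope="session")
def morph():
    return default_morphometrics()


@pytest.fixture(scope="session")
def body_mesh():
    return body_mesh_anatomical()


@pytest.fixture(scope="session")
def flat_plane():
    return GroundPlane(
        normal=np.array([0.0, 0.0, 1.0]), offset=0.0, residual_sd=0.25e-3
    )


@pytest.fixture(scope="session")
def mode_runs():
    """One analyzed noisy trial per righting mode (shared across tests)."""
    runs = {}
    for mode in ("diagonal_rotating", "lifted_rotating", "pitching"):
        cfg = SyntheticTrialConfig(mode=mode, n_attempts=1, seed=1)
        trial, truth = simulate_trial(cfg)
        res = analyze_trial(trial, config=AnalysisConfig(standardize=False))
        runs[mode] = (trial, truth, res)
    return runs


@pytest.fixture(scope="session")
def rigid_run(flat_plane):
    """Noise-free rigid-leg pitching trial: exact template geometry."""
    cfg = SyntheticTrialConfig(
        mode="pitching", n_attempts=1, seed=0, noise_sd=0.0, rigid_legs=True,
        damping=0.0,
    )
    trial, truth = simulate_trial(cfg)
    res = analyze_trial(
        trial,
        config=AnalysisConfig(standardize=False, robust_smoothing=False),
        plane=flat_plane,
    )
    return trial, truth, res


def interior_mask(truth, pad=15):
    """Frames away from phase transitions (smoothing transients)."""
    ph = truth.phase
    n = len(ph)
    near = np.zeros(n, bool)
    trans = list(np.flatnonzero(ph[1:] != ph[:-1]) + 1) + [0, n - 1]
    for t in trans:
        near[max(0, t - pad) : t + pad + 1] = True
    return ~near
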