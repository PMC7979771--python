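import numpy as np
import pytest

from flysleep import Chamber, LightSchedule, TrajectorySpec, TwoPhaseSpec, make_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_phase_spec():
    """Day-phase-like generating parameters."""
    return TwoPhaseSpec(beta=0.8, K=200.0, lam=1000.0, xmin=3.0, n_bouts=5000, seed=7)


@pytest.fixture
def small_traj():
    """A short noiseless tube trajectory with known planted rest bouts."""
    spec = TrajectorySpec(
        chamber=Chamber.tube(px_per_mm=2.0),
        fps=25.0,
        duration_s=240.0,
        jitter_px=0.0,
        rest_spec=TwoPhaseSpec(beta=0.8, K=60.0, lam=120.0, xmin=1.0),
        schedule=LightSchedule(),
        seed=11,
    )
    return make_trajectory(spec)
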