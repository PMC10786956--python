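import numpy as np
import pytest

from glottovib import EdgeTrajectory, VibrationParams, simulate_trajectory


@pytest.fixture
def constant_symmetric_params():
    """Constant-profile, unclamped, perfectly mirror-symmetric oscillation."""
    return VibrationParams(
        f0=200.0,
        base_amplitude_left=4.0,
        base_amplitude_right=4.0,
        amplitude_profile="constant",
        rest_halfwidth=5.0,
        noise_sd=0.0,
        seed=1,
    )


@pytest.fixture
def constant_symmetric_traj(constant_symmetric_params):
    return simulate_trajectory(constant_symmetric_params)


def make_trajectory(g_total, fps=3200.0, positions=None):
    """EdgeTrajectory with the gap split equally between both folds."""
    g_total = np.asarray(g_total, float)
    if positions is None:
        positions = np.linspace(0.0, 1.0, g_total.shape[1])
    return EdgeTrajectory(
        widths_left=g_total / 2.0,
        widths_right=g_total / 2.0,
        fps=fps,
        positions=positions,
    )
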