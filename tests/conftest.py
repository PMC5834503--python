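import numpy as np
import pytest

from smlmq import core_io, synth


@pytest.fixture(scope="session")
def straight_line():
    """Horizontal 13-µm centerline used by several filament fixtures."""
    return core_io.Polyline(
        np.array([[1000.0, 3000.0], [14000.0, 3000.0]]), thickness_px=11
    )


@pytest.fixture(scope="session")
def filament_table(straight_line):
    """Dense fully-covered 75-nm filament at 10-nm precision."""
    blink = synth.BlinkModel(on_frames=2)
    table, truth = synth.sim_filament_field(
        [straight_line], 75.0, 1.0, 300.0, blink, 10.0, seed=11, n_frames=4000
    )
    return table, truth


@pytest.fixture(scope="session")
def diffusion_mixture():
    """Immobile (D = 0.005) + mobile (D = 0.2) particles, 20-step tracks."""
    D = np.r_[np.full(200, 0.005), np.full(200, 0.2)]
    table, truth = synth.sim_membrane_diffusion(
        400, D, dt_s=0.04, n_frames=21, sigma_loc_nm=20.0, seed=4
    )
    return table, truth
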