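import numpy as np
import pytest

from aortaflow.flowmri import PlaneROI
from aortaflow.synth import SynthConfig, generate_acquisition

STEADY_WAVEFORM = [(0.0, 60.0), (0.4, 60.0)]
PULSATILE_WAVEFORM = [
    (0.0, 10.0),
    (0.08, 150.0),
    (0.15, 300.0),
    (0.25, 80.0),
    (0.36, 8.0),
    (0.55, 5.0),
]


@pytest.fixture(scope="session")
def steady_noiseless():
    """Small steady, noiseless parabolic-tube acquisition with ground truth."""
    cfg = SynthConfig(
        lumen_radius=8.0,
        lumen_length=24.0,
        grid_spacing=1.0,
        grid_margin=5.0,
        n_frames=4,
        cycle_period=0.8,
        flux_waveform=STEADY_WAVEFORM,
        venc=1500.0,
        noise_sigma_frac=0.0,
        seed=7,
    )
    return cfg, *generate_acquisition(cfg)


@pytest.fixture(scope="session")
def pulsatile_noiseless():
    cfg = SynthConfig(
        lumen_radius=8.0,
        lumen_length=24.0,
        grid_spacing=1.0,
        grid_margin=5.0,
        n_frames=10,
        cycle_period=0.8,
        flux_waveform=PULSATILE_WAVEFORM,
        venc=4000.0,
        noise_sigma_frac=0.0,
        seed=7,
    )
    return cfg, *generate_acquisition(cfg)


@pytest.fixture
def midplane():
    """Axis-aligned cross-sectional plane through the synthetic tube centre."""
    return PlaneROI(
        label="ROI A",
        origin=np.array([0.0, 0.0, 12.0]),
        normal=np.array([0.0, 0.0, 1.0]),
        basis_u=np.array([1.0, 0.0, 0.0]),
        basis_v=np.array([0.0, 1.0, 0.0]),
        extent=(22.0, 22.0),
        sample_spacing=1.0,
    )
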