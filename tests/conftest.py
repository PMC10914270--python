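import numpy as np
import pytest

from retinads.protocol import StimulusProtocol
from retinads.simulate import TuningGroundTruth, generate_tuned_roi


@pytest.fixture(scope="session")
def bar_protocol() -> StimulusProtocol:
    """Default 12-direction moving-bar sweep (20 s adaptation, 8 s bar)."""
    return StimulusProtocol.moving_bar()


@pytest.fixture(scope="session")
def short_protocol() -> StimulusProtocol:
    """Single-direction sweep: fast fixture for preprocessing tests."""
    return StimulusProtocol.moving_bar(directions_deg=[0.0])


@pytest.fixture(scope="session")
def flash_protocol() -> StimulusProtocol:
    return StimulusProtocol.flash()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_tuned_roi(bar_protocol):
    """One noiseless cosine-tuned ROI (pd 90 deg, contrast 0.6)."""
    truth = TuningGroundTruth(roi_id="roi0", pd_true_deg=90.0, contrast=0.6,
                              peak_amplitude=1.0, noise_sd=0.0)
    return generate_tuned_roi(bar_protocol, truth, seed=0), truth
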