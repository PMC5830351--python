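import numpy as np
import pytest

from condyn.betaseries import estimate_beta_series
from condyn.design import generate_design
from condyn.synth import acquisition_truth, simulate_bold_roi


@pytest.fixture(scope="session")
def design():
    """Default 120-trial acquisition block."""
    return generate_design(seed=42)


@pytest.fixture(scope="session")
def noiseless_truth():
    return acquisition_truth(noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def noiseless_beta(design, noiseless_truth):
    """β-series recovered from a noise-free simulated ROI (no scaling/filter,
    so recovery is exact)."""
    roi = simulate_bold_roi(design, noiseless_truth, roi="insula")
    with pytest.warns(UserWarning, match="collinearity"):
        return estimate_beta_series(roi, design, global_scaling=False,
                                    highpass_cutoff_s=None)


@pytest.fixture(scope="session")
def planted_amplitudes(design, noiseless_truth):
    return np.array([
        noiseless_truth.amplitude(i, t.condition)
        for i, t in enumerate(design.trials)
    ])
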