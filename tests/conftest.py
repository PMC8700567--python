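import numpy as np
import pytest

from pedct import (
    calibrate_distribution,
    default_phantom_spec,
    generate_phantom,
)

# 10-year-old calibration targets used throughout the suite:
# mean -803 HU, SD 147 HU, 0.53% below (mean-1SD), 10.20% above (mean+1SD).
TARGETS_10Y = dict(
    target_mean=-803.0, target_sd=147.0, target_frac_low=0.0053, target_frac_high=0.1020
)


@pytest.fixture(scope="session")
def dist10():
    return calibrate_distribution(**TARGETS_10Y)


@pytest.fixture(scope="session")
def default_phantom(dist10):
    """(volume, ground-truth mask, ground-truth mL) on the default grid."""
    spec = default_phantom_spec(distribution=dist10)
    return generate_phantom(spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260903)
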