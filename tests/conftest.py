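import numpy as np
import pytest

from muklock import synthetic


@pytest.fixture(scope="session")
def planted_genome():
    """A 50 kb circular genome with a family of sites planted near ter."""
    ter = 35000
    planted = [("GTTACATTGTAAC", (ter + off) % 50000, 0)
               for off in (-4000, -1500, 0, 1800, 3600)]
    return synthetic.gen_genome(length=50000, ori_pos=10000,
                                skew_amplitude=0.3, planted=planted, seed=11)


@pytest.fixture(scope="session")
def two_band_lane():
    """Lane with 300/100-area bands on a drifting cubic background."""
    return synthetic.gen_lane_profile(
        bands=[(300.0, 12.0, 300.0), (650.0, 12.0, 100.0)],
        background_coefficients=(5.0, 4.0, -3.0, 1.0),
        noise_sd=0.05, length_px=1000, seed=5)
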