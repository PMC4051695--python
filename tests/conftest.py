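import numpy as np
import pytest

from sarcotrack import synthetic as syn


@pytest.fixture(scope="session")
def default_truth() -> syn.StriationTruth:
    """Wild-type-like geometry: SL 3.36 µm, TFL 1.60 µm, HZ 0.16 µm."""
    return syn.StriationTruth.from_period(3.36, 0.16)


@pytest.fixture(scope="session")
def noisy_profile(default_truth):
    """8-sarcomere phalloidin profile with noise at 5% of dynamic range."""
    noise = 0.05 * (default_truth.z_peak_level - default_truth.background)
    return syn.gen_striation_profile(default_truth, 8, noise_sd=noise, seed=1)


@pytest.fixture(scope="session")
def act88f_kinetics() -> syn.TurnoverKinetics:
    return syn.TurnoverKinetics(lag=20.0, rise_end=95.0, decay_halflife=72.0)


@pytest.fixture(scope="session")
def egfp_kinetics() -> syn.TurnoverKinetics:
    return syn.TurnoverKinetics(lag=15.0, rise_end=95.0, body_fraction=0.95, decays=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
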