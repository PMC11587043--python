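import numpy as np
import pytest

import critpow as cw


@pytest.fixture(scope="session")
def canonical_profile():
    """Mid-range athlete used throughout: CP 250 W, W' 12 kJ, 20% unspent."""
    return cw.AthleteProfile(cp=250.0, w_prime=12000.0, f_unspent=0.2,
                             noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def canonical_cpt(canonical_profile):
    """Noise-free CPT at 300 W: task failure at exactly 192 s."""
    return cw.simulate_cpt(canonical_profile, prescribed_power=300.0)


@pytest.fixture(scope="session")
def allout_profile():
    """Sprint profile with explicit peak power (tau = 100/3 s)."""
    return cw.AthleteProfile(cp=250.0, w_prime=15000.0, p_max=700.0,
                             noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def canonical_3mt(allout_profile):
    return cw.simulate_3mt(allout_profile)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    return cw.simulate_cohort(8, seed=5, noise_sd=5.0)


@pytest.fixture(scope="session")
def small_clean_cohort():
    return cw.simulate_cohort(6, seed=9, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
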