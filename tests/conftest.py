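import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from nbtherm import synthetic as syn  # noqa: E402


@pytest.fixture(scope="session")
def nb1_clean():
    """Noise-free NB-AGT-1-like ground truth."""
    return syn.default_ground_truth(
        "NB-AGT-1", seed=7,
        noise=syn.NoiseSpec(cp_frac_of_peak=0.0, fluor_frac_of_max=0.0,
                            dh_cal_sigma=0.0))


@pytest.fixture(scope="session")
def nb2_clean():
    """Noise-free NB-AGT-2-like ground truth."""
    return syn.default_ground_truth(
        "NB-AGT-2", seed=7,
        noise=syn.NoiseSpec(cp_frac_of_peak=0.0, fluor_frac_of_max=0.0,
                            dh_cal_sigma=0.0))


@pytest.fixture(scope="session")
def nb1_noisy():
    """NB-AGT-1-like ground truth at the default noise level."""
    return syn.default_ground_truth("NB-AGT-1", seed=7)


@pytest.fixture(scope="session")
def nb1_clean_upscan(nb1_clean):
    return syn.gen_dsc_scan(nb1_clean)


@pytest.fixture(scope="session")
def nb1_clean_fit(nb1_clean_upscan):
    from nbtherm.dsc import fit_thermal_two_state
    return fit_thermal_two_state(nb1_clean_upscan)
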