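import pytest

from shiftbind import make_truth, simulate_titration


@pytest.fixture(scope="session")
def single_truth():
    return make_truth("single_site", seed=1, noise_sigma_ppm=0.0)


@pytest.fixture(scope="session")
def single_ds(single_truth):
    return simulate_titration(single_truth)


@pytest.fixture(scope="session")
def two_site_truth():
    return make_truth("pHMbII_two_site", seed=1, noise_sigma_ppm=0.0)


@pytest.fixture(scope="session")
def two_site_ds(two_site_truth):
    return simulate_titration(two_site_truth)
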