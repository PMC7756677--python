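import numpy as np
import pytest

from tolagree import DifferenceSummary, calibrate_to_summary, generate_fixture


@pytest.fixture(scope="session")
def dog_summary() -> DifferenceSummary:
    """Printed difference summary of the 20-dog erythrocyte comparison
    (A120 vs TH1, units 10^6/uL)."""
    return DifferenceSummary(n=20, mean_diff=-0.012, sd_diff=0.047)


@pytest.fixture(scope="session")
def dog_sample(dog_summary):
    """Synthetic paired sample calibrated so its differences reproduce the
    printed summary statistics exactly (the raw 20-dog values are not
    published)."""
    raw = generate_fixture(
        dog_summary.n, true_bias=dog_summary.mean_diff,
        sd_diff=dog_summary.sd_diff, base_level=7.3, between_subject_sd=0.6,
        seed=20, method_names=("A120", "TH1"),
    )
    return calibrate_to_summary(raw, dog_summary.mean_diff, dog_summary.sd_diff)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
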