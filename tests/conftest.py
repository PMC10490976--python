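import numpy as np
import pytest

import cornvec as cv


@pytest.fixture
def clean_config():
    """Deterministic small cohort with no injected defects and single eyes."""
    return cv.SyntheticConfig(n_eyes=30, seed=11, both_eyes_fraction=0.0)


@pytest.fixture
def noiseless_config():
    """All randomness in the measurement chain switched off: device readings
    equal the truth vectors exactly (biases zero, noise zero, deterministic SIA)."""
    zero3 = (0.0, 0.0, 0.0)
    return cv.SyntheticConfig(
        n_eyes=12,
        seed=5,
        both_eyes_fraction=0.0,
        radius_ratio=(7.77 / 6.4, 0.0),
        back_eq_jitter_sd=0.0,
        back_extra_c0=(-0.1920, 0.0),
        back_extra_c45=(-0.0327, 0.0),
        iolm_front_bias=zero3,
        iolm_back_bias=zero3,
        casia_front_bias=zero3,
        casia_back_bias=zero3,
        iolm_front_noise=zero3,
        iolm_back_noise=zero3,
        casia_front_noise=zero3,
        casia_back_noise=zero3,
        sia_front_sd=zero3,
        sia_back_sd=zero3,
    )


@pytest.fixture
def small_cohort(clean_config):
    records, truth = cv.generate_cohort(clean_config)
    return records, truth


@pytest.fixture
def kerat_to_real_arrays():
    """Panel arrays (X preop IOLM keratometric astig, Y postop real astig) from
    a mid-sized clean synthetic cohort."""
    cfg = cv.SyntheticConfig(n_eyes=88, seed=21, both_eyes_fraction=0.0)
    records, _ = cv.generate_cohort(cfg)
    panel = cv.decompose_cohort(records)
    X = panel.frame[["IOLM_keratometric_C0", "IOLM_keratometric_C45"]].to_numpy()
    Y = panel.frame[["CASIA_post_total_C0", "CASIA_post_total_C45"]].to_numpy()
    return X, Y
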