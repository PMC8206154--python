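import numpy as np
import pytest

from gsmvar import (
    FilterBankSpec,
    GSMParams,
    apply_filterbank,
    build_filterbank,
    estimate_noise_cov,
    make_texture_ensemble,
    train_moment_matching,
)

# small geometry for cheap unit tests (2 x 2 deg patch)
SMALL_SPEC = FilterBankSpec(
    patch_size_px=40, envelope_sd_deg=0.2, surround_ring_radius_deg=0.5
)


@pytest.fixture(scope="session")
def small_bank():
    return build_filterbank(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_bank():
    return build_filterbank(FilterBankSpec())


@pytest.fixture(scope="session")
def trained_params(default_bank):
    """GSM trained on 10,000 pink-texture patches at the default geometry."""
    spec = default_bank.spec
    patches = make_texture_ensemble("pink_texture", 10000, spec.patch_size_px, seed=0)
    C_g = train_moment_matching(apply_filterbank(default_bank, patches))
    C_noise = estimate_noise_cov(default_bank, n_patches=10000, seed=1)
    return GSMParams(
        C_g=C_g,
        C_noise=C_noise,
        meta={"training_source": "pink_texture", "n": 10000, "seed": 0},
    )


@pytest.fixture(scope="session")
def toy_params_2d():
    """Well-conditioned 2-D model for posterior unit tests."""
    C_g = np.array([[1.0, 0.4], [0.4, 0.8]])
    C_noise = 0.05 * np.eye(2)
    return GSMParams(C_g=C_g, C_noise=C_noise)
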