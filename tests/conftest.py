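import numpy as np
import pytest

from nuquant.simulate import MitoticParams, NucleusPhenotypeParams, gen_mitotic_stack, gen_nucleus_stack


def small_mitotic_params(seed: int, **overrides) -> MitoticParams:
    """Small, optics-free mitotic figure for fast statistical tests."""
    kw = dict(shape=(16, 48, 48), n_marker_voxels=3000, psf_fwhm_nm=None, noise=None, seed=seed)
    kw.update(overrides)
    return MitoticParams(**kw)


@pytest.fixture(scope="session")
def clean_fixture_nucleus():
    """Noise-free nucleus with a known structure inventory (shared)."""
    params = NucleusPhenotypeParams(
        phenotype="pre_mga",
        seed=9,
        psf_fwhm_nm=None,
        noise=None,
        invagination_spec=[
            ("NUP+/LamB+", 3, 1.0),
            ("NUP-/LamB+", 2, 0.8),
            ("NUP+/LamB-", 1, 0.5),
        ],
        vesicle_count=2,
        extranuclear_cluster_mode="none",
    )
    stack, truth = gen_nucleus_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def default_mitotic():
    """One default-condition mitotic scene with enrichment weights."""
    params = MitoticParams(seed=21, class_weights=(1, 6, 6, 4, 3, 2.5, 2), n_marker_voxels=20000)
    stack, truth = gen_mitotic_stack(params)
    return params, stack, truth
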