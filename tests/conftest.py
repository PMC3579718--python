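import numpy as np
import pytest

import memrimap as mm


@pytest.fixture(scope="session")
def atlas():
    """Reduced-grid atlas phantom shared across tests (desk-scale runs)."""
    return mm.build_atlas_phantom((48, 48, 32), (0.2, 0.2, 0.3), geometry_seed=1)


@pytest.fixture(scope="session")
def atlas_small():
    """Minimum-size atlas for cheap constructions."""
    return mm.build_atlas_phantom((32, 32, 32), (0.25, 0.25, 0.3), geometry_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def clean_subject(atlas):
    """One noise-free, perfectly aligned control subject and its truth."""
    spec = mm.SubjectSpec(
        bias_field_amplitude=0.0, noise_sigma=0.0, uptake_jitter_sd=0.0, seed=7
    )
    vol, truth = mm.simulate_subject(atlas, spec)
    mask = mm.BrainMask(mask=truth.labels > 0, affine=truth.affine)
    return vol, truth, mask
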