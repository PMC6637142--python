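import logging

import numpy as np
import pytest

import macsim as m

logging.getLogger("macsim").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def truth30():
    """Small ground-truth network shared across construction tests."""
    return m.make_ground_truth(n_rois=30, rng_seed=2)


@pytest.fixture(scope="session")
def cohort30(truth30):
    spec = m.SyntheticSubjectSpec(n_subjects=3, rng_seed=2, n_voxels_per_roi=10)
    return m.simulate_tractography_counts(truth30, spec)


@pytest.fixture(scope="session")
def conn8():
    """Tiny 8-node connectome for fast simulator tests."""
    return m.make_ground_truth(n_rois=8, density=0.6, rng_seed=5).to_connectome()
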