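import numpy as np
import pytest

from neurosem.geometry import make_geometry
from neurosem.synth import (
    ActivationDataset,
    GroundTruth,
    sample_ground_truth,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_geom():
    """64-voxel grid, octant lobe split (16 voxels per lobe)."""
    return make_geometry((4, 4, 4))


@pytest.fixture(scope="session")
def small_geom():
    """256-voxel grid for reduced-scale cohort tests (64 voxels per lobe)."""
    return make_geometry((8, 8, 4))


@pytest.fixture(scope="session")
def default_gt():
    """Default-scale ground truth (12x12x8 grid, 45 concepts, low noise)."""
    return sample_ground_truth(seed=1)


@pytest.fixture(scope="session")
def zero_noise_gt(small_geom):
    return sample_ground_truth(
        geometry=small_geom,
        clusters_per_dimension=2,
        cluster_size_range=(5, 6),
        noise_sd=0.0,
        participant_sd=0.0,
        seed=3,
    )


def make_noise_dataset(
    rng, n_concepts=8, n_presentations=4, geom=None, pid="N00", group="faculty"
):
    """A pure-noise participant: no planted structure at all."""
    if geom is None:
        geom = make_geometry((4, 4, 4))
    psc = rng.standard_normal((n_concepts, n_presentations, geom.n_voxels))
    return ActivationDataset(
        participant_id=pid,
        participant_index=0,
        group=group,
        psc=psc,
        concept_labels=[f"c{i}" for i in range(n_concepts)],
        geometry=geom,
    )


@pytest.fixture
def noise_dataset():
    return make_noise_dataset(np.random.default_rng(11))
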