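import numpy as np
import pytest

from alffconn import (
    AnalysisConfig,
    BoldRun,
    MaskVolume,
    RoiSet,
    demo_cohort_spec,
    desk_analysis_config,
    generate_cohort,
)
from alffconn.synth import grid_affine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_run(data=None, shape=(6, 6, 4, 40), tr=2.5, seed=0, subject_id="sub-test"):
    if data is None:
        data = np.random.default_rng(seed).standard_normal(shape)
    affine = grid_affine(data.shape[:3], (3.44, 3.44, 3.40))
    return BoldRun(data=data, tr=tr, affine=affine, subject_id=subject_id)


@pytest.fixture
def small_run():
    return make_run()


@pytest.fixture
def brain_mask(small_run):
    return MaskVolume(np.ones(small_run.shape3d, dtype=bool), "brain", small_run.affine)


@pytest.fixture(scope="session")
def demo_cohort():
    """One desk-scale cohort with planted structure, shared across tests."""
    spec = demo_cohort_spec(n_subjects=12, t_points=100, seed=7)
    subjects, truth = generate_cohort(spec)
    return spec, subjects, truth


@pytest.fixture(scope="session")
def desk_config():
    return desk_analysis_config()


def tiny_roiset(centers, radii=None, networks=None):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers)
    if radii is None:
        radii = np.full(n, 4.0)
    if networks is None:
        networks = ["net"] * n
    return RoiSet(
        labels=[f"roi{i}" for i in range(n)],
        networks=list(networks),
        centers=centers,
        radii=np.atleast_1d(np.asarray(radii, dtype=float)),
    )
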