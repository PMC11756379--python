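import numpy as np
import pandas as pd
import pytest

import lesionkit as lk

TINY = dict(
    n_subjects=80,
    grid_shape=(16, 16, 12),
    midline_x=8,
    n_regions=6,
    n_streamlines=40,
    lesion_size_range=(5, 60),
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_config():
    return lk.SimConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return lk.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return lk.generate_toy_atlas(tiny_config)


def make_cohort(masks: np.ndarray, midline_x: int | None = None) -> lk.LesionCohort:
    """Wrap a raw mask stack in a LesionCohort with a trivial clinical table."""
    n, nx, ny, nz = masks.shape
    grid = lk.VoxelGrid(shape=(nx, ny, nz), midline_x=midline_x or nx // 2)
    clinical = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": 60.0,
            "nihss_24h": 0,
            "nihss_3m": 0,
            "mrs_3m": 0,
        }
    )
    return lk.LesionCohort(
        grid=grid,
        subject_ids=list(clinical["subject_id"]),
        masks=masks.astype(bool),
        clinical=clinical,
    )


def make_space(X: np.ndarray, kind: str = "component") -> lk.FeatureSpace:
    """Feature space over a raw matrix with synthetic provenance."""
    n, F = X.shape
    if kind == "component":
        prov = [lk.FeatureProvenance(kind="component", component=k) for k in range(F)]
    elif kind == "connection":
        prov = [
            lk.FeatureProvenance(kind="connection", connection=(1, k + 2))
            for k in range(F)
        ]
    else:
        prov = [
            lk.FeatureProvenance(kind="voxel", voxel=(k, 0, 0)) for k in range(F)
        ]
    return lk.FeatureSpace(
        matrix=X, provenance=prov, subject_ids=[f"s{i}" for i in range(n)]
    )
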