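"""Lesion masks to analysis-ready feature spaces.

Three feature families are produced from a cohort of binary lesion masks:

* per-voxel lesion status (binary), restricted to voxels lesioned in at
  least ``min_patients`` subjects;
* per-connection indirect disconnection counts, obtained by intersecting
  each lesion with a reference streamline atlas and counting, for every
  region pair, the streamlines that both terminate in the pair and pass
  through the lesion;
* lesion overlap maps (per-voxel subject counts) for descriptive topography.

A streamline counts as disconnected when at least one voxel of its path lies
inside the lesion; each disconnected streamline contributes exactly once to
the symmetric region-pair cell of its two endpoints.  Connection features are
taken from the strict upper triangle only (the symmetric half and the
intra-region diagonal are redundant respectively not region-to-region).
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    FeatureProvenance,
    FeatureSpace,
    LesionCohort,
    Parcellation,
    StreamlineAtlas,
)

__all__ = [
    "compute_disconnection",
    "compute_cohort_disconnection",
    "build_voxel_features",
    "build_connection_features",
    "overlap_map",
]


def compute_disconnection(
    mask: np.ndarray, atlas: StreamlineAtlas, parcellation: Parcellation
) -> np.ndarray:
    """Symmetric region-by-region disconnected-streamline count matrix.

    Parameters
    ----------
    mask:
        Binary lesion volume on the atlas grid.
    atlas:
        Reference streamline set; each streamline carries its endpoint
        region pair.
    parcellation:
        Supplies the region count (the matrix is R-by-R).

    Returns
    -------
    (R, R) integer array; ``counts[i-1, j-1]`` is the number of atlas
    streamlines with endpoints {i, j} that intersect the lesion.  The matrix
    is symmetric and its upper triangle (diagonal included) sums to the total
    number of disconnected streamlines.
    """
    mask = np.asarray(mask)
    if mask.shape != atlas.grid.shape:
        raise ValueError("grid_mismatch")
    mask = mask.astype(bool)
    R = parcellation.n_regions
    counts = np.zeros((R, R), dtype=int)
    for sl in atlas.streamlines:
        p = sl.path
        if mask[p[:, 0], p[:, 1], p[:, 2]].any():
            i, j = sl.endpoints
            if i == j:
                counts[i - 1, i - 1] += 1
            else:
                counts[i - 1, j - 1] += 1
                counts[j - 1, i - 1] += 1
    return counts


def compute_cohort_disconnection(
    cohort: LesionCohort, atlas: StreamlineAtlas, parcellation: Parcellation
) -> np.ndarray:
    """Stack of per-subject disconnection matrices, shape (n, R, R).

    Precomputes each streamline's voxel set once, so cohort-scale runs do not
    re-walk paths per subject.
    """
    if cohort.grid.shape != atlas.grid.shape:
        raise ValueError("grid_mismatch")
    n = cohort.n_subjects
    R = parcellation.n_regions
    flat_masks = cohort.masks.reshape(n, -1)
    out = np.zeros((n, R, R), dtype=int)
    shape = atlas.grid.shape
    for sl in atlas.streamlines:
        p = sl.path
        flat_idx = np.ravel_multi_index((p[:, 0], p[:, 1], p[:, 2]), shape)
        hit = flat_masks[:, np.unique(flat_idx)].any(axis=1)
        i, j = sl.endpoints
        out[hit, i - 1, j - 1] += 1
        if i != j:
            out[hit, j - 1, i - 1] += 1
    return out


def build_voxel_features(
    cohort: LesionCohort, min_patients: int = 10
) -> FeatureSpace:
    """Binary voxel lesion-status features, prevalence-filtered.

    A voxel becomes a feature column iff it is lesioned in at least
    ``min_patients`` subjects.  Columns follow raster order with x fastest;
    ``retained_mask`` marks the surviving voxels over the full grid in that
    order.
    """
    n = cohort.n_subjects
    if n < min_patients:
        raise ValueError("empty_feature_space")
    nx, ny, nz = cohort.grid.shape
    # raster order, x fastest: transpose so x is the last (fastest) axis
    flat = np.transpose(cohort.masks, (0, 3, 2, 1)).reshape(n, -1)
    prevalence = flat.sum(axis=0)
    retained = prevalence >= min_patients
    # a voxel lesioned in every subject would be constant; drop it too
    retained &= prevalence < n
    if not retained.any():
        raise ValueError("empty_feature_space")
    cols = np.nonzero(retained)[0]
    z, y, x = np.unravel_index(cols, (nz, ny, nx))
    provenance = [
        FeatureProvenance(kind="voxel", voxel=(int(xi), int(yi), int(zi)))
        for xi, yi, zi in zip(x, y, z)
    ]
    return FeatureSpace(
        matrix=flat[:, cols].astype(float),
        provenance=provenance,
        subject_ids=list(cohort.subject_ids),
        retained_mask=retained,
    )


def build_connection_features(
    matrices: np.ndarray,
    subject_ids: list[str] | None = None,
    min_patients: int = 10,
) -> FeatureSpace:
    """Disconnection-count features over strict-upper-triangle region pairs.

    Parameters
    ----------
    matrices:
        (n_subjects, R, R) stack of symmetric disconnection matrices.
    min_patients:
        A connection is retained iff its count is nonzero in at least this
        many subjects.

    Candidate features are the strict upper triangle only — one cell per
    unordered region pair, the diagonal (intra-region) excluded — ordered
    lexicographically by (i, j).  Feature values are raw disconnected
    streamline counts.
    """
    matrices = np.asarray(matrices)
    n, R, R2 = matrices.shape
    if R != R2:
        raise ValueError("disconnection matrices must be square")
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(n)]
    iu, ju = np.triu_indices(R, k=1)
    values = matrices[:, iu, ju].astype(float)
    nonzero_in = (values > 0).sum(axis=0)
    retained = nonzero_in >= min_patients
    # drop columns identical across subjects (no variance to analyse)
    retained &= values.std(axis=0) > 0
    if not retained.any():
        raise ValueError("empty_feature_space")
    cols = np.nonzero(retained)[0]
    provenance = [
        FeatureProvenance(
            kind="connection", connection=(int(iu[c]) + 1, int(ju[c]) + 1)
        )
        for c in cols
    ]
    return FeatureSpace(
        matrix=values[:, cols],
        provenance=provenance,
        subject_ids=list(subject_ids),
        retained_mask=retained,
    )


def overlap_map(cohort: LesionCohort) -> np.ndarray:
    """Per-voxel count of lesioned subjects (the lesion overlap topography)."""
    if cohort.n_subjects < 1:
        raise ValueError("empty cohort")
    return cohort.masks.sum(axis=0).astype(int)
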