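"""Reading and writing the on-disk formats of the pipeline.

Volumes (lesion masks, parcellations, overlap and impact maps) are NIfTI via
nibabel; the clinical table and ground truth are TSV; streamlines use a
documented JSON dialect:

.. code-block:: json

    {
      "grid_shape": [32, 32, 24],
      "midline_x": 16,
      "streamlines": [
        {"path": [[x, y, z], ...], "endpoints": [i, j]},
        ...
      ]
    }

where voxel triplets are 0-based integers on the common grid and endpoint
labels are the 1-based parcellation regions of the two terminal voxels.
Disconnection matrices are written both as a dense whitespace-separated text
matrix and as an edge-list TSV (region_i, region_j, count; strict upper
triangle, nonzero cells only).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    GroundTruth,
    LesionCohort,
    Parcellation,
    Streamline,
    StreamlineAtlas,
    VoxelGrid,
)

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_atlas_json",
    "load_atlas_json",
    "save_parcellation",
    "load_parcellation",
    "save_volume",
    "save_disconnection_matrix",
    "save_ground_truth",
]

_CLINICAL_FILE = "clinical.tsv"
_MASKS_FILE = "lesion_masks.nii.gz"
_GRID_FILE = "grid.json"


def save_volume(volume: np.ndarray, path: str | Path) -> None:
    """Write a 3-D volume as NIfTI with an identity affine."""
    img = nib.Nifti1Image(np.asarray(volume).astype(np.float32), np.eye(4))
    nib.save(img, str(path))


def save_cohort(cohort: LesionCohort, out_dir: str | Path) -> None:
    """Write masks (4-D NIfTI stack), clinical TSV and grid metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.transpose(cohort.masks.astype(np.uint8), (1, 2, 3, 0))
    nib.save(nib.Nifti1Image(stack, np.eye(4)), str(out / _MASKS_FILE))
    cohort.clinical.to_csv(out / _CLINICAL_FILE, sep="\t", index=False)
    (out / _GRID_FILE).write_text(
        json.dumps(
            {"grid_shape": list(cohort.grid.shape), "midline_x": cohort.grid.midline_x}
        )
    )


def load_cohort(out_dir: str | Path) -> LesionCohort:
    out = Path(out_dir)
    meta = json.loads((out / _GRID_FILE).read_text())
    grid = VoxelGrid(shape=tuple(meta["grid_shape"]), midline_x=meta["midline_x"])
    stack = np.asanyarray(nib.load(str(out / _MASKS_FILE)).dataobj)
    masks = np.transpose(stack, (3, 0, 1, 2)).astype(bool)
    clinical = pd.read_csv(out / _CLINICAL_FILE, sep="\t")
    return LesionCohort(
        grid=grid,
        subject_ids=list(clinical["subject_id"]),
        masks=masks,
        clinical=clinical,
    )


def save_atlas_json(atlas: StreamlineAtlas, path: str | Path) -> None:
    payload = {
        "grid_shape": list(atlas.grid.shape),
        "midline_x": atlas.grid.midline_x,
        "streamlines": [
            {"path": sl.path.tolist(), "endpoints": list(sl.endpoints)}
            for sl in atlas.streamlines
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_atlas_json(path: str | Path) -> StreamlineAtlas:
    payload = json.loads(Path(path).read_text())
    grid = VoxelGrid(
        shape=tuple(payload["grid_shape"]), midline_x=payload["midline_x"]
    )
    streamlines = [
        Streamline(
            path=np.asarray(s["path"], dtype=int),
            endpoints=(int(s["endpoints"][0]), int(s["endpoints"][1])),
        )
        for s in payload["streamlines"]
    ]
    return StreamlineAtlas(grid=grid, streamlines=streamlines)


def save_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    img = nib.Nifti1Image(parcellation.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(path))


def load_parcellation(path: str | Path, midline_x: int) -> Parcellation:
    labels = np.asanyarray(nib.load(str(path)).dataobj).astype(int)
    grid = VoxelGrid(shape=labels.shape, midline_x=midline_x)
    return Parcellation(grid=grid, labels=labels)


def save_disconnection_matrix(
    counts: np.ndarray, out_prefix: str | Path
) -> None:
    """Write one subject's matrix as dense text plus an edge-list TSV."""
    counts = np.asarray(counts, dtype=int)
    prefix = Path(out_prefix)
    np.savetxt(f"{prefix}_matrix.txt", counts, fmt="%d")
    iu, ju = np.triu_indices(counts.shape[0], k=1)
    nz = counts[iu, ju] > 0
    pd.DataFrame(
        {"region_i": iu[nz] + 1, "region_j": ju[nz] + 1, "count": counts[iu, ju][nz]}
    ).to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)


def save_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write ground truth separately from the cohort (analyses never read it)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(truth.eloquent_weights, out / "eloquent_weights.nii.gz")
    pd.DataFrame(
        {
            "subject_reserve": truth.subject_reserve,
            "true_acute_linear": truth.true_acute_linear,
            "true_chronic_linear": truth.true_chronic_linear,
        }
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
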