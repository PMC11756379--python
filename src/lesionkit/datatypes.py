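"""Core data containers shared by the simulation, feature and analysis stages.

Everything in-memory is plain numpy / pandas: lesion masks are boolean 3-D
arrays on a shared :class:`VoxelGrid`, the clinical table is a
:class:`pandas.DataFrame` with one row per subject, and feature spaces carry
explicit per-column provenance so any column can be traced back to a voxel,
a region pair, a principal component or a clinical covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "LesionCohort",
    "Parcellation",
    "Streamline",
    "StreamlineAtlas",
    "FeatureSpace",
    "GroundTruth",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A common 3-D voxel grid with a sagittal midline.

    Hemisphere membership of a voxel is the sign of ``x - midline_x``:
    negative is left, positive is right, and voxels exactly on the midline
    column belong to neither hemisphere (they are excluded from
    hemisphere-specific analyses).
    """

    shape: tuple[int, int, int]
    midline_x: int

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 4 for s in self.shape):
            raise ValueError("grid_shape must be three dimensions of size >= 4")
        if not (0 <= self.midline_x < self.shape[0]):
            raise ValueError("midline_x outside grid")

    def hemisphere_of_x(self, x: np.ndarray | int) -> np.ndarray:
        """-1 for left, +1 for right, 0 for the midline column."""
        return np.sign(np.asarray(x) - self.midline_x).astype(int)

    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class LesionCohort:
    """Aligned binary lesion masks plus the clinical table.

    ``masks`` has shape ``(n_subjects, *grid.shape)`` and dtype bool.
    ``clinical`` has one row per subject, indexed 0..n-1 in mask order, with
    columns ``subject_id, age, nihss_24h, nihss_3m, mrs_3m`` (``nihss_3m``
    may contain NaN; subjects with missing outcome are excluded from the
    corresponding analyses by the caller).
    """

    grid: VoxelGrid
    subject_ids: list[str]
    masks: np.ndarray
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if self.masks.shape != (n, *self.grid.shape):
            raise ValueError("masks shape does not match grid / subject count")
        if self.masks.dtype != bool:
            uniq = np.unique(self.masks)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("masks must be binary")
            self.masks = self.masks.astype(bool)
        if len(self.clinical) != n:
            raise ValueError("clinical table must have one row per subject")
        for col in ("age", "nihss_24h", "mrs_3m"):
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        nihss = self.clinical["nihss_24h"].to_numpy(float)
        if np.nanmin(nihss) < 0 or np.nanmax(nihss) > 42:
            raise ValueError("nihss_24h out of range 0..42")
        mrs = self.clinical["mrs_3m"].to_numpy(float)
        if np.nanmin(mrs) < 0 or np.nanmax(mrs) > 6:
            raise ValueError("mrs_3m out of range 0..6")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class Parcellation:
    """Integer region labels on a voxel grid; 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray  # int volume, 0 = background, 1..n_regions

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise ValueError("parcellation labels not on the given grid")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0:
            raise ValueError("negative region label")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_hemispheres(self) -> dict[int, int]:
        """Majority hemisphere (-1 left / +1 right / 0 mixed) per region."""
        out: dict[int, int] = {}
        xs = np.arange(self.grid.shape[0])
        hemi_col = self.grid.hemisphere_of_x(xs)
        for r in range(1, self.n_regions + 1):
            where = np.nonzero(self.labels == r)
            if len(where[0]) == 0:
                out[r] = 0
                continue
            h = hemi_col[where[0]]
            out[r] = int(np.sign(h.sum()))
        return out


@dataclass(frozen=True)
class Streamline:
    """One streamline: an ordered voxel path and its two endpoint regions.

    ``path`` is an (L, 3) int array of 0-based voxel triplets; successive
    voxels are 26-adjacent.  ``endpoints`` is the unordered pair of 1-based
    region labels the two terminal voxels were assigned to.
    """

    path: np.ndarray
    endpoints: tuple[int, int]

    def __post_init__(self) -> None:
        p = np.asarray(self.path, dtype=int)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] == 0:
            raise ValueError("path must be a nonempty (L, 3) array")
        object.__setattr__(self, "path", p)
        i, j = self.endpoints
        if i < 1 or j < 1:
            raise ValueError("endpoint labels are 1-based positive integers")


@dataclass
class StreamlineAtlas:
    """A reference streamline set on a voxel grid with region endpoints."""

    grid: VoxelGrid
    streamlines: list[Streamline]

    def __len__(self) -> int:
        return len(self.streamlines)


ProvenanceKind = Literal["voxel", "connection", "component", "covariate"]


@dataclass(frozen=True)
class FeatureProvenance:
    """Origin of one feature column."""

    kind: ProvenanceKind
    voxel: tuple[int, int, int] | None = None
    connection: tuple[int, int] | None = None
    component: int | None = None
    covariate: str | None = None

    def describe(self) -> str:
        if self.kind == "voxel":
            return f"voxel{self.voxel}"
        if self.kind == "connection":
            return f"connection{self.connection}"
        if self.kind == "component":
            return f"component{self.component}"
        return f"covariate:{self.covariate}"


@dataclass
class FeatureSpace:
    """A subjects-by-features matrix with per-column provenance.

    ``retained_mask`` records, over the original candidate feature set
    (all voxels in raster order, or all strict-upper-triangle region pairs
    in lexicographic order), which candidates survived filtering.  It is
    ``None`` for derived spaces such as principal components.
    """

    matrix: np.ndarray
    provenance: list[FeatureProvenance]
    subject_ids: list[str]
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if self.matrix.shape[1] != len(self.provenance):
            raise ValueError("provenance must cover every column exactly once")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def columns_of_kind(self, kind: ProvenanceKind) -> np.ndarray:
        return np.array(
            [k for k, p in enumerate(self.provenance) if p.kind == kind], dtype=int
        )

    def voxel_coordinates(self) -> np.ndarray:
        """(F, 3) coordinates for the voxel columns, in column order."""
        cols = self.columns_of_kind("voxel")
        return np.array([self.provenance[k].voxel for k in cols], dtype=int)


@dataclass
class GroundTruth:
    """Generative ground truth of a synthetic cohort (never fed to analyses).

    ``eloquent_weights`` is the planted per-voxel deficit weight map
    (nonnegative, exactly zero outside the planted blocks);
    ``true_acute_linear`` is the pre-noise lesion-load term of the acute
    severity link and ``true_chronic_linear`` the pre-noise linear predictor
    of the 3-month latent outcome (shrunken lesion term + age + reserve).
    """

    eloquent_weights: np.ndarray
    subject_reserve: np.ndarray
    true_acute_linear: np.ndarray
    true_chronic_linear: np.ndarray
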