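"""Synthetic lesion cohorts with planted ground truth.

The generator emulates an anterior-circulation ischaemic stroke cohort at toy
spatial scale: spatially clustered, contiguous lesions concentrated around one
territory centre per hemisphere; a right-skewed acute severity score (NIHSS at
24 h) driven by a planted "eloquent" voxel-weight map with a left-lateralized
language block and bilateral motor blocks; and 3-month outcomes (mRS, NIHSS)
driven by a shrunken copy of the lesion signal plus lesion-independent factors
(age, a latent reserve, noise).  Every draw flows from a single integer seed
through per-subject substreams, so re-running with the same config is
bit-identical.

Acute severity uses a saturating link ``NIHSS = round(42 * (1 - exp(-s/tau)))``
of the noisy lesion-load term ``s``: bounded on 0..42, monotone in lesion
load, and right-skewed for typical loads, which is the distributional shape
the analysis stage has to log-transform.  The 3-month mRS is obtained by
rank-binning the latent chronic score at fixed cumulative proportions whose
``mrs >= 2`` cut sits at a 43.5% poor-outcome rate, with median 1 and
IQR (0; 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GroundTruth,
    LesionCohort,
    Parcellation,
    Streamline,
    StreamlineAtlas,
    VoxelGrid,
)

__all__ = ["SimConfig", "generate_cohort", "generate_toy_atlas"]

# Cumulative proportions of mRS grades 0..6 (median 1, IQR 0-2; the >=2 cut
# corresponds to a 43.5% poor-outcome rate).
_MRS_CUMULATIVE = np.array([0.300, 0.565, 0.760, 0.870, 0.940, 0.980, 1.0])

# Age distribution: mean 67.4 y, SD 15.1 y, truncated to 18..95 y.
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 67.4, 15.1, 18.0, 95.0

# Lesion-load normalisation (see generate_cohort) and the latent shift that
# right-skews the 3-month severity score towards 0.
_LOAD_NORM = 32.0
_CHRONIC_OFFSET = 0.6


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults encode the emulated study conditions: 685 subjects, 54.5% of
    lesions left-hemispheric, acute severity median around 3 with an
    interquartile range of roughly 1-6, and a 3-month outcome in which
    lesion-independent variance (age, reserve, noise) dominates over the
    shrunken lesion signal.
    """

    n_subjects: int = 685
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    midline_x: int = 16
    n_regions: int = 12
    n_streamlines: int = 120
    lesion_size_range: tuple[int, int] = (15, 400)
    territory_center_left: tuple[int, int, int] | None = None
    territory_center_right: tuple[int, int, int] | None = None
    left_fraction: float = 0.545
    eloquent_weight_scale: float = 1.0
    acute_noise_sd: float = 0.35
    chronic_lesion_shrinkage: float = 0.5
    age_effect: float = 0.35
    reserve_sd: float = 0.6
    nihss_link_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid dimensions must each be >= 4")
        lo, hi = self.lesion_size_range
        if lo < 1 or lo > hi:
            raise ValueError("lesion_size_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.chronic_lesion_shrinkage <= 1.0):
            raise ValueError("chronic_lesion_shrinkage must lie in [0, 1]")
        if self.n_regions % 2 != 0:
            raise ValueError("n_regions must be even (split across hemispheres)")
        if self.acute_noise_sd < 0 or self.reserve_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.eloquent_weight_scale < 0:
            raise ValueError("eloquent_weight_scale must be nonnegative")
        nx, ny, nz = self.grid_shape
        if self.territory_center_left is None:
            object.__setattr__(
                self, "territory_center_left", (self.midline_x // 2, ny // 2, nz // 2)
            )
        if self.territory_center_right is None:
            object.__setattr__(
                self,
                "territory_center_right",
                (self.midline_x + max((nx - self.midline_x) // 2, 1), ny // 2, nz // 2),
            )

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=tuple(self.grid_shape), midline_x=self.midline_x)


# --------------------------------------------------------------------------
# eloquent weight map


def _eloquent_weight_map(config: SimConfig) -> np.ndarray:
    """Planted per-voxel deficit weights.

    A left-hemisphere "language" block around the left territory centre plus
    smaller bilateral "motor" blocks in the dorsal part of each hemisphere.
    Weights are positive inside the blocks and exactly zero elsewhere.
    """
    nx, ny, nz = config.grid_shape
    w = np.zeros(config.grid_shape, dtype=float)
    cxl, cyl, czl = config.territory_center_left
    cxr, cyr, czr = config.territory_center_right

    def block(center, half, value):
        x0, y0, z0 = center
        hx, hy, hz = half
        sl = (
            slice(max(x0 - hx, 0), min(x0 + hx + 1, nx)),
            slice(max(y0 - hy, 0), min(y0 + hy + 1, ny)),
            slice(max(z0 - hz, 0), min(z0 + hz + 1, nz)),
        )
        w[sl] = np.maximum(w[sl], value)

    # language block: left hemisphere only, centred on the left territory;
    # block extents scale with the grid so toy-sized grids keep the geometry
    lang_half = (max(nx // 6, 1), max(round(ny * 0.20), 1), max(nz // 4, 1))
    motor_half = (max(nx // 8, 1), max(ny // 6, 1), max(nz // 8, 1))
    block((cxl, cyl, czl), lang_half, 1.0)
    # motor blocks: bilateral, dorsal, smaller
    motor_z = min(czl + nz // 4, nz - 3)
    block((cxl, cyl, motor_z), motor_half, 1.0)
    block((cxr, cyr, motor_z), motor_half, 1.0)

    # clip to hemispheres: nothing on the midline column
    w[config.midline_x, :, :] = 0.0
    return w


# --------------------------------------------------------------------------
# lesion growth

_NEIGHBOURS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _hemisphere_bounds(config: SimConfig, side: int) -> tuple[int, int]:
    """Half-open x range of a hemisphere (-1 left, +1 right), midline excluded."""
    if side < 0:
        return 0, config.midline_x
    return config.midline_x + 1, config.grid_shape[0]


def _grow_lesion(
    rng: np.random.Generator, config: SimConfig, side: int, size: int
) -> np.ndarray:
    """Random-walk region growing from a territory-biased seed voxel.

    Returns a boolean mask of exactly `size` 6-connected voxels confined to
    one hemisphere.
    """
    nx, ny, nz = config.grid_shape
    x_lo, x_hi = _hemisphere_bounds(config, side)
    capacity = (x_hi - x_lo) * ny * nz
    if size > capacity:
        raise ValueError("lesion_size_exceeds_grid")
    center = (
        config.territory_center_left if side < 0 else config.territory_center_right
    )
    sds = (max((x_hi - x_lo) / 5.0, 1.0), ny / 6.0, nz / 6.0)
    while True:
        seed_voxel = np.round(rng.normal(center, sds)).astype(int)
        seed_voxel[0] = np.clip(seed_voxel[0], x_lo, x_hi - 1)
        seed_voxel[1] = np.clip(seed_voxel[1], 0, ny - 1)
        seed_voxel[2] = np.clip(seed_voxel[2], 0, nz - 1)
        break

    mask = np.zeros(config.grid_shape, dtype=bool)
    mask[tuple(seed_voxel)] = True
    frontier = [tuple(seed_voxel)]
    n_in = 1
    while n_in < size:
        # pick a random member of the frontier, try to add a random neighbour
        k = rng.integers(len(frontier))
        vx = np.asarray(frontier[k])
        order = rng.permutation(6)
        added = False
        for o in order:
            cand = vx + _NEIGHBOURS6[o]
            x, y, z = cand
            if not (x_lo <= x < x_hi and 0 <= y < ny and 0 <= z < nz):
                continue
            if mask[x, y, z]:
                continue
            mask[x, y, z] = True
            frontier.append((int(x), int(y), int(z)))
            n_in += 1
            added = True
            break
        if not added:
            # voxel fully surrounded: retire it from the frontier
            frontier.pop(k)
            if not frontier:  # cannot happen before capacity is reached
                raise RuntimeError("lesion growth stalled")  # pragma: no cover
    return mask


# --------------------------------------------------------------------------
# cohort generation


def _acute_link(s: np.ndarray, tau: float) -> np.ndarray:
    """Saturating severity link: 42 * (1 - exp(-s/tau)), s clipped below 0."""
    return 42.0 * (1.0 - np.exp(-np.clip(s, 0.0, None) / tau))


def generate_cohort(config: SimConfig) -> tuple[LesionCohort, GroundTruth]:
    """Generate a synthetic lesion cohort with known generative ground truth.

    Returns the cohort (masks + clinical table) and the :class:`GroundTruth`
    holding the planted weight map and the pre-noise linear predictors.  The
    clinical table columns are ``subject_id, age, hemisphere, lesion_volume,
    nihss_24h, nihss_3m, mrs_3m``; only ``age`` and the outcome columns are
    meant to be consumed by analyses.
    """
    grid = config.grid
    root = np.random.default_rng(config.seed)
    # independent child streams: subjects, clinical noise, atlas (unused here)
    subject_seeds = root.spawn(config.n_subjects)
    clin_rng = root.spawn(1)[0]

    base_weights = _eloquent_weight_map(config)
    weights = base_weights * config.eloquent_weight_scale

    sides = np.where(
        clin_rng.random(config.n_subjects) < config.left_fraction, -1, +1
    )
    lo, hi = config.lesion_size_range
    sizes = _skewed_sizes(clin_rng, config.n_subjects, lo, hi)

    masks = np.zeros((config.n_subjects, *config.grid_shape), dtype=bool)
    for i, sub_rng in enumerate(subject_seeds):
        masks[i] = _grow_lesion(sub_rng, config, int(sides[i]), int(sizes[i]))

    # lesion-load term of the acute link; the divisor puts the load on a
    # unit-ish scale independent of grid size (calibrated so the default
    # config yields an acute severity median near 3 with IQR roughly 1-6)
    raw_load = masks.reshape(config.n_subjects, -1) @ weights.ravel()
    denom = max(base_weights.sum() / _LOAD_NORM, 1e-12)
    s = raw_load / denom

    age = stats.truncnorm.rvs(
        (_AGE_LO - _AGE_MEAN) / _AGE_SD,
        (_AGE_HI - _AGE_MEAN) / _AGE_SD,
        loc=_AGE_MEAN,
        scale=_AGE_SD,
        size=config.n_subjects,
        random_state=clin_rng,
    )
    age_z = (age - _AGE_MEAN) / _AGE_SD

    eps_acute = clin_rng.normal(0.0, config.acute_noise_sd, config.n_subjects)
    nihss24 = np.clip(
        np.round(_acute_link(s + eps_acute, config.nihss_link_scale)), 0, 42
    ).astype(int)

    reserve = clin_rng.normal(0.0, config.reserve_sd, config.n_subjects)
    true_chronic = (
        config.chronic_lesion_shrinkage * s
        + config.age_effect * age_z
        - reserve
    )
    eps_chronic = clin_rng.normal(0.0, config.acute_noise_sd, config.n_subjects)
    latent_chronic = true_chronic + eps_chronic

    mrs = _rank_bin(latent_chronic, _MRS_CUMULATIVE)
    nihss3m = np.clip(
        np.round(
            _acute_link(latent_chronic - _CHRONIC_OFFSET, config.nihss_link_scale)
        ),
        0,
        42,
    ).astype(int)

    clinical = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(config.n_subjects)],
            "age": age,
            "hemisphere": np.where(sides < 0, "L", "R"),
            "lesion_volume": masks.reshape(config.n_subjects, -1).sum(axis=1),
            "nihss_24h": nihss24,
            "nihss_3m": nihss3m,
            "mrs_3m": mrs,
        }
    )
    cohort = LesionCohort(
        grid=grid,
        subject_ids=list(clinical["subject_id"]),
        masks=masks,
        clinical=clinical,
    )
    truth = GroundTruth(
        eloquent_weights=weights,
        subject_reserve=reserve,
        true_acute_linear=s,
        true_chronic_linear=true_chronic,
    )
    return cohort, truth


def _skewed_sizes(
    rng: np.random.Generator, n: int, lo: int, hi: int
) -> np.ndarray:
    """Right-skewed lesion sizes (log-uniform between the bounds)."""
    u = rng.random(n)
    sizes = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    return np.clip(np.round(sizes), lo, hi).astype(int)


def _rank_bin(latent: np.ndarray, cumulative: np.ndarray) -> np.ndarray:
    """Assign ordinal grades 0..len(cumulative)-1 by latent rank quantiles."""
    n = latent.size
    order = np.argsort(latent, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    edges = np.floor(cumulative * n).astype(int)
    grades = np.searchsorted(edges, ranks, side="right")
    return np.clip(grades, 0, len(cumulative) - 1)


# --------------------------------------------------------------------------
# toy atlas


def generate_toy_atlas(config: SimConfig) -> tuple[StreamlineAtlas, Parcellation]:
    """Generate a toy parcellation and streamline atlas on the config grid.

    The parcellation partitions a cortical shell (the outer rim of an
    ellipsoidal brain volume) into ``n_regions`` labels, half per hemisphere;
    streamlines are 26-connected voxel paths between random voxels of two
    labelled regions, and every region is an endpoint of at least one
    streamline.
    """
    if config.n_streamlines < config.n_regions:
        raise ValueError("atlas_underconnected")
    grid = config.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7151]))

    labels = _shell_parcellation(config)
    parcellation = Parcellation(grid=grid, labels=labels)
    n_regions = config.n_regions

    region_voxels = {
        r: np.argwhere(labels == r) for r in range(1, n_regions + 1)
    }
    for r, vox in region_voxels.items():
        if len(vox) == 0:  # pragma: no cover - geometry guarantees nonempty
            raise RuntimeError(f"empty region {r} in toy parcellation")

    streamlines: list[Streamline] = []
    for k in range(config.n_streamlines):
        if k < n_regions:
            i = k + 1  # guarantee coverage of every region
            j = int(rng.integers(1, n_regions + 1))
        else:
            i = int(rng.integers(1, n_regions + 1))
            j = int(rng.integers(1, n_regions + 1))
        a = region_voxels[i][rng.integers(len(region_voxels[i]))]
        b = region_voxels[j][rng.integers(len(region_voxels[j]))]
        path = _voxel_line(a, b)
        streamlines.append(Streamline(path=path, endpoints=(i, j)))
    return StreamlineAtlas(grid=grid, streamlines=streamlines), parcellation


def _shell_parcellation(config: SimConfig) -> np.ndarray:
    """Angular-sector labels on the outer rim of an ellipsoidal brain."""
    nx, ny, nz = config.grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    rho = np.sqrt(
        ((x - cx) / (nx / 2.0)) ** 2
        + ((y - cy) / (ny / 2.0)) ** 2
        + ((z - cz) / (nz / 2.0)) ** 2
    )
    shell = (rho <= 0.98) & (rho >= 0.60)
    hemi = np.sign(x - config.midline_x)
    shell &= hemi != 0  # midline voxels belong to neither hemisphere

    per_hemi = config.n_regions // 2
    theta = np.arctan2(z - cz, y - cy)  # angle in the coronal-axial plane
    sector = np.floor((theta + np.pi) / (2 * np.pi) * per_hemi).astype(int)
    sector = np.clip(sector, 0, per_hemi - 1)

    labels = np.zeros(config.grid_shape, dtype=int)
    labels[shell & (hemi < 0)] = sector[shell & (hemi < 0)] + 1
    labels[shell & (hemi > 0)] = sector[shell & (hemi > 0)] + 1 + per_hemi
    return labels


def _voxel_line(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """26-connected voxel path from a to b (dense line sampling, deduped)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_steps = int(np.ceil(np.abs(b - a).max())) * 4 + 1
    t = np.linspace(0.0, 1.0, n_steps)
    pts = np.round(a[None, :] + t[:, None] * (b - a)[None, :]).astype(int)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (np.abs(np.diff(pts, axis=0)).sum(axis=1)) > 0
    return pts[keep]
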