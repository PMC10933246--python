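"""Parametric synthetic label atlas.

The geometry is deliberately schematic — an ellipsoidal brain carved into
wedge-like lobes with spherical deep nuclei, a cerebellum, a brain stem, and
two external reference phantoms — so that simulation and analysis share one
native space and no registration stage is needed.  Axis convention:
x = left-right, y = anterior-posterior, z = inferior-superior, all in
fractional coordinates of the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field

#: atomic region labels (0 is background)
REGION_IDS = {
    "frontal": 1,
    "parietal": 2,
    "temporal": 3,
    "occipital": 4,
    "cerebellum": 5,
    "thalamus": 6,
    "caudate": 7,
    "putamen": 8,
    "brain_stem": 9,
    "phantom_low": 10,
    "phantom_high": 11,
}
BRAIN_REGIONS = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "cerebellum",
    "thalamus",
    "caudate",
    "putamen",
    "brain_stem",
)
PHANTOM_REGIONS = ("phantom_low", "phantom_high")
REQUIRED_REGIONS = BRAIN_REGIONS + PHANTOM_REGIONS


class Sphere(BaseModel):
    center: tuple[float, float, float]
    radius: float = Field(gt=0)


class AtlasGeometry(BaseModel):
    """Fractional-coordinate geometry of the synthetic head.

    Structures are resolved in a fixed order: deep structures claim voxels by
    smallest normalized distance, remaining brain voxels fall to the lobes by
    simple anterior/posterior/inferior rules.
    """

    brain_center: tuple[float, float, float] = (0.5, 0.5, 0.55)
    brain_semiaxes: tuple[float, float, float] = (0.36, 0.40, 0.34)
    cerebellum: Sphere = Sphere(center=(0.5, 0.77, 0.33), radius=0.13)
    brain_stem: Sphere = Sphere(center=(0.5, 0.58, 0.24), radius=0.09)
    thalamus: Sphere = Sphere(center=(0.5, 0.50, 0.52), radius=0.08)
    caudate: Sphere = Sphere(center=(0.42, 0.40, 0.56), radius=0.07)
    putamen: Sphere = Sphere(center=(0.62, 0.46, 0.50), radius=0.07)
    phantom_low: Sphere = Sphere(center=(0.10, 0.10, 0.12), radius=0.10)
    phantom_high: Sphere = Sphere(center=(0.90, 0.10, 0.12), radius=0.10)
    frontal_max_y: float = 0.40
    occipital_min_y: float = 0.68
    temporal_max_z: float = 0.45


@dataclass
class LabelAtlas:
    """Integer label volume with a region-name table and composites.

    Every non-background voxel carries exactly one atomic label; composite
    regions (currently ``whole_brain``) are unions of atomic labels used only
    at aggregation time.
    """

    labels: np.ndarray  # int volume
    region_names: dict[int, str]
    voxel_mm: tuple[float, float, float]
    composites: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"whole_brain": BRAIN_REGIONS}
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self._ids = {name: rid for rid, name in self.region_names.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_id(self, name: str) -> int:
        return self._ids[name]

    def region_mask(self, name: str) -> np.ndarray:
        if name in self.composites:
            return np.isin(self.labels, [self._ids[m] for m in self.composites[name]])
        return self.labels == self._ids[name]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.region_mask("whole_brain")

    @property
    def phantom_mask(self) -> np.ndarray:
        return np.isin(self.labels, [self._ids[m] for m in PHANTOM_REGIONS])

    def voxel_counts(self) -> dict[str, int]:
        return {name: int((self.labels == rid).sum()) for rid, name in self.region_names.items()}


def _voxel_centers(shape: tuple[int, int, int]) -> np.ndarray:
    """Fractional coordinates of voxel centers, shape (nx, ny, nz, 3)."""
    axes = [(np.arange(n) + 0.5) / n for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def make_atlas(
    grid_shape: tuple[int, int, int],
    geometry: AtlasGeometry | None = None,
    voxel_mm: tuple[float, float, float] | None = None,
) -> LabelAtlas:
    """Build the synthetic label atlas on ``grid_shape``.

    Raises ``ValueError`` if the grid is too small (< 6 per axis) or if the
    geometry cannot place every required region with at least one voxel.
    """
    if any(n < 6 for n in grid_shape):
        raise ValueError(f"grid {grid_shape} too small: need >= 6 voxels per axis")
    geo = geometry or AtlasGeometry()
    if voxel_mm is None:
        voxel_mm = tuple(240.0 / n for n in grid_shape)
    xyz = _voxel_centers(grid_shape)

    c = np.asarray(geo.brain_center)
    s = np.asarray(geo.brain_semiaxes)
    brain = np.sum(((xyz - c) / s) ** 2, axis=-1) <= 1.0

    labels = np.zeros(grid_shape, dtype=np.int16)

    # deep structures: claim brain voxels by smallest normalized distance < 1
    deep = ["cerebellum", "brain_stem", "thalamus", "caudate", "putamen"]
    ndist = np.stack(
        [
            np.linalg.norm(xyz - np.asarray(getattr(geo, name).center), axis=-1)
            / getattr(geo, name).radius
            for name in deep
        ],
        axis=-1,
    )
    best = np.argmin(ndist, axis=-1)
    inside = np.min(ndist, axis=-1) < 1.0
    for k, name in enumerate(deep):
        labels[brain & inside & (best == k)] = REGION_IDS[name]

    # lobes: remaining brain voxels by position rules
    rest = brain & (labels == 0)
    y, z = xyz[..., 1], xyz[..., 2]
    labels[rest & (y < geo.frontal_max_y)] = REGION_IDS["frontal"]
    rest = brain & (labels == 0)
    labels[rest & (y > geo.occipital_min_y) & (z >= geo.temporal_max_z)] = REGION_IDS["occipital"]
    rest = brain & (labels == 0)
    labels[rest & (z < geo.temporal_max_z)] = REGION_IDS["temporal"]
    labels[brain & (labels == 0)] = REGION_IDS["parietal"]

    # phantoms: spheres outside the brain
    for name in PHANTOM_REGIONS:
        sph = getattr(geo, name)
        dist = np.linalg.norm(xyz - np.asarray(sph.center), axis=-1)
        hit = (dist <= sph.radius) & ~brain
        if not hit.any():
            # snap to the nearest non-brain, unlabelled voxel
            dist_masked = np.where(~brain & (labels == 0), dist, np.inf)
            if not np.isfinite(dist_masked).any():
                raise ValueError(f"cannot place region {name!r}: no free voxel outside the brain")
            hit = dist_masked == dist_masked.min()
        labels[hit & (labels == 0)] = REGION_IDS[name]

    _ensure_all_regions(labels, brain, xyz, geo)

    region_names = {rid: name for name, rid in REGION_IDS.items()}
    return LabelAtlas(labels, region_names, voxel_mm)


def _ensure_all_regions(
    labels: np.ndarray, brain: np.ndarray, xyz: np.ndarray, geo: AtlasGeometry
) -> None:
    """Guarantee every required region holds >= 1 voxel, stealing from lobes."""
    lobe_ids = [REGION_IDS[n] for n in ("frontal", "parietal", "temporal", "occipital")]
    anchors = {
        "cerebellum": geo.cerebellum.center,
        "brain_stem": geo.brain_stem.center,
        "thalamus": geo.thalamus.center,
        "caudate": geo.caudate.center,
        "putamen": geo.putamen.center,
        "frontal": (0.5, 0.15, 0.6),
        "parietal": (0.5, 0.5, 0.85),
        "temporal": (0.2, 0.5, 0.4),
        "occipital": (0.5, 0.85, 0.6),
    }
    for name in BRAIN_REGIONS:
        rid = REGION_IDS[name]
        if (labels == rid).any():
            continue
        # nearest brain voxel currently held by a lobe with > 1 voxel
        donor = brain & np.isin(labels, [i for i in lobe_ids if (labels == i).sum() > 1 or i == rid])
        if not donor.any():
            raise ValueError(f"grid too small to place region {name!r}")
        dist = np.linalg.norm(xyz - np.asarray(anchors[name]), axis=-1)
        dist = np.where(donor, dist, np.inf)
        labels[np.unravel_index(np.argmin(dist), labels.shape)] = rid
    for name in REQUIRED_REGIONS:
        if not (labels == REGION_IDS[name]).any():
            raise ValueError(f"grid too small to place region {name!r}")
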