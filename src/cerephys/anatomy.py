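"""Quantitative anatomy on binary region masks.

Mirrors the standard image-based workflow for Nissl-stained cerebellar
sections: threshold the stain into a binary mask, count particles
(connected components) as cell nuclei, convert foreground pixel counts to
calibrated areas, and normalize nuclear counts per 50-μm unit of a
reference extent.  Region outlining and thickness measurements are manual
upstream steps; only their downstream arithmetic lives here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .types import InvalidSpecification

__all__ = [
    "RegionMask",
    "RegionMeasure",
    "count_particles",
    "region_area",
    "nuclear_density",
    "measure_region",
    "synthetic_disk_mask",
]

REGION_LABELS = ("fastigial", "interposed", "cortex", "other")


@dataclass(frozen=True)
class RegionMask:
    """Binary 2-D mask with physical pixel calibration (μm/px)."""

    mask: np.ndarray
    um_per_px: float
    label: str = "other"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", m)
        if self.um_per_px <= 0:
            raise InvalidSpecification("pixel size must be positive")
        if m.ndim != 2 or m.size == 0:
            raise InvalidSpecification("mask must be a nonempty 2-D grid")


@dataclass(frozen=True)
class RegionMeasure:
    area_um2: float
    particle_count: int
    density_per_50um: float | None


def count_particles(region: RegionMask, min_size_px: int = 1) -> int:
    """Number of 8-connected foreground components of at least ``min_size_px``."""
    lab = measure.label(region.mask, connectivity=2)
    if lab.max() == 0:
        return 0
    sizes = np.bincount(lab.ravel())[1:]
    return int((sizes >= min_size_px).sum())


def region_area(region: RegionMask) -> float:
    """Foreground area in μm²: pixel count × (μm/px)²."""
    return float(region.mask.sum()) * region.um_per_px**2


def nuclear_density(count: int, reference_extent_um: float) -> float:
    """Nuclei per 50-μm unit: ``count / (reference_extent_um / 50)``."""
    if reference_extent_um <= 0:
        raise InvalidSpecification("reference extent must be positive")
    return count / (reference_extent_um / 50.0)


def measure_region(region: RegionMask, min_size_px: int = 1,
                   reference_extent_um: float | None = None) -> RegionMeasure:
    n = count_particles(region, min_size_px)
    dens = None if reference_extent_um is None else nuclear_density(n, reference_extent_um)
    return RegionMeasure(area_um2=region_area(region), particle_count=n,
                         density_per_50um=dens)


def synthetic_disk_mask(n_disks: int, radius_px: float, shape: tuple[int, int],
                        um_per_px: float, seed: int, label: str = "other",
                        min_gap_px: float = 2.0) -> tuple[RegionMask, np.ndarray]:
    """Random non-overlapping disks: a ground-truth particle-count fixture.

    Returns (mask, centers).  Placement is rejection-sampled; raises if the
    requested packing cannot be achieved.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    r = radius_px
    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == n_disks:
            break
        c = (rng.uniform(r + 1, h - r - 1), rng.uniform(r + 1, w - r - 1))
        if all((c[0] - y) ** 2 + (c[1] - x) ** 2 > (2 * r + min_gap_px) ** 2
               for y, x in centers):
            centers.append(c)
    if len(centers) < n_disks:
        raise InvalidSpecification("could not place the requested disks")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for y, x in centers:
        mask |= (yy - y) ** 2 + (xx - x) ** 2 <= r**2
    return RegionMask(mask, um_per_px, label), np.asarray(centers)
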