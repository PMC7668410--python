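"""Regions of interest on voxel grids.

An ROI is an analytic shape (sphere, ellipsoid or box) specified in world
millimetres.  Voxel membership is centre-based: a voxel belongs to the ROI
iff its centre lies inside the shape, with voxel centres at
``(index + 0.5) * spacing`` (grid origin at the corner of voxel (0,0,0)).
No partial-voxel weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = ["ROI", "RoiError", "roi_mask", "jitter_rois", "load_rois", "save_rois"]


class RoiError(ValueError):
    """Raised when an ROI is invalid or intersects no voxel."""


_SHAPES = ("sphere", "ellipsoid", "box")


@dataclass(frozen=True)
class ROI:
    """An analytic region of interest in world millimetres.

    Parameters
    ----------
    region_label
        Semantic name of the region sampled (e.g. ``left_atrium``).
    shape
        One of ``sphere``, ``ellipsoid``, ``box``.  A sphere uses the first
        radius on all axes; a box spans ``center ± radii`` per axis.
    center
        (x, y, z) world coordinates of the centre in mm.
    radii
        Semi-axis lengths in mm, one per axis (a single value for spheres).
    """

    region_label: str
    shape: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise RoiError(f"unknown ROI shape {self.shape!r} for region {self.region_label!r}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if radii.size == 1:
            radii = np.repeat(radii, 3)
        if radii.size != 3:
            raise RoiError(f"ROI {self.region_label!r}: need 1 or 3 radii, got {radii.size}")
        if np.any(radii <= 0):
            raise RoiError(f"ROI {self.region_label!r}: radii must be > 0")
        object.__setattr__(self, "radii", tuple(radii))


def roi_mask(roi: ROI, grid_shape: Sequence[int], spacing: Sequence[float]):
    """Voxel membership of ``roi`` on a grid.

    Returns ``(slices, mask)`` where ``slices`` is a tuple of per-axis slices
    bounding the ROI and ``mask`` a boolean array of that bounding-box shape.
    Restricting to the bounding box keeps membership evaluation cheap on
    large grids.  Raises :class:`RoiError` if no voxel centre falls inside.
    """
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(roi.center, dtype=float)
    radii = np.asarray(roi.radii, dtype=float)

    lo = np.maximum(np.floor((center - radii) / spacing - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((center + radii) / spacing + 0.5).astype(int) + 1,
                    np.asarray(grid_shape, dtype=int))
    if np.any(hi <= lo):
        raise RoiError(f"ROI for region {roi.region_label!r} lies outside the grid")

    axes = [((np.arange(lo[k], hi[k]) + 0.5) * spacing[k] - center[k]) / radii[k]
            for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    if roi.shape == "box":
        mask = (np.abs(gx) <= 1) & (np.abs(gy) <= 1) & (np.abs(gz) <= 1)
    else:  # sphere / ellipsoid: unit ball in scaled coordinates
        mask = gx * gx + gy * gy + gz * gz <= 1.0
    if not mask.any():
        raise RoiError(f"ROI for region {roi.region_label!r} contains no voxel centre")
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi)), mask


def jitter_rois(rois: Iterable[ROI], sigma_mm: float, seed: int) -> list[ROI]:
    """Displace ROI centres by independent 3D Gaussians of SD ``sigma_mm`` per axis.

    Models interobserver placement variability.  Shapes and radii are
    unchanged; the same seed reproduces the same jittered set.
    """
    if sigma_mm < 0:
        raise RoiError("sigma_mm must be >= 0")
    rois = list(rois)
    if sigma_mm == 0:
        return rois
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, sigma_mm, size=(len(rois), 3))
    return [replace(r, center=tuple(np.asarray(r.center) + d)) for r, d in zip(rois, shifts)]


def save_rois(rois: Iterable[ROI], path) -> None:
    payload = [
        {"region_label": r.region_label, "shape": r.shape,
         "center": [float(c) for c in r.center], "radii": [float(x) for x in r.radii]}
        for r in rois
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_rois(path) -> list[ROI]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [ROI(d["region_label"], d["shape"], tuple(d["center"]), tuple(d["radii"]))
            for d in payload]
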