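"""Distance-graded white-matter seed regions around the hypometabolic PET ROI.

A 3x3x3 mm^3 volume of interest (VOI) is placed at the ROI voxel closest to
white matter, then dilated into surrounding WM at incremental distances
(default 3, 9 and 15 mm).  A mirrored contralateral VOI (reflection about
the sagittal midline — an automated stand-in for the manual contralateral
placement) is dilated the same way, yielding matched ipsilateral and
contralateral seed regions per distance.  Dilation is cumulative: the 9 mm
region contains the 3 mm region.  All placements are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .aimap import PETROI
from .volume import BinaryMask

__all__ = ["SeedSpec", "SeedRegion", "place_voi", "dilate_into_wm",
           "mirror_contralateral", "build_seed_regions"]


@dataclass
class SeedSpec:
    voi_edge: float = 3.0                      # mm, cube edge
    distances: Tuple[float, ...] = (3.0, 9.0, 15.0)  # mm, strictly increasing
    midline_world_x: float = 0.0
    mode: str = "cumulative"                   # "cumulative" | "shell"

    def __post_init__(self) -> None:
        if self.voi_edge <= 0:
            raise ValueError("VOI edge must be > 0")
        d = np.asarray(self.distances, dtype=float)
        if len(d) == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be positive and strictly increasing")
        if self.mode not in ("cumulative", "shell"):
            raise ValueError(f"unknown dilation mode {self.mode!r}")


@dataclass
class SeedRegion:
    mask: BinaryMask
    side: str                 # "ipsilateral" | "contralateral"
    distance: float           # mm
    source_voi_center: np.ndarray  # world mm

    @property
    def empty(self) -> bool:
        return not self.mask.data.any()


def _cube_mask(geometry: BinaryMask, center_world: np.ndarray,
               edge: float) -> np.ndarray:
    """Voxels whose centers lie within the axis-aligned world cube of the
    given edge centered at ``center_world``."""
    idx = np.indices(geometry.shape).reshape(3, -1).T
    world = geometry.index_to_world(idx)
    inside = (np.abs(world - np.asarray(center_world)) <= edge / 2.0 + 1e-9).all(axis=1)
    return inside.reshape(geometry.shape)


def place_voi(roi: PETROI, wm_mask: BinaryMask,
              spec: SeedSpec) -> Tuple[BinaryMask, np.ndarray]:
    """Place the VOI at the ROI voxel directly adjacent to the closest WM.

    The center is the ROI voxel minimizing Euclidean (world-mm) distance to
    the nearest WM voxel; ties are broken by distance to the ROI centroid,
    then by smallest linear voxel index.  Returns the VOI mask (cube of
    ``voi_edge``, clipped to the grid) and its center in world mm.
    """
    if roi.empty or not roi.mask.data.any():
        raise ValueError("cannot place VOI: PET ROI is empty")
    if not wm_mask.data.any():
        raise ValueError("cannot place VOI: WM mask is empty")
    spacing = wm_mask.spacing
    # distance of every voxel to the nearest WM voxel (0 inside WM)
    dist_to_wm = ndimage.distance_transform_edt(~wm_mask.data, sampling=spacing)
    roi_idx = np.argwhere(roi.mask.data)
    d = dist_to_wm[tuple(roi_idx.T)]
    centroid = roi_idx.mean(axis=0)
    cdist = np.linalg.norm((roi_idx - centroid) * spacing, axis=1)
    lin = np.ravel_multi_index(tuple(roi_idx.T), roi.mask.shape)
    order = np.lexsort((lin, np.round(cdist, 9), np.round(d, 9)))
    best = roi_idx[order[0]]
    center_world = roi.mask.index_to_world(best.astype(float))[0]
    voi = _cube_mask(wm_mask, center_world, spec.voi_edge)
    return wm_mask.like(voi), center_world


def dilate_into_wm(voi: BinaryMask, wm_mask: BinaryMask, distance: float,
                   side: str = "ipsilateral", center_world=None,
                   inner: float = 0.0) -> SeedRegion:
    """WM voxels within ``distance`` mm (Euclidean, world space) of the VOI.

    The distance field is the Euclidean distance transform from the VOI
    voxels (voxel-center to voxel-center).  Regions are nested in distance
    by construction.  ``inner`` > 0 selects the shell
    ``inner < d <= distance`` instead (sensitivity-analysis mode).
    An empty result is returned flagged, not raised (tracking is skipped
    for that distance).
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    if not voi.data.any():
        raise ValueError("VOI mask is empty")
    dist = ndimage.distance_transform_edt(~voi.data, sampling=voi.spacing)
    region = (dist <= distance + 1e-9) & wm_mask.data
    if inner > 0:
        region &= dist > inner + 1e-9
    if center_world is None:
        center_world = voi.index_to_world(np.argwhere(voi.data).mean(axis=0))[0]
    return SeedRegion(mask=wm_mask.like(region), side=side, distance=distance,
                      source_voi_center=np.asarray(center_world, dtype=float))


def mirror_contralateral(voi_center_world, wm_mask: BinaryMask,
                         spec: SeedSpec, snap_to_mask: BinaryMask = None) -> np.ndarray:
    """Reflect the VOI center about the sagittal midline x = midline.

    Automated stand-in for a manual homologous placement.  With
    ``snap_to_mask`` given, the reflected center snaps to the nearest voxel
    center of that mask (e.g. GM).  Raises if the reflected point falls off
    the grid.
    """
    c = np.asarray(voi_center_world, dtype=float).copy()
    c[0] = 2.0 * spec.midline_world_x - c[0]
    idx = wm_mask.world_to_index(c)[0]
    if np.any(np.rint(idx) < 0) or np.any(np.rint(idx) > np.asarray(wm_mask.shape) - 1):
        raise ValueError(f"reflected VOI center {c} is off-grid")
    if snap_to_mask is not None and snap_to_mask.data.any():
        cand = np.argwhere(snap_to_mask.data)
        world = snap_to_mask.index_to_world(cand.astype(float))
        c = world[np.argmin(np.linalg.norm(world - c, axis=1))]
    return c


def build_seed_regions(roi: PETROI, wm_mask: BinaryMask,
                       spec: SeedSpec) -> List[SeedRegion]:
    """Full seeding stage: VOI placement, mirroring, and dilation at every
    distance on both sides.  Returns 2 x len(distances) regions."""
    voi, center = place_voi(roi, wm_mask, spec)
    contra_center = mirror_contralateral(center, wm_mask, spec)
    contra_voi = wm_mask.like(_cube_mask(wm_mask, contra_center, spec.voi_edge))
    regions: List[SeedRegion] = []
    for dist_i, d in enumerate(spec.distances):
        inner = 0.0
        if spec.mode == "shell" and dist_i > 0:
            inner = float(spec.distances[dist_i - 1])
        regions.append(dilate_into_wm(voi, wm_mask, d, "ipsilateral",
                                      center, inner))
        regions.append(dilate_into_wm(contra_voi, wm_mask, d, "contralateral",
                                      contra_center, inner))
    return regions
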