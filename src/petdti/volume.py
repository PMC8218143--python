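"""Scalar 3-D volumes with world geometry, and the spatial primitives built on them.

Everything downstream (asymmetry mapping, seeding, tractography) works in a
single shared world space expressed in millimetres, RAS orientation, with a
4x4 voxel-index -> world affine carried on every volume.  Sagittal flipping,
symmetric-template construction, Gaussian smoothing, resampling and 3-D
connected components all live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "BinaryMask",
    "Component",
    "flip_sagittal",
    "make_symmetric_template",
    "gaussian_smooth",
    "resample",
    "connected_components",
]

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume3D:
    """A scalar 3-D grid with a voxel-index -> world-mm affine.

    The value units depend on the role of the volume: Bq/mL for raw PET
    activity, unitless for SUV / SUVr / tissue probability, percent for
    asymmetry-index maps, z-units for standardized maps.  Undefined voxels
    are represented as NaN.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 in each axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (norm of each affine column)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def world_extent_x(self) -> tuple:
        """Min/max world x over the eight grid-corner voxel centers."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)], dtype=float)
        xs = self.index_to_world(corners)[:, 0]
        return float(xs.min()), float(xs.max())

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume sharing this volume's geometry."""
        return Volume3D(np.asarray(data), self.affine.copy())

    # -- I/O ----------------------------------------------------------------

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32),
                                 self.affine), str(path))

    @classmethod
    def load(cls, path) -> "Volume3D":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)


@dataclass
class BinaryMask:
    """Boolean grid sharing a :class:`Volume3D`'s geometry.

    ``connectivity`` is the neighbourhood convention used when the mask is
    decomposed into connected components: 6 (faces), 18 (faces+edges) or
    26 (faces+edges+corners).
    """

    data: np.ndarray
    affine: np.ndarray
    connectivity: int = 26

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def index_to_world(self, idx):
        return Volume3D.index_to_world(self, idx)  # type: ignore[arg-type]

    def world_to_index(self, xyz):
        return Volume3D.world_to_index(self, xyz)  # type: ignore[arg-type]

    def like(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(data, dtype=bool), self.affine.copy(),
                          self.connectivity)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine),
                 str(path))

    @classmethod
    def load(cls, path, connectivity: int = 26) -> "BinaryMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()) > 0.5, img.affine, connectivity)


# ---------------------------------------------------------------------------
# sagittal reflection and the symmetric template


def _reflection_index_transform(vol: Volume3D, midline_world_x: float) -> np.ndarray:
    """4x4 index-space transform realising world reflection x -> 2m - x."""
    refl = np.eye(4)
    refl[0, 0] = -1.0
    refl[0, 3] = 2.0 * midline_world_x
    return np.linalg.inv(vol.affine) @ refl @ vol.affine


def _check_midline(vol: Volume3D, midline_world_x: float) -> None:
    lo, hi = vol.world_extent_x()
    if not (lo <= midline_world_x <= hi):
        raise ValueError(
            f"midline x={midline_world_x} mm outside volume world-x extent "
            f"[{lo}, {hi}] mm")


def default_midline(vol: Volume3D) -> float:
    """World x of the grid's central sagittal plane.

    On an even-dimension grid this falls between the two central slices, so
    voxel centers pair up exactly under the reflection and flipping is exact.
    """
    center_idx = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0
    return float(vol.index_to_world(center_idx)[0, 0])


def flip_sagittal(vol: Volume3D, midline_world_x: float, order: int = 1) -> Volume3D:
    """Reflect a volume about the world-space sagittal plane x = midline.

    World point (x, y, z) maps to (2*midline - x, y, z); the grid geometry is
    unchanged and values are resampled by trilinear interpolation where the
    reflected point is off-grid (exact where it lands on grid points, which
    is everywhere when the midline is grid-aligned).
    """
    _check_midline(vol, midline_world_x)
    t = _reflection_index_transform(vol, midline_world_x)
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float), t[:3, :3], offset=t[:3, 3],
        order=order, mode="constant", cval=0.0, prefilter=False)
    return vol.like(out)


def make_symmetric_template(vol: Volume3D, midline_world_x: float) -> Volume3D:
    """Mean of a volume and its sagittal mirror.

    The output is invariant under :func:`flip_sagittal` about the same
    midline (exactly so on a grid-aligned midline).
    """
    flipped = flip_sagittal(vol, midline_world_x)
    return vol.like((np.asarray(vol.data, dtype=float) + flipped.data) / 2.0)


# ---------------------------------------------------------------------------
# smoothing / resampling


def gaussian_smooth(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Gaussian smoothing with an isotropic world-space FWHM in mm.

    Anisotropic voxels are handled by a per-axis sigma of
    ``fwhm * FWHM_TO_SIGMA / spacing_axis`` voxels.  Boundary mode is
    'reflect' so compactly supported signals keep their total sum.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.like(np.asarray(vol.data, dtype=float).copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.spacing
    out = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float),
                                  sigma=sigma_vox, mode="reflect")
    return vol.like(out)


def resample(vol: Volume3D, target_spacing, order: int = 1) -> Volume3D:
    """Trilinear resampling onto a grid covering the same world extent.

    ``target_spacing`` is a scalar or a 3-vector in mm.  The new grid keeps
    the old grid's axis directions; its first voxel center sits half a new
    voxel in from the old grid's edge (edge = half an old voxel beyond the
    first old center), so world extent is preserved up to rounding of the
    voxel count.  Masks should be resampled with ``order=0``.
    """
    target_spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)).copy()
    if np.any(target_spacing <= 0):
        raise ValueError("target spacing must be > 0")
    old_spacing = vol.spacing
    directions = vol.affine[:3, :3] / old_spacing  # unit columns
    old_shape = np.asarray(vol.shape)
    new_shape = np.maximum(1, np.rint(old_shape * old_spacing / target_spacing).astype(int))

    new3 = directions * target_spacing
    # world position of the grid edge (half a voxel before the first center)
    edge = vol.affine[:3, 3] - vol.affine[:3, :3] @ np.full(3, 0.5)
    new_origin = edge + new3 @ np.full(3, 0.5)
    new_affine = np.eye(4)
    new_affine[:3, :3] = new3
    new_affine[:3, 3] = new_origin

    t = np.linalg.inv(vol.affine) @ new_affine
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float), t[:3, :3], offset=t[:3, 3],
        output_shape=tuple(new_shape), order=order, mode="nearest",
        prefilter=False)
    return Volume3D(out, new_affine)


# ---------------------------------------------------------------------------
# connected components


@dataclass
class Component:
    label: int
    size: int
    min_linear_index: int
    indices: np.ndarray = field(repr=False)  # (n, 3) voxel indices


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def connected_components(mask: BinaryMask) -> List[Component]:
    """Label a mask into maximal connected components.

    Components are returned sorted by voxel count descending; ties are broken
    by the smallest minimum linear (C-order) voxel index, so the ordering is
    deterministic.  An empty mask yields an empty list.
    """
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[mask.connectivity])
    labeled, n = ndimage.label(mask.data, structure=structure)
    comps: List[Component] = []
    if n == 0:
        return comps
    flat = labeled.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    # contiguous runs of each label in the flattened, label-sorted array
    boundaries = np.searchsorted(sorted_labels, np.arange(1, n + 2))
    shape = mask.shape
    for lab in range(1, n + 1):
        lin = order[boundaries[lab - 1]:boundaries[lab]]
        idx = np.column_stack(np.unravel_index(lin, shape))
        comps.append(Component(label=lab, size=lin.size,
                               min_linear_index=int(lin.min()), indices=idx))
    comps.sort(key=lambda c: (-c.size, c.min_linear_index))
    return comps
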