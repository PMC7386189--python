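"""Voxel grids, binary structure masks, and Euclidean distance machinery.

Everything downstream (feature extraction, dose synthesis, DVH metrics) is
anchored to a :class:`VoxelGrid`: a regular 3D lattice with physical spacing
in mm. The world coordinate of voxel index ``(i, j, k)`` is
``origin + index * spacing`` (voxel centers), and all distances in this
package are Euclidean distances between voxel centers, in mm.

The planning structures follow isotoxicity-style SBRT conventions for
abdominal targets: the planning target volume (PTV) is the gross tumor
volume (GTV) plus a 5 mm isotropic margin, the critical organs-at-risk
(OAR_CRIT, the nearby GI organs) are expanded by 5 mm into OAR_5mm, and the
optimization target PTV_OPT is the PTV with OAR_5mm carved out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "StructureSet",
    "GridMismatchError",
    "expand_mask",
    "derive_structure_set",
    "signed_distance_map",
    "interior_depth_map",
    "sphere_mask",
]

#: 6-connectivity structuring element used to define the mask surface.
_FACE_CONN = ndimage.generate_binary_structure(3, 1)


class GridMismatchError(ValueError):
    """Raised when masks or doses that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with physical spacing.

    Parameters
    ----------
    shape
        Voxel counts per axis; every component >= 1.
    spacing
        Voxel spacing in mm per axis; every component > 0. Default 3 mm
        isotropic (a typical dose-grid resolution).
    origin
        World position in mm of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("VoxelGrid is strictly three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def diagonal_mm(self) -> float:
        """Physical length of the grid bounding-box diagonal (finite upper
        bound on any center-to-center distance)."""
        extent = (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return float(np.linalg.norm(extent)) or max(self.spacing)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for an (N, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def all_centers(self) -> np.ndarray:
        """(n_voxels, 3) world coordinates of every voxel center, C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_centers(idx)


@dataclass
class StructureMask:
    """A binary structure defined on exactly one :class:`VoxelGrid`."""

    grid: VoxelGrid
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_cc(self) -> float:
        """Structure volume in cubic centimeters (voxel count x voxel volume)."""
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0

    def indices(self) -> np.ndarray:
        """(N, 3) integer indices of member voxels, C order."""
        return np.argwhere(self.voxels)

    def same_grid(self, other: "StructureMask") -> bool:
        return self.grid == other.grid


@dataclass
class StructureSet:
    """The five planning structures of an isotoxicity abdominal plan.

    Invariants (validated on construction): gtv ⊆ ptv, oar_crit ⊆ oar_5mm,
    ptv_opt = ptv AND NOT oar_5mm, and all masks share one grid.
    """

    gtv: StructureMask
    ptv: StructureMask
    oar_crit: StructureMask
    oar_5mm: StructureMask
    ptv_opt: StructureMask

    def __post_init__(self) -> None:
        grid = self.gtv.grid
        for name in ("ptv", "oar_crit", "oar_5mm", "ptv_opt"):
            if getattr(self, name).grid != grid:
                raise GridMismatchError(f"structure '{name}' not on the GTV grid")
        if np.any(self.gtv.voxels & ~self.ptv.voxels):
            raise ValueError("invariant violated: GTV must be a subset of PTV")
        if np.any(self.oar_crit.voxels & ~self.oar_5mm.voxels):
            raise ValueError("invariant violated: OAR_CRIT must be a subset of OAR_5mm")
        if np.any(self.ptv_opt.voxels != (self.ptv.voxels & ~self.oar_5mm.voxels)):
            raise ValueError("invariant violated: PTV_OPT must equal PTV minus OAR_5mm")

    @property
    def grid(self) -> VoxelGrid:
        return self.gtv.grid


def expand_mask(mask: StructureMask, margin: float) -> StructureMask:
    """Isotropic expansion of a mask by ``margin`` mm.

    A voxel belongs to the expansion iff its center lies within ``margin``
    (Euclidean, inclusive) of the center of some voxel in the input mask.
    The result is always a superset of the input; ``margin == 0`` returns an
    identical copy.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if mask.is_empty or margin == 0:
        return StructureMask(mask.grid, mask.voxels.copy())
    # EDT of the complement = distance from each voxel center to the nearest
    # mask voxel center.
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)
    return StructureMask(mask.grid, dist <= margin)


def derive_structure_set(
    gtv: StructureMask, oar_crit: StructureMask, margin: float = 5.0
) -> StructureSet:
    """Derive the full planning structure set from GTV and OAR_CRIT.

    PTV = GTV + ``margin`` mm isotropic; OAR_5mm = OAR_CRIT + ``margin`` mm
    isotropic; PTV_OPT = PTV AND NOT OAR_5mm. When the OAR abuts or overlaps
    the target, part (or all) of the GTV may fall outside PTV_OPT — this is
    the expected isotoxicity situation, not an error.
    """
    if gtv.grid != oar_crit.grid:
        raise GridMismatchError("GTV and OAR_CRIT must share a grid")
    ptv = expand_mask(gtv, margin)
    oar_5mm = expand_mask(oar_crit, margin)
    ptv_opt = StructureMask(gtv.grid, ptv.voxels & ~oar_5mm.voxels)
    return StructureSet(gtv=gtv, ptv=ptv, oar_crit=oar_crit, oar_5mm=oar_5mm, ptv_opt=ptv_opt)


def _surface(voxels: np.ndarray) -> np.ndarray:
    """Mask voxels 6-connected to background (outside the grid counts as
    background)."""
    eroded = ndimage.binary_erosion(voxels, structure=_FACE_CONN, border_value=0)
    return voxels & ~eroded


def signed_distance_map(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance (mm) from every voxel center to the mask
    surface.

    The surface is the set of mask voxels 6-connected to background. The
    magnitude is the distance to the nearest surface voxel center; the sign
    is negative for voxels inside the mask and positive outside, so a
    negative value at a tumor voxel means overlap with the structure.
    Surface voxels themselves are at distance 0. An empty mask yields +inf
    everywhere (nothing is ever "inside"), which downstream clamping turns
    into the capped / positive-part feature values naturally.
    """
    if mask.is_empty:
        return np.full(mask.grid.shape, np.inf)
    surf = _surface(mask.voxels)
    dist = ndimage.distance_transform_edt(~surf, sampling=mask.grid.spacing)
    return np.where(mask.voxels, -dist, dist)


def interior_depth_map(mask: StructureMask) -> np.ndarray:
    """Unsigned distance (mm) to the mask surface for voxels inside the
    mask; 0 outside. Errors on an empty mask."""
    if mask.is_empty:
        raise ValueError("interior_depth_map requires a non-empty mask")
    surf = _surface(mask.voxels)
    dist = ndimage.distance_transform_edt(~surf, sampling=mask.grid.spacing)
    return np.where(mask.voxels, dist, 0.0)


def sphere_mask(grid: VoxelGrid, center_mm, radius_mm: float) -> StructureMask:
    """Voxelized sphere: voxels whose center lies within ``radius_mm`` of
    ``center_mm`` (world coordinates, inclusive)."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    coords = [
        grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    c = np.asarray(center_mm, dtype=float)
    d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
    return StructureMask(grid, d2 <= radius_mm**2)
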