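"""Per-voxel geometric input variables for the dose prediction network.

For every voxel inside the GTV, sixteen variables describe the local and
global relationship between the target and the nearby organs-at-risk. They
fall into four families:

* local OAR crowding — the percentage of grid voxels within 5/10/15/20 mm
  of the voxel that belong to OAR_5mm (variables 1-4);
* whole-plan context — the percentage of the GTV overlapped by OAR_5mm and
  the maximum centroid-to-surface radius of the GTV (variables 5 and 7,
  constant across a plan's voxels);
* target-internal geometry — distance to the GTV centroid, depth below the
  GTV surface and its square root (variables 6, 8, 9);
* signed surface distances — minimum distance to the OAR_5mm, PTV_OPT and
  (OAR_5mm − OAR_CRIT) shell surfaces, split into their non-negative and
  non-positive parts (a negative value means the voxel overlaps that
  structure), plus a signed square root for OAR_5mm (variables 10-16). The
  non-negative OAR_5mm distance saturates at 16 mm: beyond that range its
  correlation with dose is flat, so larger distances carry no extra
  information.

The column order is a frozen contract (`FEATURE_NAMES`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .geometry import (
    StructureMask,
    StructureSet,
    interior_depth_map,
    signed_distance_map,
)

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_DESCRIPTIONS",
    "OAR_DISTANCE_CAP_MM",
    "FeatureMatrix",
    "neighborhood_occupancy",
    "compute_voxel_features",
]

#: Saturation value (mm) for the non-negative min-distance-to-OAR_5mm input.
OAR_DISTANCE_CAP_MM = 16.0

#: Frozen column order of the feature matrix.
FEATURE_NAMES = tuple(f"f{i:02d}" for i in range(1, 17))

FEATURE_DESCRIPTIONS = {
    "f01": "% of voxels within 5 mm occupied by OAR_5mm",
    "f02": "% of voxels within 10 mm occupied by OAR_5mm",
    "f03": "% of voxels within 15 mm occupied by OAR_5mm",
    "f04": "% of voxels within 20 mm occupied by OAR_5mm",
    "f05": "% of GTV occupied by OAR_5mm (plan constant)",
    "f06": "distance to GTV centroid (mm)",
    "f07": "max distance GTV centroid to GTV surface (mm, plan constant)",
    "f08": "min distance to GTV surface (mm)",
    "f09": "sqrt of min distance to GTV surface",
    "f10": "min distance to OAR_5mm, >=0 part, capped at 16 mm",
    "f11": "min distance to OAR_5mm, <=0 part",
    "f12": "signed sqrt of min distance to OAR_5mm",
    "f13": "min distance to PTV_OPT, >=0 part",
    "f14": "min distance to PTV_OPT, <=0 part",
    "f15": "min distance to (OAR_5mm - OAR_CRIT) shell, >=0 part",
    "f16": "min distance to (OAR_5mm - OAR_CRIT) shell, <=0 part",
}


@dataclass
class FeatureMatrix:
    """Per-GTV-voxel feature rows for one plan.

    ``values`` has one row per GTV voxel and exactly 16 columns in the
    :data:`FEATURE_NAMES` order; ``voxel_indices`` holds the (i, j, k) grid
    index of each row.
    """

    plan_id: str
    voxel_indices: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns, "
                f"got shape {self.values.shape}"
            )
        if self.voxel_indices.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_indices must be (n_rows, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "plan_id", self.plan_id)
        for axis, name in enumerate(("i", "j", "k")):
            df.insert(1 + axis, name, self.voxel_indices[:, axis])
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        plan_ids = df["plan_id"].unique()
        if len(plan_ids) != 1:
            raise ValueError("one FeatureMatrix per plan; filter the frame first")
        return cls(
            plan_id=str(plan_ids[0]),
            voxel_indices=df[["i", "j", "k"]].to_numpy(),
            values=df[list(FEATURE_NAMES)].to_numpy(),
        )


def _ball_footprint(spacing, radius_mm: float) -> np.ndarray:
    """Boolean footprint of lattice offsets with ||offset * spacing|| <= radius."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    return dx**2 + dy**2 + dz**2 <= radius_mm**2


def neighborhood_occupancy(mask: StructureMask, radius_mm: float) -> np.ndarray:
    """Percentage (0-100) of grid voxels within ``radius_mm`` of each voxel
    center that belong to ``mask``.

    The neighborhood is a Euclidean ball over voxel centers (the center
    voxel included). At grid edges only in-grid voxels enter the count, so
    edge values are not diluted by out-of-grid padding.
    """
    if radius_mm < min(mask.grid.spacing):
        raise ValueError(
            f"radius {radius_mm} mm is below the minimum spacing "
            f"{min(mask.grid.spacing)} mm: the neighborhood holds no neighbors"
        )
    foot = _ball_footprint(mask.grid.spacing, radius_mm).astype(float)
    # FFT convolution then rounding recovers exact integer counts.
    hits = signal.fftconvolve(mask.voxels.astype(float), foot, mode="same")
    total = signal.fftconvolve(np.ones(mask.grid.shape), foot, mode="same")
    hits = np.rint(hits)
    total = np.rint(total)
    return 100.0 * hits / total


def _finite(sd: np.ndarray, bound: float) -> np.ndarray:
    """Clamp a signed distance map into [-bound, bound] so empty-structure
    sentinels (+inf) become a finite 'far away' value."""
    return np.clip(sd, -bound, bound)


def compute_voxel_features(structs: StructureSet, plan_id: str = "") -> FeatureMatrix:
    """Compute the 16 input variables for every GTV voxel of a plan."""
    gtv = structs.gtv
    if gtv.is_empty:
        raise ValueError("cannot compute features for an empty GTV")
    grid = structs.grid
    idx = gtv.indices()
    centers = grid.voxel_centers(idx)
    rows = tuple(idx.T)
    far = grid.diagonal_mm

    # Variables 1-4: OAR_5mm occupancy within 5/10/15/20 mm.
    occ = [
        neighborhood_occupancy(structs.oar_5mm, r)[rows] for r in (5.0, 10.0, 15.0, 20.0)
    ]

    # Variable 5: % of GTV overlapped by OAR_5mm (plan constant).
    overlap_pct = 100.0 * np.sum(gtv.voxels & structs.oar_5mm.voxels) / gtv.n_voxels

    # Variables 6-9: GTV-internal geometry.
    centroid = centers.mean(axis=0)
    dist_centroid = np.linalg.norm(centers - centroid, axis=1)
    depth_map = interior_depth_map(gtv)
    depth = depth_map[rows]
    surface_rows = depth <= 0.0  # surface voxels have zero depth
    if not surface_rows.any():  # pragma: no cover - cannot happen on a finite grid
        surface_rows = np.ones_like(surface_rows)
    max_radius = float(dist_centroid[surface_rows].max())

    # Variables 10-16: signed surface distances, split by sign.
    d_oar5 = _finite(signed_distance_map(structs.oar_5mm)[rows], far)
    d_ptvopt = _finite(signed_distance_map(structs.ptv_opt)[rows], far)
    shell = StructureMask(grid, structs.oar_5mm.voxels & ~structs.oar_crit.voxels)
    d_shell = _finite(signed_distance_map(shell)[rows], far)

    values = np.column_stack(
        [
            occ[0],
            occ[1],
            occ[2],
            occ[3],
            np.full(len(idx), overlap_pct),
            dist_centroid,
            np.full(len(idx), max_radius),
            depth,
            np.sqrt(depth),
            np.clip(d_oar5, 0.0, OAR_DISTANCE_CAP_MM),
            np.minimum(d_oar5, 0.0),
            np.sign(d_oar5) * np.sqrt(np.abs(d_oar5)),
            np.maximum(d_ptvopt, 0.0),
            np.minimum(d_ptvopt, 0.0),
            np.maximum(d_shell, 0.0),
            np.minimum(d_shell, 0.0),
        ]
    )
    return FeatureMatrix(plan_id=plan_id, voxel_indices=idx, values=values)
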