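"""Independent brute-force oracles for the geometric machinery.

Everything here is written with plain numpy pairwise enumeration — no
scipy.ndimage, no FFTs, no reuse of the package's distance code — so the
package implementation and these oracles can only agree if both are right.
Intended for grids up to ~20^3.
"""

from __future__ import annotations

import numpy as np

OAR_CAP_MM = 16.0


def centers(shape, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(n_voxels, 3) voxel-center world coordinates, C order."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return np.asarray(origin) + idx * np.asarray(spacing)


def surface_voxels(vox: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-neighbor in background (outside the grid counts
    as background)."""
    padded = np.pad(vox, 1, constant_values=False)
    out = np.zeros_like(vox)
    for axis in range(3):
        for shift in (1, -1):
            nb = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            out |= vox & ~nb
    return out


def min_dist_to_set(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to the target point set."""
    if targets.size == 0:
        return np.full(len(points), np.inf)
    out = np.empty(len(points))
    for start in range(0, len(points), 512):
        chunk = points[start : start + 512]
        d2 = ((chunk[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
        out[start : start + 512] = np.sqrt(d2.min(axis=1))
    return out


def brute_expand(vox: np.ndarray, spacing, margin: float) -> np.ndarray:
    """Expansion by center-to-center distance <= margin (inclusive)."""
    shape = vox.shape
    all_c = centers(shape, spacing)
    mask_c = all_c[vox.ravel()]
    d = min_dist_to_set(all_c, mask_c)
    return (d <= margin).reshape(shape)


def brute_expand_offsets(vox: np.ndarray, spacing, margin: float) -> np.ndarray:
    """Expansion oracle by direct lattice-offset enumeration: OR of the mask
    shifted by every integer offset with ||offset * spacing|| <= margin.
    Equivalent to `brute_expand` but usable on larger grids."""
    spacing = np.asarray(spacing, dtype=float)
    half = [int(np.floor(margin / s)) for s in spacing]
    out = np.zeros_like(vox)
    for dx in range(-half[0], half[0] + 1):
        for dy in range(-half[1], half[1] + 1):
            for dz in range(-half[2], half[2] + 1):
                off = np.array([dx, dy, dz]) * spacing
                if off @ off > margin**2:
                    continue
                shifted = vox
                for axis, d in enumerate((dx, dy, dz)):
                    shifted = _shift(shifted, d, axis)
                out |= shifted
    return out


def _shift(a: np.ndarray, d: int, axis: int) -> np.ndarray:
    """Shift without wraparound, padding with False."""
    if d == 0:
        return a
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if d > 0:
        src[axis], dst[axis] = slice(0, a.shape[axis] - d), slice(d, None)
    else:
        src[axis], dst[axis] = slice(-d, None), slice(0, a.shape[axis] + d)
    out[tuple(dst)] = a[tuple(src)]
    return out


def brute_signed_distance(vox: np.ndarray, spacing) -> np.ndarray:
    """Signed distance to the nearest surface-voxel center; negative inside."""
    shape = vox.shape
    if not vox.any():
        return np.full(shape, np.inf)
    surf_c = centers(shape, spacing)[surface_voxels(vox).ravel()]
    d = min_dist_to_set(centers(shape, spacing), surf_c).reshape(shape)
    return np.where(vox, -d, d)


def brute_occupancy(vox: np.ndarray, spacing, radius: float) -> np.ndarray:
    """% of in-grid voxels within `radius` of each voxel center that are in
    the mask."""
    shape = vox.shape
    all_c = centers(shape, spacing)
    flat = vox.ravel()
    out = np.empty(flat.size)
    for start in range(0, flat.size, 256):
        chunk = all_c[start : start + 256]
        near = ((chunk[:, None, :] - all_c[None, :, :]) ** 2).sum(axis=2) <= radius**2
        out[start : start + 256] = (
            100.0 * (near & flat).sum(axis=1) / near.sum(axis=1)
        )
    return out.reshape(shape)


def brute_feature_matrix(gtv: np.ndarray, oar_crit: np.ndarray, spacing, margin=5.0):
    """All 16 per-GTV-voxel variables, from scratch.

    Returns (voxel_indices, values) with the same frozen column order as
    the package. Distances to empty structures clamp at the grid diagonal.
    """
    shape = gtv.shape
    spacing = np.asarray(spacing, dtype=float)
    diag = float(np.linalg.norm((np.asarray(shape) - 1) * spacing)) or spacing.max()

    ptv = brute_expand(gtv, spacing, margin)
    oar5 = brute_expand(oar_crit, spacing, margin)
    ptv_opt = ptv & ~oar5
    shell = oar5 & ~oar_crit

    idx = np.argwhere(gtv)
    pts = idx.astype(float) * spacing
    rows = tuple(idx.T)

    occ = [brute_occupancy(oar5, spacing, r)[rows] for r in (5.0, 10.0, 15.0, 20.0)]
    overlap = 100.0 * np.count_nonzero(gtv & oar5) / np.count_nonzero(gtv)

    centroid = pts.mean(axis=0)
    d_centroid = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
    depth = -brute_signed_distance(gtv, spacing)[rows]  # >= 0 inside
    on_surface = depth <= 0
    max_radius = d_centroid[on_surface].max()

    def signed(vox_struct):
        d = brute_signed_distance(vox_struct, spacing)[rows]
        return np.clip(d, -diag, diag)

    d_oar5 = signed(oar5)
    d_ptvopt = signed(ptv_opt)
    d_shell = signed(shell)

    values = np.column_stack(
        [
            occ[0], occ[1], occ[2], occ[3],
            np.full(len(idx), overlap),
            d_centroid,
            np.full(len(idx), max_radius),
            depth,
            np.sqrt(depth),
            np.clip(d_oar5, 0.0, OAR_CAP_MM),
            np.minimum(d_oar5, 0.0),
            np.sign(d_oar5) * np.sqrt(np.abs(d_oar5)),
            np.maximum(d_ptvopt, 0.0),
            np.minimum(d_ptvopt, 0.0),
            np.maximum(d_shell, 0.0),
            np.minimum(d_shell, 0.0),
        ]
    )
    return idx, values
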