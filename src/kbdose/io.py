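"""NIfTI volume I/O, cohort manifests, and run provenance.

Volumes are stored one file per structure/dose as NIfTI with a diagonal
affine (spacing on the diagonal, origin in the translation column); a JSON
sidecar names the structure role. A cohort manifest is a CSV with one row
per plan pointing at the GTV, OAR_CRIT and dose volumes; derived structures
(PTV, OAR_5mm, PTV_OPT) are re-derived on load so manifests stay small and
internally consistent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dosimetry import DoseGrid
from .geometry import GridMismatchError, StructureMask, VoxelGrid, derive_structure_set
from .synthetic import RX_GY, Plan

__all__ = [
    "write_volume",
    "read_mask",
    "read_dose",
    "write_cohort",
    "read_cohort",
    "config_hash",
    "write_run_log",
]

MANIFEST_COLUMNS = [
    "plan_id",
    "patient_id",
    "plan_type",
    "protocol",
    "rx_gy",
    "gtv_path",
    "oar_crit_path",
    "dose_path",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(shape, affine) -> VoxelGrid:
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("affine must encode positive spacing")
    return VoxelGrid(tuple(shape), tuple(spacing), tuple(affine[:3, 3]))


def write_volume(path, obj, role: str | None = None) -> None:
    """Write a StructureMask (as 0/1) or DoseGrid (Gy) to NIfTI, with an
    optional JSON sidecar naming the structure role."""
    path = Path(path)
    if isinstance(obj, StructureMask):
        data = obj.voxels.astype(np.uint8)
        grid = obj.grid
    elif isinstance(obj, DoseGrid):
        data = obj.dose.astype(np.float64)
        grid = obj.grid
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    nib.save(nib.Nifti1Image(data, _affine(grid)), str(path))
    if role is not None:
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz/.nii
        Path(str(sidecar) + ".json").write_text(json.dumps({"role": role}, indent=1))


def _load(path) -> tuple[np.ndarray, VoxelGrid]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data, _grid_from_affine(data.shape, img.affine)


def read_mask(path) -> StructureMask:
    """Read a binary structure (values binarized at > 0.5)."""
    data, grid = _load(path)
    return StructureMask(grid, data > 0.5)


def read_dose(path, rx: float) -> DoseGrid:
    data, grid = _load(path)
    return DoseGrid(grid=grid, dose=data, rx=rx)


def write_cohort(plans: list[Plan], out_dir) -> Path:
    """Write all cohort volumes plus a manifest CSV; returns the manifest
    path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for plan in plans:
        base = out_dir / plan.plan_id
        gtv_path = f"{base}_gtv.nii.gz"
        oar_path = f"{base}_oar_crit.nii.gz"
        dose_path = f"{base}_dose.nii.gz"
        write_volume(gtv_path, plan.structs.gtv, role="GTV")
        write_volume(oar_path, plan.structs.oar_crit, role="OAR_CRIT")
        write_volume(dose_path, plan.dose, role="DOSE")
        rows.append(
            {
                "plan_id": plan.plan_id,
                "patient_id": plan.patient_id,
                "plan_type": plan.plan_type,
                "protocol": plan.protocol,
                "rx_gy": plan.rx,
                "gtv_path": Path(gtv_path).name,
                "oar_crit_path": Path(oar_path).name,
                "dose_path": Path(dose_path).name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path, margin: float = 5.0) -> list[Plan]:
    """Load a cohort from a manifest CSV, re-deriving PTV / OAR_5mm /
    PTV_OPT from the stored GTV and OAR_CRIT."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    root = manifest_path.parent
    plans = []
    for _, row in df.iterrows():
        gtv = read_mask(root / row["gtv_path"])
        oar = read_mask(root / row["oar_crit_path"])
        if gtv.grid != oar.grid:
            raise GridMismatchError(
                f"plan {row['plan_id']}: GTV and OAR_CRIT grids differ"
            )
        rx = float(row["rx_gy"])
        expected_rx = RX_GY.get(str(row["protocol"]))
        if expected_rx is not None and abs(rx - expected_rx) > 1e-6:
            raise ValueError(
                f"plan {row['plan_id']}: rx {rx} inconsistent with protocol "
                f"{row['protocol']}"
            )
        dose = read_dose(root / row["dose_path"], rx=rx)
        if dose.grid != gtv.grid:
            raise GridMismatchError(f"plan {row['plan_id']}: dose grid differs")
        plans.append(
            Plan(
                plan_id=str(row["plan_id"]),
                patient_id=str(row["patient_id"]),
                plan_type=str(row["plan_type"]),
                protocol=str(row["protocol"]),
                structs=derive_structure_set(gtv, oar, margin=margin),
                dose=dose,
            )
        )
    return plans


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config, for provenance."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_run_log(out_dir, seed: int, config: dict, extra: dict | None = None) -> Path:
    """Write a run log (seed, config + hash, package version) next to the
    outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "kbdose_version": __version__,
    }
    if extra:
        doc.update(extra)
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(doc, indent=1, default=str))
    return path
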