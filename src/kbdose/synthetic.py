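"""Seeded phantom cohorts: abdominal-style targets, adjacent GI organs, and
isotoxicity-shaped dose distributions with known ground truth.

The generator emulates the kind of cohort an adaptive MR-guided program
accumulates: per patient, a blob-perturbed ellipsoidal GTV with a critical
OAR sitting near (sometimes overlapping) the PTV; one "simulation" plan plus
adapted plans in which the OAR has shifted while the GTV is unchanged (the
common case clinically). The dose model encodes isotoxicity planning: the
normalized dose floor ``c`` is the OAR constraint fraction (36/50 for SBRT,
50/67.5 for hypofractionation), and dose ramps linearly from ``c`` at the
OAR_5mm surface up to a plateau ``h`` (default 105% of Rx) over a falloff
range ``F`` (default 16 mm):

    g(v) = c + (h - c) * clip(d_OAR5mm(v), 0, F) / F

where d_OAR5mm is the signed distance to the OAR_5mm surface. Inside
OAR_5mm (d <= 0) the dose sits at the constraint floor ``c``, so a voxel on
the OAR_CRIT surface receives exactly the constraint dose. Delivered dose
adds smooth correlated heterogeneity noise and occasional Gaussian
hotspots, clipped to 150% of Rx; ``g`` itself is retained as the per-voxel
ground truth that a dose prediction model should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._rand import child_rng, child_seed
from .dosimetry import DoseGrid
from .geometry import (
    StructureMask,
    StructureSet,
    VoxelGrid,
    derive_structure_set,
    signed_distance_map,
)

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "GenerationError",
    "Plan",
    "generate_phantom",
    "synth_dose",
    "generate_cohort",
    "degrade_plan",
]

RX_GY = {"SBRT": 50.0, "HYP": 67.5}
CONSTRAINT_GY = {"SBRT": 36.0, "HYP": 50.0}


class GenerationError(RuntimeError):
    """Raised when no feasible phantom geometry is found within the retry
    budget."""


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the synthetic cohort.

    Geometry: GTV radii 10-25 mm (≈4-65 cc, typical abdominal targets) with
    a smooth radial perturbation; the OAR surface sits within
    ``oar_offset_mm`` of the GTV surface — negative offsets produce
    PTV/OAR_5mm overlap with the GTV, the hallmark isotoxicity geometry.
    Dose: constraint fraction per protocol (None = derived from the
    protocol's constraint dose), 105% plateau, 16 mm falloff, 3% Rx smooth
    noise with 9 mm correlation length; an occasional (10% of plans)
    localized hotspot bump (5 mm sigma, peak up to the 150% Rx limit).
    Cohort:
    one simulation plan plus adapted plans per patient; ~5/53 of patients
    are hypofractionated, as in an abdominal SBRT service.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 3.0
    gtv_radius_mm: tuple[float, float] = (10.0, 25.0)
    irregularity: float = 0.15
    oar_radius_mm: tuple[float, float] = (15.0, 30.0)
    oar_offset_mm: tuple[float, float] = (-4.0, 8.0)
    constraint_fraction: float | None = None
    hot_fraction: float = 1.05
    falloff_mm: float = 16.0
    noise_amplitude: float = 0.03
    noise_corr_mm: float = 9.0
    hotspot_prob: float = 0.1
    hotspot_sigma_mm: float = 5.0
    adapt_shift_mm: float = 4.0
    n_patients: int = 20
    plans_per_patient: int = 3
    hyp_patient_fraction: float = 5.0 / 53.0
    margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.constraint_fraction is not None and not (
            0 < self.constraint_fraction < 1
        ):
            raise ValueError("constraint_fraction must lie in (0, 1)")
        if not 1 <= self.hot_fraction <= 1.5:
            raise ValueError("hot_fraction must lie in [1, 1.5]")
        if self.falloff_mm <= 0:
            raise ValueError("falloff_mm must be positive")
        if self.noise_amplitude < 0 or self.hotspot_prob < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, (self.spacing_mm,) * 3)

    def constraint_for(self, protocol: str) -> float:
        if self.constraint_fraction is not None:
            return self.constraint_fraction
        return CONSTRAINT_GY[protocol] / RX_GY[protocol]

    def noiseless(self) -> "PhantomConfig":
        """A copy with heterogeneity noise and hotspots switched off."""
        return replace(self, noise_amplitude=0.0, hotspot_prob=0.0)


@dataclass
class GroundTruth:
    """The generator's noiseless normalized dose (dose / Rx) per GTV voxel."""

    voxel_indices: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)  # in [floor, hot_fraction]


@dataclass
class Plan:
    """One treatment plan: structures plus the delivered dose on one grid."""

    plan_id: str
    patient_id: str
    plan_type: str  # "simulation" | "adapted"
    protocol: str  # "SBRT" | "HYP"
    structs: StructureSet
    dose: DoseGrid
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.protocol not in RX_GY:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if abs(self.dose.rx - RX_GY[self.protocol]) > 1e-9:
            raise ValueError(
                f"plan {self.plan_id}: rx {self.dose.rx} inconsistent with "
                f"protocol {self.protocol}"
            )
        if self.dose.grid != self.structs.grid:
            raise ValueError(f"plan {self.plan_id}: dose and structures disagree on grid")

    @property
    def rx(self) -> float:
        return self.dose.rx


def _blob_mask(
    grid: VoxelGrid, center: np.ndarray, radius: float, irregularity: float, rng
) -> StructureMask:
    """Ellipsoid-ish blob: radius modulated by a smooth random function of
    direction (a small sum of random plane-wave harmonics)."""
    coords = [
        grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    dx, dy, dz = xx - center[0], yy - center[1], zz - center[2]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r > 0, dx / r, 0.0), np.where(r > 0, dy / r, 0.0), np.where(
            r > 0, dz / r, 0.0
        )
    pert = np.zeros_like(r)
    if irregularity > 0:
        for _ in range(4):
            w = rng.normal(size=3) * 2.0
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.3, 1.0)
            pert += amp * np.cos(w[0] * u[0] + w[1] * u[1] + w[2] * u[2] + phase)
        pert *= irregularity / 4.0
    local_radius = radius * (1.0 + pert)
    return StructureMask(grid, r <= local_radius)


def _fits_in_grid(mask: StructureMask, margin_mm: float) -> bool:
    """True when the mask keeps at least ``margin_mm`` clearance from every
    grid face (so 5 mm expansions stay in-grid)."""
    if mask.is_empty:
        return False
    idx = mask.indices()
    spacing = np.asarray(mask.grid.spacing)
    lo = idx.min(axis=0) * spacing
    hi = (np.asarray(mask.grid.shape) - 1 - idx.max(axis=0)) * spacing
    return bool(np.all(lo >= margin_mm) and np.all(hi >= margin_mm))


def generate_phantom(
    cfg: PhantomConfig, patient_seed: int, oar_shift_mm: np.ndarray | None = None
) -> StructureSet:
    """Generate one patient's structure set (GTV + adjacent OAR_CRIT, with
    PTV / OAR_5mm / PTV_OPT derived).

    ``oar_shift_mm`` displaces the OAR (GTV unchanged) to emulate
    interfraction anatomy change for adapted plans.
    """
    rng = child_rng(patient_seed, "phantom")
    grid = cfg.grid
    extent = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    for _attempt in range(40):
        gtv_radius = rng.uniform(*cfg.gtv_radius_mm)
        center = extent / 2.0 + rng.uniform(-0.1, 0.1, 3) * extent
        gtv = _blob_mask(grid, center, gtv_radius, cfg.irregularity, rng)
        oar_radius = rng.uniform(*cfg.oar_radius_mm)
        offset = rng.uniform(*cfg.oar_offset_mm)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        oar_center = center + direction * (gtv_radius + oar_radius + offset)
        if oar_shift_mm is not None:
            oar_center = oar_center + np.asarray(oar_shift_mm, dtype=float)
        oar = _blob_mask(grid, oar_center, oar_radius, cfg.irregularity, rng)
        if not _fits_in_grid(gtv, cfg.margin_mm + 1):
            continue
        if oar.is_empty:
            continue
        return derive_structure_set(gtv, oar, margin=cfg.margin_mm)
    raise GenerationError(
        f"no feasible phantom geometry within 40 attempts (seed {patient_seed})"
    )


def synth_dose(
    structs: StructureSet, cfg: PhantomConfig, seed: int, protocol: str = "SBRT"
) -> tuple[DoseGrid, GroundTruth]:
    """Isotoxicity-style dose for a structure set, plus its noiseless
    ground truth over GTV voxels."""
    grid = structs.grid
    rng = child_rng(seed, "dose")
    rx = RX_GY[protocol]
    c = cfg.constraint_for(protocol)
    h = cfg.hot_fraction
    f_range = cfg.falloff_mm

    d = signed_distance_map(structs.oar_5mm)  # +inf when the OAR is empty
    g = c + (h - c) * np.clip(d, 0.0, f_range) / f_range

    delivered = g.copy()
    if cfg.noise_amplitude > 0:
        white = rng.standard_normal(grid.shape)
        sigma_vox = cfg.noise_corr_mm / np.asarray(grid.spacing)
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
        sd = smooth.std()
        if sd > 0:
            delivered = delivered + smooth / sd * cfg.noise_amplitude
    if cfg.hotspot_prob > 0 and rng.uniform() < cfg.hotspot_prob:
        # one Gaussian hotspot centered on a random GTV voxel
        idx = structs.gtv.indices()
        center = grid.voxel_centers(idx[rng.integers(len(idx))])[0]
        coords = [
            grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a]
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*coords, indexing="ij")
        r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
        amp = rng.uniform(0.1, max(0.1, 1.5 - h))
        delivered = delivered + amp * np.exp(-r2 / (2 * cfg.hotspot_sigma_mm**2))

    dose = np.clip(delivered * rx, 0.0, 1.5 * rx)
    gt = GroundTruth(
        voxel_indices=structs.gtv.indices(),
        values=g[structs.gtv.voxels],
    )
    return DoseGrid(grid=grid, dose=dose, rx=rx), gt


def generate_cohort(cfg: PhantomConfig) -> list[Plan]:
    """Generate the full cohort: per patient one simulation plan plus
    ``plans_per_patient - 1`` adapted plans (OAR shifted, GTV fixed)."""
    if cfg.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    plans: list[Plan] = []
    for p in range(cfg.n_patients):
        patient_id = f"pat{p:03d}"
        patient_seed = child_seed(cfg.seed, "patient", p)
        protocol = (
            "HYP"
            if child_rng(patient_seed, "protocol").uniform() < cfg.hyp_patient_fraction
            else "SBRT"
        )
        for j in range(cfg.plans_per_patient):
            plan_type = "simulation" if j == 0 else "adapted"
            if j == 0:
                shift = None
            else:
                shift = child_rng(patient_seed, "shift", j).uniform(
                    -cfg.adapt_shift_mm, cfg.adapt_shift_mm, 3
                )
            structs = generate_phantom(cfg, patient_seed, oar_shift_mm=shift)
            dose, gt = synth_dose(
                structs, cfg, seed=child_seed(patient_seed, "plan", j), protocol=protocol
            )
            plans.append(
                Plan(
                    plan_id=f"{patient_id}_plan{j}",
                    patient_id=patient_id,
                    plan_type=plan_type,
                    protocol=protocol,
                    structs=structs,
                    dose=dose,
                    ground_truth=gt,
                )
            )
    return plans


def degrade_plan(plan: Plan, factor: float = 0.8, seed: int = 0) -> Plan:
    """Plant a ground-truth inferior plan: scale the dose by ``factor``
    inside a random half-space of the GTV (through its centroid)."""
    if not 0 < factor < 1:
        raise ValueError("degradation factor must lie in (0, 1)")
    rng = child_rng(seed, "degrade", plan.plan_id)
    grid = plan.structs.grid
    idx = plan.structs.gtv.indices()
    centroid = grid.voxel_centers(idx).mean(axis=0)
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)
    centers = grid.all_centers().reshape(*grid.shape, 3)
    halfspace = (centers - centroid) @ normal >= 0
    dose = plan.dose.dose.copy()
    sel = halfspace & plan.structs.gtv.voxels
    dose[sel] *= factor
    return Plan(
        plan_id=plan.plan_id,
        patient_id=plan.patient_id,
        plan_type=plan.plan_type,
        protocol=plan.protocol,
        structs=plan.structs,
        dose=DoseGrid(grid=grid, dose=dose, rx=plan.dose.rx),
        ground_truth=plan.ground_truth,
    )
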