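"""Dose grids, DVH metrics (Vx / Dx / Dmean) and prediction-error statistics.

Plan quality is tracked with the GTV coverage metrics used for online
adaptive decision-making: V95 and V100 (percentage of GTV volume receiving
at least 95% / 100% of the prescription dose Rx), D95 (minimum dose received
by 95% of the GTV volume) and the mean GTV dose. Prediction errors are
reported per plan as actual minus predicted, in Gy and in % of Rx, then
summarized across plans as mean ± sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import GridMismatchError, StructureMask, VoxelGrid

__all__ = [
    "DoseGrid",
    "PlanMetrics",
    "ErrorSummary",
    "vx",
    "dx",
    "dmean",
    "compute_plan_metrics",
    "dvh_error_profile",
    "summarize_errors",
    "METRIC_NAMES",
]

METRIC_NAMES = ("v95", "v100", "d95", "dmean")


@dataclass
class DoseGrid:
    """A dose distribution in Gy on a voxel grid, with its prescription."""

    grid: VoxelGrid
    dose: np.ndarray = field(repr=False)
    rx: float = 50.0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise GridMismatchError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}"
            )
        if self.rx <= 0:
            raise ValueError("prescription dose must be positive")
        finite = self.dose[np.isfinite(self.dose)]
        if finite.size and finite.min() < 0:
            raise ValueError("dose must be non-negative everywhere")


def _gtv_doses(dose: DoseGrid, gtv: StructureMask) -> np.ndarray:
    if dose.grid != gtv.grid:
        raise GridMismatchError("dose and GTV mask must share a grid")
    if gtv.is_empty:
        raise ValueError("metric undefined for an empty GTV")
    return dose.dose[gtv.voxels]


def vx(dose: DoseGrid, gtv: StructureMask, x: float) -> float:
    """Vx: percentage of GTV volume receiving at least ``x``% of Rx
    (inclusive threshold)."""
    d = _gtv_doses(dose, gtv)
    thresh = x / 100.0 * dose.rx
    return 100.0 * np.count_nonzero(d >= thresh) / d.size


def dx(dose: DoseGrid, gtv: StructureMask, p: float) -> float:
    """Dp in Gy: the largest dose d such that at least ``p``% of the GTV
    volume receives >= d (inverse empirical CDF; no interpolation).

    D0 is the maximum GTV dose by convention.
    """
    d = _gtv_doses(dose, gtv)
    if not 0 <= p <= 100:
        raise ValueError("p must be in [0, 100]")
    k = int(np.ceil(p / 100.0 * d.size))
    k = max(k, 1)
    return float(np.sort(d)[::-1][k - 1])


def dmean(dose: DoseGrid, gtv: StructureMask) -> float:
    """Arithmetic mean GTV dose in Gy (all voxels weighted equally)."""
    return float(_gtv_doses(dose, gtv).mean())


@dataclass(frozen=True)
class PlanMetrics:
    """GTV coverage metrics of one plan. v95/v100 in % volume; d95/dmean Gy."""

    v95: float
    v100: float
    d95: float
    dmean: float

    def __post_init__(self) -> None:
        vals = (self.v95, self.v100, self.d95, self.dmean)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("plan metrics must be finite")
        if not (0 <= self.v100 <= self.v95 <= 100):
            raise ValueError("expected 0 <= V100 <= V95 <= 100")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_plan_metrics(dose: DoseGrid, gtv: StructureMask) -> PlanMetrics:
    return PlanMetrics(
        v95=vx(dose, gtv, 95.0),
        v100=vx(dose, gtv, 100.0),
        d95=dx(dose, gtv, 95.0),
        dmean=dmean(dose, gtv),
    )


def dvh_error_profile(
    actual: DoseGrid,
    predicted: DoseGrid,
    gtv: StructureMask,
    x_values=None,
) -> pd.Series:
    """Vx(actual) − Vx(predicted) over a range of dose levels x (% of Rx).

    Defaults to x = 20, 25, ..., 160, the range over which prediction error
    profiles are examined (large errors concentrate above 100% of Rx, where
    beam-geometry hotspots live).
    """
    if actual.grid != predicted.grid:
        raise GridMismatchError("actual and predicted doses must share a grid")
    if x_values is None:
        x_values = np.arange(20.0, 161.0, 5.0)
    errs = {
        float(x): vx(actual, gtv, x) - vx(predicted, gtv, x) for x in x_values
    }
    return pd.Series(errs, name="vx_error_pct")


@dataclass
class ErrorSummary:
    """Cohort prediction-error statistics on a plan-by-plan basis.

    ``per_plan`` holds one row per plan (voxel-dose errors in Gy and % Rx,
    plus actual/predicted/error views of each plan metric). ``dose`` and
    ``metrics`` aggregate across plans: mean ± sample sd of the per-plan
    mean error and mean absolute error; for each plan metric additionally
    the value encompassing the absolute error of 95% of plans and the R² of
    the actual-vs-predicted linear fit.
    """

    per_plan: pd.DataFrame
    dose: dict
    metrics: dict
    n_plans: int
    degenerate_sd: bool = False  # single plan: sd reported as 0

    def to_dict(self) -> dict:
        return {
            "n_plans": self.n_plans,
            "degenerate_sd": self.degenerate_sd,
            "dose": self.dose,
            "metrics": self.metrics,
        }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def summarize_errors(plans) -> ErrorSummary:
    """Summarize prediction errors for a list of
    ``(plan_id, actual: DoseGrid, predicted: DoseGrid, gtv)`` tuples.

    Per plan, voxel errors are ΔDose = actual − predicted over GTV voxels;
    %Rx errors are computed per voxel as ΔDose / Rx × 100 before averaging.
    Predicted grids may carry NaN outside the GTV; only GTV voxels enter.
    """
    plans = list(plans)
    if not plans:
        raise ValueError("at least one plan is required")

    rows = []
    for plan_id, actual, predicted, gtv in plans:
        if actual.grid != predicted.grid or actual.grid != gtv.grid:
            raise GridMismatchError(f"plan {plan_id}: grids differ")
        delta = actual.dose[gtv.voxels] - predicted.dose[gtv.voxels]
        if not np.all(np.isfinite(delta)):
            raise ValueError(f"plan {plan_id}: non-finite predicted dose inside GTV")
        am = compute_plan_metrics(actual, gtv)
        pm = compute_plan_metrics(predicted, gtv)
        row = {
            "plan_id": plan_id,
            "mean_err_gy": delta.mean(),
            "mean_abs_err_gy": np.abs(delta).mean(),
            "mean_err_pct": (delta / actual.rx * 100.0).mean(),
            "mean_abs_err_pct": (np.abs(delta) / actual.rx * 100.0).mean(),
        }
        for m in METRIC_NAMES:
            row[f"{m}_actual"] = getattr(am, m)
            row[f"{m}_predicted"] = getattr(pm, m)
            row[f"{m}_error"] = getattr(am, m) - getattr(pm, m)
        rows.append(row)
    per_plan = pd.DataFrame(rows)

    dose_stats = {}
    for col, label in (
        ("mean_err_gy", "error_gy"),
        ("mean_abs_err_gy", "abs_error_gy"),
        ("mean_err_pct", "error_pct_rx"),
        ("mean_abs_err_pct", "abs_error_pct_rx"),
    ):
        mean, sd = _mean_sd(per_plan[col].to_numpy())
        dose_stats[label] = {"mean": mean, "sd": sd}

    metric_stats = {}
    for m in METRIC_NAMES:
        err = per_plan[f"{m}_error"].to_numpy()
        mean, sd = _mean_sd(err)
        abs_mean, abs_sd = _mean_sd(np.abs(err))
        actual_v = per_plan[f"{m}_actual"].to_numpy()
        pred_v = per_plan[f"{m}_predicted"].to_numpy()
        if len(plans) > 1 and np.std(pred_v) > 0 and np.std(actual_v) > 0:
            fit = stats.linregress(pred_v, actual_v)
            r2 = float(fit.rvalue**2)
        else:
            r2 = 1.0 if np.allclose(actual_v, pred_v) else float("nan")
        metric_stats[m] = {
            "error_mean": mean,
            "error_sd": sd,
            "abs_error_mean": abs_mean,
            "abs_error_sd": abs_sd,
            # smallest value encompassing the absolute error of 95% of plans
            "abs_error_p95": float(np.quantile(np.abs(err), 0.95)),
            "r2": r2,
        }

    return ErrorSummary(
        per_plan=per_plan,
        dose=dose_stats,
        metrics=metric_stats,
        n_plans=len(plans),
        degenerate_sd=len(plans) == 1,
    )
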