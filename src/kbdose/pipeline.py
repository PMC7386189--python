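"""Patient-wise cross-validation, prediction intervals, inferior-plan
detection and two-round model refinement.

Validation is grouped by patient: patients are partitioned into groups of
five (plus one remainder group), each group cycles through as the test set,
and the ensemble for a fold is trained only on plans from the other
patients' groups — a plan is never predicted by a model that saw any plan
of the same patient. Training voxels are subsampled once per fold at a 1/20
ratio per plan, so each GTV contributes proportionally regardless of size.

Plans whose observed V95, V100 or D95 falls outside the 95% prediction
interval of the cross-validated errors (mean error ± 1.96 × sd) are flagged
as inferior; refinement drops flagged plans from the training pools and
retrains, for a configurable number of rounds (two by default). Discarded
plans still receive predictions for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import child_rng, child_seed
from .dosimetry import DoseGrid, PlanMetrics, compute_plan_metrics, summarize_errors
from .features import FeatureMatrix, compute_voxel_features
from .model import EnsembleModel, TrainConfig, train_ensemble
from .synthetic import Plan

__all__ = [
    "Plan",
    "CVConfig",
    "PredictionInterval",
    "PlanPrediction",
    "CVResult",
    "RefinementResult",
    "plan_features",
    "sample_training_voxels",
    "make_patient_folds",
    "cross_validate",
    "fit_prediction_interval",
    "detect_inferior_plans",
    "refine_model",
]

#: Metrics used for inferior-plan flagging (Dmean is tracked but not used
#: to flag).
FLAGGING_METRICS = ("v95", "v100", "d95")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol: groups of five patients, 1/20 voxel
    sampling, 50 training repeats."""

    group_size: int = 5
    sampling_ratio: float = 1.0 / 20.0
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    n_repeats: int = 50
    seed: int = 0
    two_sided_flagging: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sampling_ratio <= 1:
            raise ValueError("sampling_ratio must lie in (0, 1]")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")


@dataclass(frozen=True)
class PredictionInterval:
    """95% prediction interval of a plan-metric error distribution."""

    metric: str
    mean_error: float
    sd_error: float
    degenerate: bool = False  # sd == 0

    @property
    def lower(self) -> float:
        return self.mean_error - 1.96 * self.sd_error

    @property
    def upper(self) -> float:
        return self.mean_error + 1.96 * self.sd_error

    def contains(self, error: float, two_sided: bool = True) -> bool:
        if two_sided:
            return self.lower <= error <= self.upper
        return error <= self.upper


@dataclass
class PlanPrediction:
    """Out-of-fold prediction for one plan."""

    plan: Plan
    fold: int
    predicted_dose: DoseGrid
    actual_metrics: PlanMetrics
    predicted_metrics: PlanMetrics


@dataclass
class CVResult:
    """Accumulated cross-validation output: exactly one out-of-fold
    prediction per plan."""

    predictions: dict[str, PlanPrediction]
    folds: list[list[str]]
    models: list[EnsembleModel]
    excluded_from_training: frozenset[str] = frozenset()

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for pp in self.predictions.values():
            row = {
                "plan_id": pp.plan.plan_id,
                "patient_id": pp.plan.patient_id,
                "plan_type": pp.plan.plan_type,
                "protocol": pp.plan.protocol,
                "rx_gy": pp.plan.rx,
                "fold": pp.fold,
            }
            for m, actual in pp.actual_metrics.as_dict().items():
                pred = pp.predicted_metrics.as_dict()[m]
                row[f"{m}_actual"] = actual
                row[f"{m}_predicted"] = pred
                row[f"{m}_error"] = actual - pred
            rows.append(row)
        return pd.DataFrame(rows).sort_values("plan_id").reset_index(drop=True)

    def error_summary(self):
        return summarize_errors(
            (pp.plan.plan_id, pp.plan.dose, pp.predicted_dose, pp.plan.structs.gtv)
            for pp in self.predictions.values()
        )


def plan_features(plan: Plan) -> tuple[FeatureMatrix, np.ndarray]:
    """Feature rows plus normalized dose targets (dose / Rx) for all GTV
    voxels of a plan."""
    fm = compute_voxel_features(plan.structs, plan_id=plan.plan_id)
    targets = plan.dose.dose[tuple(fm.voxel_indices.T)] / plan.rx
    return fm, targets


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def sample_training_voxels(
    plans,
    ratio: float,
    seed: int,
    features: dict[str, tuple[FeatureMatrix, np.ndarray]] | None = None,
):
    """Per plan, draw exactly round(ratio × n_gtv_voxels) voxels (half-up,
    at least 1) without replacement; accumulate across plans.

    Returns ``(X, y)`` stacked over plans. ``features`` may carry
    precomputed ``plan_features`` output keyed by plan_id.
    """
    xs, ys = [], []
    for plan in plans:
        if plan.structs.gtv.is_empty:
            warnings.warn(f"plan {plan.plan_id}: empty GTV skipped", stacklevel=2)
            continue
        if features is not None and plan.plan_id in features:
            fm, targets = features[plan.plan_id]
        else:
            fm, targets = plan_features(plan)
        n = fm.n_rows
        k = max(1, _round_half_up(ratio * n))
        rng = child_rng(seed, "sample", plan.plan_id)
        sel = rng.choice(n, size=min(k, n), replace=False)
        xs.append(fm.values[sel])
        ys.append(targets[sel])
    if not xs:
        raise ValueError("no plans with a non-empty GTV to sample from")
    return np.vstack(xs), np.concatenate(ys)


def make_patient_folds(patient_ids, group_size: int, seed: int) -> list[list[str]]:
    """Seeded random partition of patients into groups of ``group_size``
    with one smaller remainder group (53 patients at size 5 → ten groups of
    five and one of three)."""
    unique = sorted(dict.fromkeys(patient_ids))
    if len(unique) < 2:
        raise ValueError("need at least 2 patients for cross-validation")
    if group_size > len(unique):
        raise ValueError(
            f"group_size {group_size} exceeds the {len(unique)} patients: "
            "only a single fold would remain"
        )
    rng = child_rng(seed, "folds")
    order = [unique[i] for i in rng.permutation(len(unique))]
    folds = [order[i : i + group_size] for i in range(0, len(order), group_size)]
    return folds


def cross_validate(
    plans: list[Plan],
    cfg: CVConfig | None = None,
    exclude_from_training: frozenset[str] = frozenset(),
    features: dict[str, tuple[FeatureMatrix, np.ndarray]] | None = None,
) -> CVResult:
    """Patient-wise cross-validation: every plan receives exactly one
    prediction from an ensemble trained without any plan of its patient.

    ``exclude_from_training`` removes plans (by id) from every training
    pool; they are still predicted and reported.
    """
    cfg = cfg or CVConfig()
    if features is None:
        features = {p.plan_id: plan_features(p) for p in plans}
    folds = make_patient_folds(
        [p.patient_id for p in plans], cfg.group_size, cfg.seed
    )
    predictions: dict[str, PlanPrediction] = {}
    models: list[EnsembleModel] = []
    for fold_idx, test_patients in enumerate(folds):
        test_set = set(test_patients)
        train_plans = [
            p
            for p in plans
            if p.patient_id not in test_set and p.plan_id not in exclude_from_training
        ]
        test_plans = [p for p in plans if p.patient_id in test_set]
        # leakage is structurally impossible; assert it anyway
        train_patients = {p.patient_id for p in train_plans}
        if train_patients & test_set:
            raise AssertionError("patient leakage between train and test sets")
        if not train_plans:
            raise ValueError(f"fold {fold_idx}: empty training pool")

        x, y = sample_training_voxels(
            train_plans,
            cfg.sampling_ratio,
            seed=child_seed(cfg.seed, "fold", fold_idx),
            features=features,
        )
        train_cfg = TrainConfig(
            max_epochs=cfg.train_cfg.max_epochs,
            patience=cfg.train_cfg.patience,
            val_fraction=cfg.train_cfg.val_fraction,
            seed=child_seed(cfg.seed, "train", fold_idx),
            input_norm=cfg.train_cfg.input_norm,
        )
        model = train_ensemble(x, y, train_cfg, n_repeats=cfg.n_repeats)
        models.append(model)

        for plan in test_plans:
            fm, _ = features[plan.plan_id]
            pred_norm = model.predict_normalized(fm.values)
            dose = np.full(plan.structs.grid.shape, np.nan)
            dose[tuple(fm.voxel_indices.T)] = np.clip(pred_norm, 0.0, None) * plan.rx
            pred_grid = DoseGrid(grid=plan.structs.grid, dose=dose, rx=plan.rx)
            predictions[plan.plan_id] = PlanPrediction(
                plan=plan,
                fold=fold_idx,
                predicted_dose=pred_grid,
                actual_metrics=compute_plan_metrics(plan.dose, plan.structs.gtv),
                predicted_metrics=compute_plan_metrics(pred_grid, plan.structs.gtv),
            )
    return CVResult(
        predictions=predictions,
        folds=folds,
        models=models,
        excluded_from_training=frozenset(exclude_from_training),
    )


def fit_prediction_interval(
    actual, predicted=None, metric: str = "metric"
) -> PredictionInterval:
    """Fit mean ± 1.96 sd bounds on per-plan metric errors.

    Call either with an array of errors, or with parallel arrays of actual
    and predicted metric values (errors = actual − predicted). Uses the
    sample standard deviation (n − 1).
    """
    errors = np.asarray(actual, dtype=float)
    if predicted is not None:
        errors = errors - np.asarray(predicted, dtype=float)
    if errors.size < 3:
        raise ValueError("prediction interval needs at least 3 plans")
    sd = float(errors.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        warnings.warn(f"{metric}: zero error spread, degenerate interval", stacklevel=2)
    return PredictionInterval(
        metric=metric,
        mean_error=float(errors.mean()),
        sd_error=sd,
        degenerate=degenerate,
    )


def fit_intervals(metrics_frame: pd.DataFrame) -> dict[str, PredictionInterval]:
    """Prediction intervals for each flagging metric from a pooled
    cross-validation metrics frame."""
    return {
        m: fit_prediction_interval(
            metrics_frame[f"{m}_error"].to_numpy(), metric=m
        )
        for m in FLAGGING_METRICS
    }


def detect_inferior_plans(
    metrics_frame: pd.DataFrame,
    intervals: dict[str, PredictionInterval],
    two_sided: bool = True,
) -> set[str]:
    """Plans whose error for ANY of V95, V100 or D95 falls outside that
    metric's 95% prediction interval."""
    missing = [m for m in FLAGGING_METRICS if m not in intervals]
    if missing:
        raise ValueError(f"missing prediction intervals for {missing}")
    flagged: set[str] = set()
    for _, row in metrics_frame.iterrows():
        for m in FLAGGING_METRICS:
            if not intervals[m].contains(row[f"{m}_error"], two_sided=two_sided):
                flagged.add(row["plan_id"])
                break
    return flagged


@dataclass
class RefinementResult:
    """Outcome of iterative outlier rejection and retraining."""

    result: CVResult
    discarded_per_round: list[set[str]]
    intervals: dict[str, PredictionInterval]

    @property
    def discarded(self) -> set[str]:
        out: set[str] = set()
        for s in self.discarded_per_round:
            out |= s
        return out


def refine_model(
    plans: list[Plan], cfg: CVConfig | None = None, rounds: int = 2
) -> RefinementResult:
    """Cross-validate, flag inferior plans, drop them from the training
    pools, and retrain — ``rounds`` times.

    With ``rounds = 0`` this is plain cross-validation. Flagged plans keep
    receiving predictions; the final intervals are fitted on the retained
    plans of the last round.
    """
    cfg = cfg or CVConfig()
    features = {p.plan_id: plan_features(p) for p in plans}
    discarded: set[str] = set()
    discarded_per_round: list[set[str]] = []
    result = cross_validate(plans, cfg, features=features)
    frame = result.metrics_frame()
    intervals = fit_intervals(frame)
    for _round in range(rounds):
        retained = frame[~frame["plan_id"].isin(discarded)]
        intervals = fit_intervals(retained)
        newly = (
            detect_inferior_plans(retained, intervals, cfg.two_sided_flagging)
            - discarded
        )
        discarded_per_round.append(newly)
        discarded |= newly
        if len(discarded) == len(plans):
            raise RuntimeError(
                "every plan was flagged as inferior; the error model is "
                "degenerate — check the cohort or the interval fit"
            )
        result = cross_validate(
            plans, cfg, exclude_from_training=frozenset(discarded), features=features
        )
        frame = result.metrics_frame()
    retained = frame[~frame["plan_id"].isin(discarded)]
    intervals = fit_intervals(retained)
    return RefinementResult(
        result=result,
        discarded_per_round=discarded_per_round,
        intervals=intervals,
    )
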