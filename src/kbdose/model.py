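"""The 16→2→1 feed-forward network, Levenberg–Marquardt training, and the
50-member ensemble.

The network is deliberately tiny: one hidden layer of two tanh nodes and a
linear output node — 37 free parameters in total (2×16 hidden weights + 2
hidden biases + 1×2 output weights + 1 output bias). Wider or deeper
variants overfit voxel-dose data without improving accuracy, and a model
this small trains in seconds with a batch second-order optimizer.

Training minimizes mean square error on normalized dose (dose / Rx) with
Levenberg–Marquardt: a damped Gauss–Newton iteration on the residual
Jacobian, where the damping λ (``mu``) is increased tenfold on rejected
steps and decreased tenfold on accepted ones. With λ → ∞ the step turns
into scaled gradient descent; at λ = 0 it is the pure Gauss–Newton step.
One epoch is one full LM pass over the training split (LM is batch by
nature). Early stopping watches a held-out validation split (15% of the
sampled voxels): after six consecutive validation-error increases training
halts and the weights with the best validation MSE seen are restored.

An ensemble repeats training 50 times with fresh random initializations and
fresh 85/15 splits; its prediction is the arithmetic mean of the members'
outputs, rescaled by Rx.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._rand import child_rng
from .dosimetry import DoseGrid
from .features import FEATURE_NAMES, compute_voxel_features
from .geometry import StructureSet

__all__ = [
    "TrainConfig",
    "NetworkParameters",
    "Normalizer",
    "TrainingHistory",
    "EnsembleModel",
    "train_network",
    "train_ensemble",
    "predict_dose",
]

N_INPUTS = len(FEATURE_NAMES)
N_HIDDEN = 2
N_PARAMS = N_HIDDEN * N_INPUTS + N_HIDDEN + N_HIDDEN + 1  # 37


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: MSE loss, LM optimizer, 85/15 split, patience 6,
    at most 200 epochs."""

    max_epochs: int = 200
    patience: int = 6
    val_fraction: float = 0.15
    seed: int = 0
    input_norm: str = "minmax"  # or "zscore"
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.input_norm not in ("minmax", "zscore"):
            raise ValueError("input_norm must be 'minmax' or 'zscore'")


@dataclass
class NetworkParameters:
    """Weights of one 16→2→1 network (tanh hidden, identity output)."""

    w1: np.ndarray  # (2, 16)
    b1: np.ndarray  # (2,)
    w2: np.ndarray  # (1, 2)
    b2: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float).reshape(N_HIDDEN, N_INPUTS)
        self.b1 = np.asarray(self.b1, dtype=float).reshape(N_HIDDEN)
        self.w2 = np.asarray(self.w2, dtype=float).reshape(1, N_HIDDEN)
        self.b2 = np.asarray(self.b2, dtype=float).reshape(1)
        if not all(
            np.all(np.isfinite(a)) for a in (self.w1, self.b1, self.w2, self.b2)
        ):
            raise ValueError("network parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    @classmethod
    def from_vector(cls, w: np.ndarray) -> "NetworkParameters":
        w = np.asarray(w, dtype=float)
        if w.shape != (N_PARAMS,):
            raise ValueError(f"expected parameter vector of length {N_PARAMS}")
        i = N_HIDDEN * N_INPUTS
        return cls(
            w1=w[:i],
            b1=w[i : i + N_HIDDEN],
            w2=w[i + N_HIDDEN : i + 2 * N_HIDDEN],
            b2=w[i + 2 * N_HIDDEN :],
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Network output for normalized inputs ``x`` of shape (n, 16)."""
        h = np.tanh(x @ self.w1.T + self.b1)
        return (h @ self.w2.T + self.b2).ravel()


@dataclass
class Normalizer:
    """Input normalization fitted on the training split only.

    Maps each feature to [-1, 1] (min-max, the default) or to z-scores.
    Zero-variance columns cannot be scaled; they are mapped to a constant 0
    and recorded in ``constant_columns`` (the architecture keeps all 16
    inputs, so the column is silenced rather than removed). The target
    scale is the prescription dose: targets are dose / Rx.
    """

    center: np.ndarray
    scale: np.ndarray
    constant_columns: list[int] = field(default_factory=list)
    mode: str = "minmax"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(N_INPUTS)
        self.scale = np.asarray(self.scale, dtype=float).reshape(N_INPUTS)
        if np.any(self.scale <= 0):
            raise ValueError("normalizer scales must be positive")

    @classmethod
    def fit(cls, x: np.ndarray, mode: str = "minmax") -> "Normalizer":
        x = np.asarray(x, dtype=float)
        if mode == "minmax":
            lo, hi = x.min(axis=0), x.max(axis=0)
            center = (hi + lo) / 2.0
            scale = (hi - lo) / 2.0
        elif mode == "zscore":
            center = x.mean(axis=0)
            scale = x.std(axis=0)
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        constant = np.flatnonzero(scale == 0)
        if constant.size:
            warnings.warn(
                f"zero-variance feature column(s) {constant.tolist()} mapped to 0",
                stacklevel=2,
            )
            scale = scale.copy()
            scale[constant] = 1.0
        return cls(
            center=center, scale=scale, constant_columns=constant.tolist(), mode=mode
        )

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        if self.constant_columns:
            z[:, self.constant_columns] = 0.0
        return z


@dataclass
class TrainingHistory:
    train_mse: list[float]
    val_mse: list[float]
    stop_reason: str  # "early_stop" | "max_epochs" | "mu_max"
    best_epoch: int
    seed: int

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


def _init_params(rng: np.random.Generator) -> np.ndarray:
    """Small uniform init scaled by fan-in."""
    lim1 = 1.0 / np.sqrt(N_INPUTS)
    lim2 = 1.0 / np.sqrt(N_HIDDEN)
    return np.concatenate(
        [
            rng.uniform(-lim1, lim1, N_HIDDEN * N_INPUTS),
            rng.uniform(-lim1, lim1, N_HIDDEN),
            rng.uniform(-lim2, lim2, N_HIDDEN),
            rng.uniform(-lim2, lim2, 1),
        ]
    )


def _forward_jacobian(w: np.ndarray, x: np.ndarray):
    """Residual-model forward pass plus the analytic Jacobian d(out)/d(w)."""
    p = NetworkParameters.from_vector(w)
    z = x @ p.w1.T + p.b1  # (n, 2)
    h = np.tanh(z)
    out = (h @ p.w2.T + p.b2).ravel()
    dz = (1.0 - h**2) * p.w2.ravel()  # (n, 2): d out / d z_j
    n = x.shape[0]
    jac = np.empty((n, N_PARAMS))
    # hidden weights W1[j, i]: dz_j * x_i
    jac[:, : N_HIDDEN * N_INPUTS] = (dz[:, :, None] * x[:, None, :]).reshape(n, -1)
    i = N_HIDDEN * N_INPUTS
    jac[:, i : i + N_HIDDEN] = dz  # hidden biases
    jac[:, i + N_HIDDEN : i + 2 * N_HIDDEN] = h  # output weights
    jac[:, -1] = 1.0  # output bias
    return out, jac


def lm_step(w, x, y, mu):
    """One damped Gauss–Newton trial step: solve (JᵀJ + μI) δ = −Jᵀr."""
    out, jac = _forward_jacobian(w, x)
    r = out - y
    g = jac.T @ r
    hess = jac.T @ jac
    delta = np.linalg.solve(hess + mu * np.eye(N_PARAMS), -g)
    return w + delta


def _mse(w: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    p = NetworkParameters.from_vector(w)
    r = p.forward(x) - y
    return float(np.mean(r**2))


def train_network(
    features: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Train one network on (raw feature rows, normalized dose targets).

    Returns ``(NetworkParameters, Normalizer, TrainingHistory)``. The data
    are split 85/15 into training and validation subsets; the training split
    drives the LM updates and the validation split drives early stopping.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if x.ndim != 2 or x.shape[1] != N_INPUTS:
        raise ValueError(f"features must be (n, {N_INPUTS})")
    if x.shape[0] != y.size:
        raise ValueError("features and targets disagree in length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs or targets")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    # split, then fit normalization on the training split only
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    norm = Normalizer.fit(x[train_idx], mode=cfg.input_norm)
    xt, yt = norm.transform(x[train_idx]), y[train_idx]
    xv, yv = norm.transform(x[val_idx]), y[val_idx]

    w = _init_params(rng)
    mu = cfg.mu0
    train_mse = _mse(w, xt, yt)
    best_w, best_val, best_epoch = w.copy(), np.inf, 0
    consec_increase = 0
    prev_val = np.inf
    hist_train: list[float] = []
    hist_val: list[float] = []
    stop_reason = "max_epochs"

    for epoch in range(cfg.max_epochs):
        # one LM epoch: raise mu until a step lowers the training MSE
        accepted = False
        while mu <= cfg.mu_max:
            try:
                w_new = lm_step(w, xt, yt, mu)
            except np.linalg.LinAlgError:
                # silenced (zero-variance) inputs leave zero Jacobian
                # columns; a larger damping regularizes the solve
                mu *= cfg.mu_inc
                continue
            new_mse = _mse(w_new, xt, yt)
            if np.isfinite(new_mse) and new_mse < train_mse:
                w, train_mse = w_new, new_mse
                mu = max(mu * cfg.mu_dec, 1e-12)
                accepted = True
                break
            mu *= cfg.mu_inc
        if not accepted:
            stop_reason = "mu_max"
            break

        val_mse = _mse(w, xv, yv)
        hist_train.append(train_mse)
        hist_val.append(val_mse)
        if val_mse < best_val:
            best_val, best_w, best_epoch = val_mse, w.copy(), epoch
        consec_increase = consec_increase + 1 if val_mse > prev_val else 0
        prev_val = val_mse
        if consec_increase >= cfg.patience:
            stop_reason = "early_stop"
            break

    params = NetworkParameters.from_vector(best_w)
    history = TrainingHistory(
        train_mse=hist_train,
        val_mse=hist_val,
        stop_reason=stop_reason,
        best_epoch=best_epoch,
        seed=cfg.seed,
    )
    return params, norm, history


@dataclass
class EnsembleModel:
    """An averaged ensemble of independently trained networks."""

    members: list[tuple[NetworkParameters, Normalizer]]
    histories: list[TrainingHistory] = field(default_factory=list)
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")

    def predict_normalized(self, features: np.ndarray) -> np.ndarray:
        """Mean member output (dose / Rx) for raw feature rows."""
        x = np.asarray(features, dtype=float)
        preds = [p.forward(norm.transform(x)) for p, norm in self.members]
        return np.mean(preds, axis=0)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "format": "kbdose-ensemble-v1",
            "architecture": {"inputs": N_INPUTS, "hidden": N_HIDDEN, "outputs": 1},
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "members": [
                {
                    "w1": p.w1.tolist(),
                    "b1": p.b1.tolist(),
                    "w2": p.w2.tolist(),
                    "b2": p.b2.tolist(),
                    "norm": {
                        "center": norm.center.tolist(),
                        "scale": norm.scale.tolist(),
                        "constant_columns": norm.constant_columns,
                        "mode": norm.mode,
                    },
                }
                for p, norm in self.members
            ],
            "histories": [asdict(h) for h in self.histories],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EnsembleModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("format") != "kbdose-ensemble-v1":
            raise ValueError("unrecognized model document")
        members = [
            (
                NetworkParameters(m["w1"], m["b1"], m["w2"], m["b2"]),
                Normalizer(
                    center=m["norm"]["center"],
                    scale=m["norm"]["scale"],
                    constant_columns=list(m["norm"]["constant_columns"]),
                    mode=m["norm"]["mode"],
                ),
            )
            for m in doc["members"]
        ]
        histories = [TrainingHistory(**h) for h in doc.get("histories", [])]
        return cls(
            members=members,
            histories=histories,
            n_repeats=doc["n_repeats"],
            seed=doc["seed"],
        )


def train_ensemble(
    features: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig | None = None,
    n_repeats: int = 50,
) -> EnsembleModel:
    """Repeat training ``n_repeats`` times (fresh init + fresh 85/15 split,
    seeded deterministically from ``cfg.seed`` and the repeat index) and
    average the members at prediction time."""
    cfg = cfg or TrainConfig()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    members = []
    histories = []
    for rep in range(n_repeats):
        rng = child_rng(cfg.seed, "repeat", rep)
        params, norm, hist = train_network(features, targets, cfg, rng=rng)
        members.append((params, norm))
        histories.append(hist)
    return EnsembleModel(
        members=members, histories=histories, n_repeats=n_repeats, seed=cfg.seed
    )


def predict_dose(model: EnsembleModel, structs: StructureSet, rx: float) -> DoseGrid:
    """Predict the 3D dose (Gy) inside the GTV of a plan.

    Features are computed from the structures alone (no beam information),
    normalized per member, averaged across the ensemble and rescaled by the
    prescription. Voxels outside the GTV carry NaN (no prediction).
    """
    if rx <= 0:
        raise ValueError("prescription must be positive")
    fm = compute_voxel_features(structs)
    pred_norm = model.predict_normalized(fm.values)
    dose = np.full(structs.grid.shape, np.nan)
    dose[tuple(fm.voxel_indices.T)] = np.clip(pred_norm, 0.0, None) * rx
    # NaN outside the GTV is the no-prediction sentinel; DoseGrid only
    # validates the finite part.
    return DoseGrid(grid=structs.grid, dose=dose, rx=rx)
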