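"""Placebo-propensity estimation from pre-randomization item changes.

The predictor matrix is the per-item change between the two pre-randomization
visits (baseline minus screening by default).  A small fully connected
feed-forward network with logistic activations maps the scaled item changes to
the probability of a >=50% placebo response at end of study.  Model selection
is a grid search over layer/node counts by stratified cross-validated AUC on
the 75% placebo training split; the held-out 25% provides a bootstrap ROC-AUC
confidence interval that gates the weighted analysis (the lower 95% bound must
clear the non-informative 0.5).  Validated models score every randomized
subject; the inverse probability (floored, then renormalized to mean one)
becomes the analysis weight.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .labeling import LabelingResult
from .simulate import ScaleDefinition, SubjectTrajectory

__all__ = [
    "DELTA_DIRECTION",
    "DegenerateLabelError",
    "TrainingError",
    "PropensityModelSpec",
    "PropensityModel",
    "RocResult",
    "PropensityScores",
    "DEFAULT_GRID",
    "build_item_delta_matrix",
    "split_placebo",
    "grid_search_ann",
    "train_ann",
    "auc_mann_whitney",
    "bootstrap_roc",
    "validate_model",
    "predict_propensity",
    "propensity_distribution",
]

# Direction of the pre-randomization item change used as predictor.  The
# instrument records improvement as a score decrease, so "baseline - screening"
# is negative for subjects already improving before randomization.
DELTA_DIRECTION = "baseline_minus_screening"

PROPENSITY_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
_BIN_LABELS = ("<0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", ">0.8")


class DegenerateLabelError(ValueError):
    """Single-class labels: a propensity model cannot be trained."""


class TrainingError(RuntimeError):
    """Network training failed to converge after the allowed restarts."""


@dataclass(frozen=True)
class PropensityModelSpec:
    """Architecture and training hyper-parameters for the propensity network."""

    hidden_layers: tuple[int, ...] = (3,)
    activation: str = "logistic"
    max_iterations: int = 2000
    tol: float = 1e-6
    seed: int = 0
    input_scaling: str = "minmax"  # or "zscore"
    # L2 penalty on the network weights; small placebo-arm training sets need
    # real shrinkage for the held-out ranking to hold up
    l2_penalty: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_layers) <= 3:
            raise ValueError("between 1 and 3 hidden layers are supported")
        if any(n < 1 for n in self.hidden_layers):
            raise ValueError("every hidden layer needs >= 1 node")
        if self.input_scaling not in ("minmax", "zscore"):
            raise ValueError(f"unknown input scaling {self.input_scaling!r}")

    @property
    def total_nodes(self) -> int:
        return int(sum(self.hidden_layers))


# layers in {1,2,3} x nodes per layer in {1,3,5,7}
DEFAULT_GRID: tuple[PropensityModelSpec, ...] = tuple(
    PropensityModelSpec(hidden_layers=(nodes,) * layers)
    for layers in (1, 2, 3)
    for nodes in (1, 3, 5, 7)
)


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    n_boot: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")
        if self.ci_lower > self.ci_upper:
            raise ValueError("CI bounds out of order")


@dataclass
class PropensityModel:
    """A fitted propensity network plus the preprocessing learned with it."""

    spec: PropensityModelSpec
    feature_names: list[str]
    kept_columns: list[int]  # indices into feature_names after variance guard
    scale_offset: np.ndarray  # per-kept-column offset (min or mean)
    scale_factor: np.ndarray  # per-kept-column divisor (range or sd)
    network: MLPClassifier = field(repr=False)
    n_restarts_used: int = 0

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float)[:, self.kept_columns]
        return (Z - self.scale_offset) / self.scale_factor

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(placebo response) in the open interval (0, 1)."""
        p = self.network.predict_proba(self._preprocess(X))[:, 1]
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def to_json(self) -> str:
        """Serialize architecture, scaling and weights for reproducibility."""
        payload = {
            "spec": {
                "hidden_layers": list(self.spec.hidden_layers),
                "activation": self.spec.activation,
                "max_iterations": self.spec.max_iterations,
                "tol": self.spec.tol,
                "seed": self.spec.seed,
                "input_scaling": self.spec.input_scaling,
                "l2_penalty": self.spec.l2_penalty,
            },
            "feature_names": self.feature_names,
            "kept_columns": self.kept_columns,
            "scale_offset": self.scale_offset.tolist(),
            "scale_factor": self.scale_factor.tolist(),
            "coefs": [w.tolist() for w in self.network.coefs_],
            "intercepts": [b.tolist() for b in self.network.intercepts_],
        }
        return json.dumps(payload, indent=1)


def build_item_delta_matrix(
    subjects: Sequence[SubjectTrajectory],
    scale: ScaleDefinition,
    direction: str = DELTA_DIRECTION,
) -> pd.DataFrame:
    """Per-item pre-randomization change matrix (subjects x items).

    Screening and baseline are required visits; subjects missing either are
    dropped (callers read the count off the index difference).
    """
    if direction not in ("baseline_minus_screening", "screening_minus_baseline"):
        raise ValueError(f"unknown delta direction {direction!r}")
    sign = 1.0 if direction == "baseline_minus_screening" else -1.0
    rows, ids = [], []
    for s in subjects:
        weeks = s.observed_weeks
        scr = next((w for w in weeks if w < 0), None)
        if scr is None or 0.0 not in s.item_scores:
            continue
        delta = sign * (
            s.item_scores[0.0].astype(float) - s.item_scores[scr].astype(float)
        )
        rows.append(delta)
        ids.append(s.subject_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"),
                        columns=scale.item_columns)


def split_placebo(
    labels: LabelingResult | pd.DataFrame,
    fraction_train: float = 0.75,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Deterministic stratified train/validation split of labeled placebo subjects.

    Per-class counts are floors of the train fraction, with leftover slots
    assigned by largest fractional remainder so the overall train size is
    ``round(fraction_train * n)``.
    """
    frame = labels.to_frame() if isinstance(labels, LabelingResult) else labels
    y = frame["responder"].to_numpy()
    ids = frame["subject_id"].to_numpy()
    if len(ids) < 8:
        raise ValueError("need at least 8 labeled subjects to split")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("labels contain a single class; cannot stratify")

    rng = np.random.default_rng(seed)
    n_train_target = int(round(fraction_train * len(ids)))
    class_values, class_counts = np.unique(y, return_counts=True)
    exact = fraction_train * class_counts
    base = np.floor(exact).astype(int)
    remainder = n_train_target - base.sum()
    order = np.argsort(-(exact - base))  # largest fractional part first
    take = base.copy()
    for j in order[: max(remainder, 0)]:
        take[j] += 1

    train_ids: list[str] = []
    val_ids: list[str] = []
    for cls, n_take in zip(class_values, take):
        members = ids[y == cls]
        perm = rng.permutation(len(members))
        train_ids.extend(members[perm[:n_take]])
        val_ids.extend(members[perm[n_take:]])
    return sorted(train_ids), sorted(val_ids)


def _fit_scaler(X: np.ndarray, scaling: str) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Learn column filter + scaling on training data only."""
    X = np.asarray(X, dtype=float)
    variances = X.var(axis=0)
    kept = [j for j in range(X.shape[1]) if variances[j] > 0]
    if not kept:
        raise TrainingError("all predictor columns are constant")
    Z = X[:, kept]
    if scaling == "minmax":
        offset = Z.min(axis=0)
        factor = Z.max(axis=0) - offset
    else:
        offset = Z.mean(axis=0)
        factor = Z.std(axis=0)
    factor = np.where(factor > 0, factor, 1.0)
    return kept, offset, factor


def train_ann(
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence[int],
    spec: PropensityModelSpec,
    max_restarts: int = 3,
) -> PropensityModel:
    """Fit the feed-forward propensity network; deterministic given spec.seed.

    Zero-variance predictor columns are dropped before scaling.  On
    non-convergence the fit restarts with an incremented seed up to
    ``max_restarts`` times before raising :class:`TrainingError`.
    """
    feature_names = (
        list(X_train.columns)
        if isinstance(X_train, pd.DataFrame)
        else [f"x{j}" for j in range(np.shape(X_train)[1])]
    )
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("single-class training labels")

    kept, offset, factor = _fit_scaler(X, spec.input_scaling)
    Z = (X[:, kept] - offset) / factor

    last_exc: Exception | None = None
    for attempt in range(max_restarts + 1):
        net = MLPClassifier(
            hidden_layer_sizes=spec.hidden_layers,
            activation=spec.activation,
            solver="lbfgs",
            alpha=spec.l2_penalty,
            max_iter=spec.max_iterations,
            tol=spec.tol,
            random_state=spec.seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                net.fit(Z, y)
            except ConvergenceWarning as exc:  # retry with a fresh init
                last_exc = exc
                continue
        return PropensityModel(
            spec=spec,
            feature_names=feature_names,
            kept_columns=kept,
            scale_offset=offset,
            scale_factor=factor,
            network=net,
            n_restarts_used=attempt,
        )
    raise TrainingError(
        f"network failed to converge after {max_restarts + 1} attempts"
    ) from last_exc


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC by the Mann-Whitney pairwise formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def grid_search_ann(
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence[int],
    grid: Sequence[PropensityModelSpec] = DEFAULT_GRID,
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[PropensityModelSpec, pd.DataFrame]:
    """Pick the architecture with the best stratified k-fold CV AUC.

    Ties break toward fewer total nodes, then fewer layers.  Grid points whose
    training fails are skipped with a warning; if every point fails an error
    is raised.  Returns the winning spec (with the search seed folded in) and
    the per-spec CV table.
    """
    if not grid:
        raise ValueError("empty architecture grid")
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if len(grid) == 1:
        return replace(grid[0], seed=seed), pd.DataFrame(
            {"hidden_layers": [grid[0].hidden_layers], "cv_auc": [np.nan]}
        )

    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise DegenerateLabelError("too few minority-class subjects for CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    records = []
    for spec in grid:
        spec = replace(spec, seed=seed)
        fold_aucs = []
        try:
            for tr_idx, te_idx in folds:
                model = train_ann(X[tr_idx], y[tr_idx], spec)
                p = model.predict_proba(X[te_idx])
                fold_aucs.append(auc_mann_whitney(p, y[te_idx]))
        except (TrainingError, DegenerateLabelError, ValueError) as exc:
            warnings.warn(f"grid point {spec.hidden_layers} skipped: {exc}")
            continue
        records.append(
            {
                "hidden_layers": spec.hidden_layers,
                "n_layers": len(spec.hidden_layers),
                "total_nodes": spec.total_nodes,
                "cv_auc": float(np.mean(fold_aucs)),
            }
        )
    if not records:
        raise TrainingError("every grid point failed to train")
    table = pd.DataFrame(records)
    best = table.sort_values(
        by=["cv_auc", "total_nodes", "n_layers"],
        ascending=[False, True, True],
        kind="mergesort",
    ).iloc[0]
    return (
        replace(PropensityModelSpec(hidden_layers=tuple(best["hidden_layers"])), seed=seed),
        table,
    )


def bootstrap_roc(
    model: PropensityModel | None,
    X_val: pd.DataFrame | np.ndarray,
    y_val: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    scores: np.ndarray | None = None,
    refit_train: tuple[np.ndarray, np.ndarray] | None = None,
) -> RocResult:
    """Validation AUC with a stratified-bootstrap percentile 95% CI.

    By default the model is *not* refit per resample: held-out predictions
    are computed once and the (score, label) pairs are resampled within each
    class, so every resample retains both classes.  Passing ``refit_train``
    (the training features and labels) switches to the expensive variant
    that refits the network on a stratified resample of the training set for
    every bootstrap iteration and re-scores the fixed validation set.
    """
    y = np.asarray(y_val, dtype=int)
    if scores is None:
        if model is None:
            raise ValueError("either a model or precomputed scores is required")
        scores = model.predict_proba(np.asarray(X_val, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("validation set needs both classes")

    if refit_train is not None:
        return _bootstrap_roc_refit(
            model, refit_train, np.asarray(X_val, dtype=float), y, scores,
            n_boot, seed,
        )

    point_auc = auc_mann_whitney(scores, y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    rng = np.random.default_rng(seed)
    # vectorized: ranks of resampled positives among resampled negatives
    pos_idx = rng.integers(0, len(pos), size=(n_boot, len(pos)))
    neg_idx = rng.integers(0, len(neg), size=(n_boot, len(neg)))
    P = pos[pos_idx][:, :, None]
    N = neg[neg_idx][:, None, :]
    wins = (P > N).sum(axis=(1, 2)) + 0.5 * (P == N).sum(axis=(1, 2))
    aucs = wins / (len(pos) * len(neg))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(auc=point_auc, ci_lower=float(lo), ci_upper=float(hi), n_boot=n_boot)


def _bootstrap_roc_refit(
    model: PropensityModel,
    refit_train: tuple[np.ndarray, np.ndarray],
    X_val: np.ndarray,
    y_val: np.ndarray,
    point_scores: np.ndarray,
    n_boot: int,
    seed: int,
) -> RocResult:
    """Refit-per-resample bootstrap: stratified resamples of the training set,
    a fresh network per resample, AUC of its predictions on the fixed
    validation set."""
    X_tr = np.asarray(refit_train[0], dtype=float)
    y_tr = np.asarray(refit_train[1], dtype=int)
    pos = np.flatnonzero(y_tr == 1)
    neg = np.flatnonzero(y_tr == 0)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        spec = replace(model.spec, seed=int(rng.integers(2**31)))
        refit = train_ann(X_tr[idx], y_tr[idx], spec)
        aucs[b] = auc_mann_whitney(refit.predict_proba(X_val), y_val)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(
        auc=auc_mann_whitney(point_scores, y_val),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
    )


def validate_model(roc: RocResult) -> bool:
    """Model qualifies only if the CI lower bound strictly exceeds 0.5."""
    return roc.ci_lower > 0.5


@dataclass(frozen=True)
class PropensityScores:
    """Per-subject placebo-response probability and analysis weight."""

    table: pd.DataFrame  # columns: subject_id, arm, p, w_raw, w
    p_floor: float
    renormalized: bool

    def weight_for(self, subject_id: str) -> float:
        row = self.table.loc[self.table["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return float(row["w"].iloc[0])


def predict_propensity(
    model: PropensityModel,
    subjects: Sequence[SubjectTrajectory],
    scale: ScaleDefinition,
    p_floor: float = 0.05,
    renormalize: bool = True,
) -> tuple[PropensityScores, list[str]]:
    """Score every randomized subject and build inverse-probability weights.

    ``w_raw = 1 / max(p, p_floor)``; with ``renormalize`` (default) the final
    weights are rescaled to mean one, which leaves the weighted longitudinal
    estimator unchanged while keeping the weight scale interpretable.  Returns
    the scores and the ids of subjects excluded for missing pre-randomization
    visits.
    """
    if not 0.0 < p_floor < 1.0:
        raise ValueError("p_floor must be in (0, 1)")
    deltas = build_item_delta_matrix(subjects, scale)
    all_ids = [s.subject_id for s in subjects]
    excluded = sorted(set(all_ids) - set(deltas.index))
    arm_of = {s.subject_id: s.arm for s in subjects}

    p = model.predict_proba(deltas.to_numpy())
    w_raw = 1.0 / np.maximum(p, p_floor)
    w = w_raw / w_raw.mean() if renormalize else w_raw.copy()
    table = pd.DataFrame(
        {
            "subject_id": deltas.index.to_numpy(),
            "arm": [arm_of[i] for i in deltas.index],
            "p": p,
            "w_raw": w_raw,
            "w": w,
        }
    ).reset_index(drop=True)
    return PropensityScores(table=table, p_floor=p_floor, renormalized=renormalize), excluded


def propensity_distribution(scores: PropensityScores) -> pd.DataFrame:
    """Per-arm proportions of subjects in the five propensity bins.

    Bins are [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1]; each arm's
    proportions sum to one.  Empty arms are omitted with a warning.
    """
    frame = scores.table
    if frame.empty:
        raise ValueError("no propensity scores to bin")
    out = {}
    for arm, g in frame.groupby("arm", sort=True):
        if g.empty:  # defensive; groupby drops truly empty arms
            warnings.warn(f"arm {arm!r} has no scored subjects; omitted")
            continue
        counts, _ = np.histogram(g["p"].to_numpy(), bins=PROPENSITY_BINS)
        out[arm] = counts / counts.sum()
    return pd.DataFrame(out, index=list(_BIN_LABELS)).T
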