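"""Three-model class-weighted probability-voting ensemble.

A random forest, an RBF-kernel SVM and a gradient-boosted tree model are
trained on the (filtered) feature matrix — the SVM on a further RFE-reduced
subset, the tree models on the full filtered set, since they select
features internally. Their class probabilities are combined with six
non-negative class weights (w1,w2 RF; w3,w4 XGB; w5,w6 SVM):

    score(AHTP) = w1*P_RF(AHTP) + w3*P_XGB(AHTP) + w5*P_SVM(AHTP)
    score(non)  = w2*P_RF(non)  + w4*P_XGB(non)  + w6*P_SVM(non)
    P_ens(AHTP) = score(AHTP) / (score(AHTP) + score(non))

and the peptide is called AHTP when P_ens >= 0.5 (ties go to AHTP — a
screening tool favors sensitivity). The weight set is found by exhaustive
grid search maximizing a cross-validated objective on held-out data.

Base-model hyperparameters default to the published values: RF 350 trees,
depth 12; SVM C=36.0, gamma=0.119; XGB 800 rounds, depth 10, eta 0.01,
subsample 0.8.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureMatrix
from .peptide_io import NEGATIVE_LABEL, POSITIVE_LABEL
from .selection import apply_cutoff, relieff_scores, rfe_select

MODEL_ORDER = ("RF", "XGB", "SVM")


def labels_to_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    return (arr == POSITIVE_LABEL).astype(int)


@dataclass(frozen=True)
class BaseModelSpec:
    """Kind and hyperparameters of one ensemble member."""

    kind: str
    params: dict = field(default_factory=dict)

    @staticmethod
    def defaults() -> dict[str, "BaseModelSpec"]:
        return {
            "RF": BaseModelSpec("RF", {"n_estimators": 350, "max_depth": 12}),
            "SVM": BaseModelSpec("SVM", {"C": 36.0, "kernel": "rbf",
                                         "gamma": 0.119}),
            "XGB": BaseModelSpec("XGB", {"n_estimators": 800, "max_depth": 10,
                                         "learning_rate": 0.01,
                                         "subsample": 0.8}),
        }

    def build(self, seed: int = 0):
        if self.kind == "RF":
            return RandomForestClassifier(random_state=seed, n_jobs=1,
                                          **self.params)
        if self.kind == "SVM":
            # the RBF kernel needs commensurate feature scales: raw blocks
            # span orders of magnitude, and with hundreds of features the
            # stated gamma only leaves usable kernel values for [0,1]-scaled
            # inputs. Sigmoid (Platt) probability calibration on internal
            # folds.
            return make_pipeline(
                MinMaxScaler(),
                CalibratedClassifierCV(SVC(random_state=seed, **self.params),
                                       method="sigmoid", cv=5,
                                       ensemble=False))
        if self.kind == "XGB":
            # 64 histogram bins: a numerical discretisation choice that keeps
            # single-core training fast without touching the stated
            # hyperparameters (rounds, depth, eta, subsample)
            return XGBClassifier(random_state=seed, n_jobs=1,
                                 tree_method="hist", max_bin=64,
                                 eval_metric="logloss", **self.params)
        raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass(frozen=True)
class WeightSet:
    """Six class weights (w1,w2)=RF, (w3,w4)=XGB, (w5,w6)=SVM, max-normalised."""

    w: tuple[float, float, float, float, float, float]

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape != (6,):
            raise ValueError("need exactly six weights")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.all(w == 0):
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "w", tuple(float(x) for x in w / w.max()))

    @property
    def positive(self) -> np.ndarray:  # (w1, w3, w5)
        return np.array(self.w[0::2])

    @property
    def negative(self) -> np.ndarray:  # (w2, w4, w6)
        return np.array(self.w[1::2])


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = labels_to_binary(y_true)
        yp = labels_to_binary(y_pred)
        return cls(TP=int(((yt == 1) & (yp == 1)).sum()),
                   TN=int(((yt == 0) & (yp == 0)).sum()),
                   FP=int(((yt == 0) & (yp == 1)).sum()),
                   FN=int(((yt == 1) & (yp == 0)).sum()))

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def evaluate_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, Sn, Sp and MCC from confusion counts.

    A metric whose denominator is zero is reported as None (undefined), not
    as 0 — except MCC, which takes the conventional value 0 when any
    marginal is empty (the degenerate-predictor limit).
    """
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise ValueError("empty confusion table")
    out: dict[str, float | None] = {"ACC": (c.TP + c.TN) / total}
    out["Sn"] = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    out["Sp"] = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom == 0:
        out["MCC"] = 0.0
    else:
        out["MCC"] = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    return out


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (trapezoidal over all thresholds; tie-averaged) and ROC points."""
    yb = labels_to_binary(labels)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(yb, np.asarray(scores, dtype=float))
    return float(_sk_auc(fpr, tpr)), fpr, tpr


@dataclass
class EnsembleModel:
    """Trained base models, their feature subsets, and the voting weights."""

    models: dict  # kind -> fitted classifier
    weights: WeightSet
    schema_hash: str
    feature_subsets: dict  # kind -> list of column indices into the schema
    feature_names: tuple[str, ...]
    seed: int = 0

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        """n x 3 matrix of P(AHTP) per base model, in RF, XGB, SVM order."""
        X = np.asarray(X, dtype=float)
        cols = []
        for kind in MODEL_ORDER:
            sub = self.feature_subsets[kind]
            proba = self.models[kind].predict_proba(X[:, sub])
            cols.append(proba[:, 1])
        return np.column_stack(cols)

    def predict_matrix(self, X: np.ndarray) -> dict[str, np.ndarray]:
        P = self.base_probabilities(X)
        prob = ensemble_probability(P, self.weights)
        labels = np.where(prob >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
        return {"P_RF": P[:, 0], "P_XGB": P[:, 1], "P_SVM": P[:, 2],
                "P_ensemble": prob, "label": labels}

    def predict_vector(self, v, schema_hash: str | None = None) -> dict:
        """Predict one feature vector; refuses mismatched schemas."""
        vh = schema_hash if schema_hash is not None else v.schema.hash
        if vh != self.schema_hash:
            raise ValueError(
                f"schema hash mismatch: model {self.schema_hash}, input {vh}")
        res = self.predict_matrix(v.values[None, :])
        return {k: (val[0] if isinstance(val, np.ndarray) else val)
                for k, val in res.items()}

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {"schema_hash": self.schema_hash, "weights": list(self.weights.w),
                "feature_subsets": {k: list(map(int, v))
                                    for k, v in self.feature_subsets.items()},
                "feature_names": list(self.feature_names), "seed": self.seed}
        (d / "metadata.json").write_text(json.dumps(meta, indent=1))
        for kind, model in self.models.items():
            joblib.dump(model, d / f"model_{kind}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        models = {k: joblib.load(d / f"model_{k}.joblib") for k in MODEL_ORDER}
        return cls(models=models, weights=WeightSet(tuple(meta["weights"])),
                   schema_hash=meta["schema_hash"],
                   feature_subsets={k: list(v) for k, v in
                                    meta["feature_subsets"].items()},
                   feature_names=tuple(meta["feature_names"]),
                   seed=meta["seed"])


def ensemble_probability(P: np.ndarray, weights: WeightSet) -> np.ndarray:
    """Weighted-voting probability from an n x 3 P(AHTP) matrix."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    pos = P @ weights.positive
    neg = (1.0 - P) @ weights.negative
    denom = pos + neg
    # a zero denominator needs one class's weights all zero AND degenerate
    # base probabilities; treat as maximal uncertainty
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, pos / np.where(denom > 0, denom, 1.0), 0.5)


def train_base_models(X: np.ndarray, y, svm_features: list[int] | None = None,
                      specs: dict[str, BaseModelSpec] | None = None,
                      seed: int = 0) -> tuple[dict, dict]:
    """Fit the three base classifiers; returns (models, feature_subsets)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    yb = labels_to_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")
    specs = specs or BaseModelSpec.defaults()
    full = list(range(X.shape[1]))
    subsets = {"RF": full, "XGB": full,
               "SVM": list(svm_features) if svm_features is not None else full}
    models = {}
    for kind in MODEL_ORDER:
        est = specs[kind].build(seed)
        est.fit(X[:, subsets[kind]], yb)
        models[kind] = est
    return models, subsets


def _weight_grid(resolution: float = 0.1) -> np.ndarray:
    """All six-weight combinations on the grid with max weight = 1.

    Normalisation symmetry (scores scale linearly in the weights) means any
    candidate is equivalent to its max-normalised form, so only candidates
    whose largest weight equals 1 are enumerated.
    """
    levels = np.round(np.arange(0.0, 1.0 + 1e-9, resolution), 10)
    grids = np.meshgrid(*[levels] * 6, indexing="ij")
    W = np.stack([g.ravel() for g in grids], axis=1)
    return W[np.isclose(W.max(axis=1), 1.0)]


def optimize_weights(P: np.ndarray, y, grid: np.ndarray | None = None,
                     objective: str = "accuracy", folds: int = 10,
                     seed: int = 0, chunk: int = 20000) -> WeightSet:
    """Exhaustive grid search for the voting weight set.

    ``P`` is the n x 3 matrix of base-model P(AHTP) on held-out data. The
    objective is the mean over ``folds`` stratified partitions of per-fold
    accuracy or MCC. Ties are broken by smaller weight-vector norm, then
    lexicographically.
    """
    P = np.asarray(P, dtype=float)
    yb = labels_to_binary(y)
    if grid is None:
        grid = _weight_grid(0.1)
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty weight grid")
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")

    n_splits = min(folds, np.bincount(yb).min())
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_idx = [test for _, test in skf.split(P, yb)]

    obj = np.empty(len(grid))
    for start in range(0, len(grid), chunk):
        W = grid[start:start + chunk]
        pos = P @ W[:, 0::2].T          # n x c
        neg = (1.0 - P) @ W[:, 1::2].T
        denom = pos + neg
        prob = np.where(denom > 0, pos / np.where(denom > 0, denom, 1.0), 0.5)
        pred = (prob >= 0.5)
        if objective == "accuracy":
            vals = np.zeros(len(W))
            for idx in fold_idx:
                vals += (pred[idx] == (yb[idx] == 1)[:, None]).mean(0)
            obj[start:start + chunk] = vals / len(fold_idx)
        elif objective == "MCC":
            vals = np.zeros(len(W))
            for idx in fold_idx:
                yt = yb[idx] == 1
                tp = (pred[idx] & yt[:, None]).sum(0).astype(float)
                fp = (pred[idx] & ~yt[:, None]).sum(0).astype(float)
                fn = (~pred[idx] & yt[:, None]).sum(0).astype(float)
                tn = (~pred[idx] & ~yt[:, None]).sum(0).astype(float)
                denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
                mcc = np.where(denom > 0, (tp * tn - fp * fn) /
                               np.where(denom > 0, denom, 1.0), 0.0)
                vals += mcc
            obj[start:start + chunk] = vals / len(fold_idx)
        else:
            raise ValueError(f"unknown objective {objective!r}")

    best = obj.max()
    cand = np.flatnonzero(np.isclose(obj, best))
    norms = np.linalg.norm(grid[cand], axis=1)
    cand = cand[np.isclose(norms, norms.min())]
    rows = [tuple(grid[i]) for i in cand]
    return WeightSet(min(rows))


@dataclass
class PipelineConfig:
    """End-to-end training configuration.

    ReliefF filtering keeps features with positive relevance; the SVM input
    is further reduced by RFE (linear-surrogate importance by default, with
    a coarse elimination step for speed); the weight grid resolution is 0.1.
    """

    relieff_k: int = 10
    relieff_n_samples: int | None = 400
    relieff_cutoff: float = 0.0
    rfe_target_fraction: float = 256 / 379
    rfe_step: int = 16
    rfe_importance: str = "linear"
    weight_resolution: float = 0.1
    objective: str = "accuracy"
    val_fraction: float = 0.25
    weight_folds: int = 10


def train_ensemble(X: np.ndarray, y, feature_names=None,
                   config: PipelineConfig | None = None,
                   schema_hash: str = "", seed: int = 0) -> EnsembleModel:
    """Full training pipeline: filter, RFE, base models, weight search.

    Feature selection and weight optimisation happen inside the training
    data only: weights are searched on an internal stratified validation
    split, after which the base models are refitted on all training rows.
    """
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    yb = labels_to_binary(y)
    p = X.shape[1]
    feature_names = (tuple(feature_names) if feature_names is not None
                     else tuple(f"f{i}" for i in range(p)))

    scores = relieff_scores(X, yb, names=feature_names,
                            k_neighbors=cfg.relieff_k,
                            n_samples=cfg.relieff_n_samples, seed=seed)
    kept = apply_cutoff(scores, cutoff=cfg.relieff_cutoff)
    Xk = X[:, kept]

    target_k = max(1, int(round(len(kept) * cfg.rfe_target_fraction)))
    svm_local = rfe_select(Xk, yb, step=cfg.rfe_step, target_k=target_k,
                           importance=cfg.rfe_importance, seed=seed)
    svm_subset = [kept[j] for j in svm_local]

    Xtr, Xval, ytr, yval = train_test_split(
        X, yb, test_size=cfg.val_fraction, random_state=seed, stratify=yb)
    sub_map = {"RF": kept, "XGB": kept, "SVM": svm_subset}
    probe_models = {}
    for kind in MODEL_ORDER:
        est = BaseModelSpec.defaults()[kind].build(seed)
        est.fit(Xtr[:, sub_map[kind]], ytr)
        probe_models[kind] = est
    Pval = np.column_stack([probe_models[k].predict_proba(Xval[:, sub_map[k]])[:, 1]
                            for k in MODEL_ORDER])
    weights = optimize_weights(Pval, yval, grid=_weight_grid(cfg.weight_resolution),
                               objective=cfg.objective, folds=cfg.weight_folds,
                               seed=seed)

    models = {}
    for kind in MODEL_ORDER:
        est = BaseModelSpec.defaults()[kind].build(seed)
        est.fit(X[:, sub_map[kind]], yb)
        models[kind] = est
    return EnsembleModel(models=models, weights=weights, schema_hash=schema_hash,
                         feature_subsets=sub_map, feature_names=feature_names,
                         seed=seed)


def cross_validate(X: np.ndarray, y, config: PipelineConfig | None = None,
                   folds: int = 10, seed: int = 0) -> dict:
    """Stratified k-fold evaluation of the full pipeline (no leakage).

    Selection and weight optimisation are refitted inside every training
    fold. Returns per-fold metrics, the pooled confusion counts and pooled
    metrics, plus the pooled AUC of the ensemble probability.
    """
    X = np.asarray(X, dtype=float)
    yb = labels_to_binary(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts()
    per_fold = []
    all_scores = np.empty(len(yb))
    for tr, te in skf.split(X, yb):
        model = train_ensemble(X[tr], yb[tr], config=config, seed=seed)
        res = model.predict_matrix(X[te])
        c = ConfusionCounts.from_predictions(yb[te], res["label"])
        pooled = pooled + c
        per_fold.append(evaluate_metrics(c))
        all_scores[te] = res["P_ensemble"]
    auc_val, _, _ = roc_auc(all_scores, yb)
    return {"per_fold": per_fold, "pooled_counts": pooled,
            "pooled": evaluate_metrics(pooled), "AUC": auc_val,
            "fold_assignment_seed": seed}
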