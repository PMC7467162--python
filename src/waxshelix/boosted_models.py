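"""Gradient-boosted tree models mapping log-intensity spectra to descriptors.

One boosted regressor per continuous descriptor (squared-error objective)
and one 12-class softmax classifier for the A-form fraction, trained on the
conformation-grouped splits of a :class:`~waxshelix.dataset_builder.LabeledDataset`.
The module also provides the five training variants (noise-free, noisy,
sparsely/densely sampled, random-label control), conformation-grouped
k-fold cross-validation with a reduced tree count, learning-curve /
under-sampling / noise studies, linear baselines, and the two
feature-importance traces (gain and weight) mapped back onto the q grid.

Boosting minimizes a regularized objective: the data loss plus per-tree
penalties on leaf count (``min_split_loss``), and on the L1/L2 norms of
the leaf weights (``reg_alpha`` / ``reg_lambda``).  The final prediction
is the sum of all tree outputs.  Hyperparameters live in one
:class:`TrainingConfig` and are config-overridable; training is
deterministic given a config, a seed and a dataset (single-threaded
histogram tree construction).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.metrics import accuracy_score, confusion_matrix, mean_squared_error, r2_score
from sklearn.model_selection import GroupKFold
from xgboost import XGBClassifier, XGBRegressor

from . import dataset_builder as db
from .descriptors import CLASSIFIER_DESCRIPTOR, DESCRIPTOR_NAMES, REGRESSION_DESCRIPTORS
from .scattering import QGrid

N_AFORM_CLASSES = 12


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    """Centralized, overridable boosting hyperparameters."""

    n_trees_cv: int = 750
    n_trees_final: int = 7500
    early_stopping_patience: int = 50
    learning_rate: float = 0.1
    max_depth: int = 6
    min_split_loss: float = 0.0   # penalty per additional leaf (xgboost gamma)
    reg_alpha: float = 0.0        # L1 on leaf weights
    reg_lambda: float = 1.0       # L2 on leaf weights
    seed: int = 0
    noise_level: float = 0.05     # the 'noisy' variant (S/N = 20)
    sparse_points: int = 100
    dense_points: int = 400

    def __post_init__(self):
        if self.n_trees_cv < 1 or self.n_trees_final < 1:
            raise ModelError("tree counts must be positive")
        if self.early_stopping_patience < 1:
            raise ModelError("early-stopping patience must be positive")

    def _estimator(self, task: str, n_trees: int, early_stopping: bool):
        common = dict(
            n_estimators=n_trees,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            gamma=self.min_split_loss,
            reg_alpha=self.reg_alpha,
            reg_lambda=self.reg_lambda,
            random_state=self.seed,
            tree_method="hist",
            n_jobs=1,
            early_stopping_rounds=self.early_stopping_patience if early_stopping else None,
        )
        if task == "regression":
            return XGBRegressor(objective="reg:squarederror", **common)
        return XGBClassifier(objective="multi:softprob", **common)


VARIANTS = ("noise-free", "noisy", "sparse", "dense", "random")


@dataclass
class ModelBundle:
    """A trained ensemble plus its frozen evaluation report."""

    descriptor: str
    task: str                      # 'regression' | 'classification'
    variant: str
    model: object
    config: TrainingConfig
    qgrid: QGrid
    report: dict
    classes: np.ndarray | None = None  # original class values, encoded 0..m-1

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != len(self.qgrid):
            raise ModelError(
                f"feature width {features.shape[1]} does not match the model's "
                f"{len(self.qgrid)}-point q grid; resample explicitly"
            )
        pred = self.model.predict(features)
        if self.classes is not None:
            pred = self.classes[pred]
        return pred


def task_for(descriptor: str) -> str:
    if descriptor == CLASSIFIER_DESCRIPTOR:
        return "classification"
    if descriptor in REGRESSION_DESCRIPTORS:
        return "regression"
    raise ModelError(f"unknown descriptor {descriptor!r}; choose from {DESCRIPTOR_NAMES}")


def _xy(dataset: db.LabeledDataset, descriptor: str, tag: str):
    idx = dataset.rows(tag)
    y = dataset.labels[descriptor].to_numpy()[idx]
    if descriptor == CLASSIFIER_DESCRIPTOR:
        y = y.astype(int)
    return dataset.features[idx], y


def _metric(task: str, y_true, y_pred) -> float:
    if task == "regression":
        return float(mean_squared_error(y_true, y_pred))
    return float(accuracy_score(y_true, y_pred))


def _discretize(y: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.clip(np.digitize(y, edges[1:-1]), 0, len(edges) - 2)


def train(
    dataset: db.LabeledDataset,
    descriptor: str,
    config: TrainingConfig = TrainingConfig(),
    variant: str = "noise-free",
) -> ModelBundle:
    """Fit on train rows, early-stop on validation loss, report on test once.

    The held-out rows are verified against the hash fixed at split time
    before the final evaluation; a dataset without split tags is rejected.
    """
    task = task_for(descriptor)
    if not (dataset.split != "").all() or not len(dataset.rows("train")):
        raise ModelError("dataset must carry train/validation/test split tags")
    X_tr, y_tr = _xy(dataset, descriptor, "train")
    X_val, y_val = _xy(dataset, descriptor, "validation")
    est = config._estimator(task, config.n_trees_final, early_stopping=True)
    classes = None
    if task == "classification":
        # boosted softmax needs contiguous 0..m-1 targets covering y_train;
        # encode over the train classes and decode all predictions.
        # Validation rows of a class absent from training (possible on very
        # small ensembles) cannot enter the early-stopping loss.
        classes = np.unique(y_tr)
        enc = {c: i for i, c in enumerate(classes)}
        val_seen = np.isin(y_val, classes)
        eval_X = X_val[val_seen] if val_seen.any() else X_tr
        eval_y = y_val[val_seen] if val_seen.any() else y_tr
        est.fit(
            X_tr,
            np.array([enc[v] for v in y_tr]),
            eval_set=[(eval_X, np.array([enc[v] for v in eval_y]))],
            verbose=False,
        )
    else:
        est.fit(X_tr, y_tr, eval_set=[(X_val, y_val)], verbose=False)

    db.verify_test_integrity(dataset)
    X_te, y_te = _xy(dataset, descriptor, "test")
    pred_tr, pred_val, pred_te = (est.predict(x) for x in (X_tr, X_val, X_te))
    if classes is not None:
        pred_tr, pred_val, pred_te = (classes[p] for p in (pred_tr, pred_val, pred_te))
    report = {
        "descriptor": descriptor,
        "task": task,
        "variant": variant,
        "n_trees_limit": config.n_trees_final,
        "best_iteration": int(getattr(est, "best_iteration", config.n_trees_final)),
        "n_features": int(dataset.features.shape[1]),
        "n_train_rows": int(len(y_tr)),
    }
    if task == "regression":
        report.update(
            train_mse=_metric(task, y_tr, pred_tr),
            validation_mse=_metric(task, y_val, pred_val),
            test_mse=_metric(task, y_te, pred_te),
            test_r2=float(r2_score(y_te, pred_te)),
            label_variance=float(np.var(dataset.labels[descriptor].to_numpy())),
        )
        edges = np.linspace(min(y_tr.min(), y_te.min()),
                            max(y_tr.max(), y_te.max()), 11)
        report["test_confusion_discretized"] = confusion_matrix(
            _discretize(y_te, edges), _discretize(pred_te, edges),
            labels=np.arange(10),
        ).tolist()
    else:
        report.update(
            train_accuracy=_metric(task, y_tr, pred_tr),
            validation_accuracy=_metric(task, y_val, pred_val),
            test_accuracy=_metric(task, y_te, pred_te),
        )
        report["test_confusion"] = confusion_matrix(
            y_te, pred_te, labels=np.arange(N_AFORM_CLASSES)
        ).tolist()
    return ModelBundle(
        descriptor=descriptor,
        task=task,
        variant=variant,
        model=est,
        config=config,
        qgrid=dataset.qgrid,
        report=report,
        classes=classes,
    )


def train_variants(
    dataset: db.LabeledDataset,
    descriptor: str,
    config: TrainingConfig = TrainingConfig(),
) -> dict[str, ModelBundle]:
    """The five training variants of one descriptor."""
    out = {}
    out["noise-free"] = train(dataset, descriptor, config, variant="noise-free")
    # noise goes into the training rows only; validation and test stay clean
    noisy = db.add_noise(dataset, config.noise_level, seed=config.seed,
                         tags=("train",))
    out["noisy"] = train(noisy, descriptor, config, variant="noisy")
    sparse = db.resample_qgrid(dataset, config.sparse_points)
    out["sparse"] = train(sparse, descriptor, config, variant="sparse")
    dense = db.resample_qgrid(dataset, config.dense_points)
    out["dense"] = train(dense, descriptor, config, variant="dense")
    randomized = db.randomize_labels(dataset, seed=config.seed)
    out["random"] = train(randomized, descriptor, config, variant="random")
    return out


def cross_validate(
    dataset: db.LabeledDataset,
    descriptor: str,
    k: int = 10,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[float, float, list[float]]:
    """Conformation-grouped k-fold CV with the reduced tree count.

    Folds partition conformations (never rows) over the train+validation
    portion, the same grouping principle as the main split; each fold fits
    a fixed ``n_trees_cv``-tree ensemble.  Returns (mean, sd, fold metrics)
    where the metric is MSE for regressors and accuracy for the classifier.
    """
    task = task_for(descriptor)
    idx = np.concatenate([dataset.rows("train"), dataset.rows("validation")])
    groups = dataset.groups[idx]
    if k > len(np.unique(groups)):
        raise ModelError(f"k={k} exceeds the {len(np.unique(groups))} conformations")
    X = dataset.features[idx]
    y = dataset.labels[descriptor].to_numpy()[idx]
    if task == "classification":
        y = y.astype(int)
    scores = []
    for tr, te in GroupKFold(n_splits=k).split(X, y, groups):
        est = config._estimator(task, config.n_trees_cv, early_stopping=False)
        if task == "classification":
            classes = np.unique(y[tr])
            enc = {c: i for i, c in enumerate(classes)}
            est.fit(X[tr], np.array([enc[v] for v in y[tr]]), verbose=False)
            scores.append(_metric(task, y[te], classes[est.predict(X[te])]))
        else:
            est.fit(X[tr], y[tr], verbose=False)
            scores.append(_metric(task, y[te], est.predict(X[te])))
    return float(np.mean(scores)), float(np.std(scores)), scores


def learning_curve(
    dataset: db.LabeledDataset,
    descriptor: str,
    sizes: Sequence[int],
    config: TrainingConfig = TrainingConfig(),
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Test metric versus number of training profiles, fixed test set.

    ``sizes`` count profiles (rows); each subset keeps whole conformations.
    """
    if list(sizes) != sorted(sizes):
        raise ModelError("sizes must be ascending")
    n_cond = int(dataset.meta.get("n_conditions", 1))
    train_ids = np.unique(dataset.groups[dataset.rows("train")])
    records = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(train_ids)
        for size in sizes:
            n_conf = max(1, size // n_cond)
            if n_conf > len(train_ids):
                raise ModelError(f"size {size} exceeds the training pool")
            keep = set(order[:n_conf]) | set(
                np.unique(dataset.groups[dataset.rows("validation")])
            ) | set(np.unique(dataset.groups[dataset.rows("test")]))
            sub = dataset.subset_conformations(sorted(keep))
            sub.meta["test_hash"] = db._test_hash(sub)
            bundle = train(sub, descriptor, replace(config, seed=seed))
            key = "test_mse" if bundle.task == "regression" else "test_accuracy"
            train_key = "train_mse" if bundle.task == "regression" else "train_accuracy"
            records.append(
                {
                    "n_profiles": n_conf * n_cond,
                    "seed": seed,
                    "test_metric": bundle.report[key],
                    "train_metric": bundle.report[train_key],
                }
            )
    return pd.DataFrame(records)


def shannon_channels(qmax: float, dmax: float) -> float:
    """Number of independent information channels, n_s = q_max * D_max / pi."""
    return qmax * dmax / np.pi


def undersampling_study(
    dataset: db.LabeledDataset,
    descriptor: str,
    n_points_list: Sequence[int],
    config: TrainingConfig = TrainingConfig(),
) -> tuple[pd.DataFrame, float]:
    """Metric versus q-resolution, with the ensemble's Shannon channel count."""
    n_s = shannon_channels(dataset.qgrid.qmax, float(dataset.meta["dmax"]))
    records = []
    for n_points in n_points_list:
        sub = db.resample_qgrid(dataset, n_points)
        bundle = train(sub, descriptor, config)
        key = "test_mse" if bundle.task == "regression" else "test_accuracy"
        records.append({"n_points": n_points, "test_metric": bundle.report[key]})
    return pd.DataFrame(records), float(n_s)


def noise_study(
    dataset: db.LabeledDataset,
    descriptor: str,
    levels: Sequence[float],
    config: TrainingConfig = TrainingConfig(),
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Train/validation/test metrics per injected noise level."""
    records = []
    for seed in seeds:
        for level in levels:
            noisy = (db.add_noise(dataset, level, seed=seed, tags=("train",))
                     if level else dataset)
            bundle = train(noisy, descriptor, replace(config, seed=seed))
            prefix = "mse" if bundle.task == "regression" else "accuracy"
            records.append(
                {
                    "level": level,
                    "seed": seed,
                    "train_metric": bundle.report[f"train_{prefix}"],
                    "validation_metric": bundle.report[f"validation_{prefix}"],
                    "test_metric": bundle.report[f"test_{prefix}"],
                }
            )
    return pd.DataFrame(records)


def linear_baselines(
    dataset: db.LabeledDataset,
    descriptor: str,
    ridge_alpha: float = 1.0,
    lasso_alpha: float = 1e-3,
) -> dict[str, dict]:
    """Unregularized / ridge / lasso regression under the identical split."""
    if task_for(descriptor) != "regression":
        raise ModelError("linear baselines apply to regression descriptors only")
    X_tr, y_tr = _xy(dataset, descriptor, "train")
    X_te, y_te = _xy(dataset, descriptor, "test")
    X_val, y_val = _xy(dataset, descriptor, "validation")
    models = {
        "linear": LinearRegression(),
        "ridge": Ridge(alpha=ridge_alpha),
        "lasso": Lasso(alpha=lasso_alpha, max_iter=50_000),
    }
    out = {}
    for name, est in models.items():
        est.fit(X_tr, y_tr)
        out[name] = {
            "train_mse": float(mean_squared_error(y_tr, est.predict(X_tr))),
            "validation_mse": float(mean_squared_error(y_val, est.predict(X_val))),
            "test_mse": float(mean_squared_error(y_te, est.predict(X_te))),
            "coefficients": est.coef_.tolist(),
        }
    return out


@dataclass(frozen=True)
class ImportanceTrace:
    """Per-q gain and weight importances of one trained ensemble.

    ``gain`` is the total loss improvement contributed by splits on each q
    point; ``weight`` is the number of times each q point is used in a
    decision rule.  Both are normalized to sum to 1.
    """

    qgrid: QGrid
    gain: np.ndarray
    weight: np.ndarray

    def trace(self, kind: str) -> np.ndarray:
        if kind not in ("gain", "weight"):
            raise ModelError("importance kind must be 'gain' or 'weight'")
        return getattr(self, kind)


def importance(bundle: ModelBundle) -> ImportanceTrace:
    """Map tree-library importances back onto the model's q grid."""
    try:
        booster = bundle.model.get_booster()
    except Exception as exc:  # pragma: no cover - defensive
        raise ModelError("model is not trained") from exc
    if booster is None or not getattr(bundle.model, "__sklearn_is_fitted__", lambda: True)():
        raise ModelError("model is not trained")
    n = len(bundle.qgrid)
    traces = {}
    for kind in ("gain", "weight"):
        scores = booster.get_score(importance_type=kind)
        v = np.zeros(n)
        for feat, val in scores.items():
            v[int(feat[1:])] = val
        total = v.sum()
        if total <= 0:
            raise ModelError("ensemble contains no splits; importance undefined")
        traces[kind] = v / total
    return ImportanceTrace(qgrid=bundle.qgrid, gain=traces["gain"], weight=traces["weight"])


# ---------------------------------------------------------------------------
# serialization

def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    """Model file + JSON report + q grid + config snapshot, one directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    # serialize the booster itself (text JSON); the sklearn wrapper is
    # reconstructed at load time and keeps best_iteration
    bundle.model.get_booster().save_model(d / "model.json")
    (d / "report.json").write_text(json.dumps(bundle.report, indent=2))
    np.savetxt(d / "qgrid.txt", bundle.qgrid.values)
    meta = {
        "descriptor": bundle.descriptor,
        "task": bundle.task,
        "variant": bundle.variant,
        "config": asdict(bundle.config),
        "classes": None if bundle.classes is None else bundle.classes.tolist(),
    }
    (d / "bundle.json").write_text(json.dumps(meta, indent=2))


def load_bundle(directory: str | Path) -> ModelBundle:
    d = Path(directory)
    meta = json.loads((d / "bundle.json").read_text())
    cls = XGBClassifier if meta["task"] == "classification" else XGBRegressor
    model = cls()
    model.load_model(d / "model.json")
    return ModelBundle(
        descriptor=meta["descriptor"],
        task=meta["task"],
        variant=meta["variant"],
        model=model,
        config=TrainingConfig(**meta["config"]),
        qgrid=QGrid(np.loadtxt(d / "qgrid.txt")),
        report=json.loads((d / "report.json").read_text()),
        classes=None if meta.get("classes") is None else np.asarray(meta["classes"]),
    )
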