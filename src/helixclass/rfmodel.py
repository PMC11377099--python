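"""Random-forest training, grid-search optimization and deployment.

The optimized configuration carried through the pipeline is 89 trees of
maximum depth 4, sqrt(n_features) candidate features per split, minimum
1 sample per leaf / 2 per internal split, bootstrap disabled.  Deployment
to an unseen gene context evaluates a stratified random 95% of the
unseen rows.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .bench import MetricSet, compute_metrics
from .canal_io import TrajectoryBundle
from .features import (FeatureMatrix, WindowSpec, build_feature_matrix,
                       equilibration_window)

__all__ = [
    "RFParams",
    "OPTIMIZED_PARAMS",
    "FittedModel",
    "DeployReport",
    "default_grid",
    "grid_search",
    "fit_rf",
    "deploy",
    "window_robustness",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters."""

    n_estimators: int = 100
    max_depth: int | None = None
    max_features: str | None = "sqrt"   # sqrt | log2 | all/None
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    bootstrap: bool = True

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")

    def to_estimator(self, seed: int = 0) -> RandomForestClassifier:
        mf = None if self.max_features in (None, "all") else self.max_features
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_features=mf,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            bootstrap=self.bootstrap,
            random_state=seed,
        )


#: Grid-search optimum used throughout the deployment stages.
OPTIMIZED_PARAMS = RFParams(n_estimators=89, max_depth=4, max_features="sqrt",
                            min_samples_leaf=1, min_samples_split=2,
                            bootstrap=False)


def default_grid() -> dict[str, list]:
    """Shipped search grid; contains the optimized configuration."""
    return {
        "n_estimators": [50, 89, 100, 200],
        "max_depth": [2, 4, 8, None],
        "max_features": ["sqrt", "log2"],
        "min_samples_leaf": [1, 2],
        "min_samples_split": [2, 4],
        "bootstrap": [True, False],
    }


def grid_search(X: FeatureMatrix, label: str = "class4",
                grid: dict[str, list] | None = None, folds: int = 10,
                seed: int = 0) -> tuple[RFParams, pd.DataFrame]:
    """Exhaustive cross-validated grid search maximizing mean CV accuracy.

    Candidates are enumerated in grid order (itertools product over the
    mapping's insertion order); ties keep the first maximum.  Returns
    the winning parameter set and the full score table.
    """
    if grid is None:
        grid = default_grid()
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    y = X.labels(label).to_numpy()
    Xv = X.features.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    keys = list(grid.keys())
    best_params, best_score = None, -np.inf
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = RFParams(**dict(zip(keys, combo)))
        score = float(np.mean(cross_val_score(
            params.to_estimator(seed), Xv, y, cv=cv, scoring="accuracy")))
        rows.append({**dict(zip(keys, combo)), "mean_cv_accuracy": score})
        if score > best_score:
            best_score, best_params = score, params
    return best_params, pd.DataFrame(rows)


@dataclass
class FittedModel:
    """A trained forest plus everything needed to deploy it."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    label_name: str
    params: RFParams
    seed: int

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(features.to_numpy(dtype=float))

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(features.to_numpy(dtype=float))

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_,
                         index=self.feature_names)


def fit_rf(X: FeatureMatrix, label: str = "class4",
           params: RFParams = OPTIMIZED_PARAMS, seed: int = 0) -> FittedModel:
    """Train a random forest; deterministic given the seed."""
    y = X.labels(label).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data has a single class")
    est = params.to_estimator(seed)
    est.fit(X.features.to_numpy(dtype=float), y)
    return FittedModel(estimator=est, feature_names=X.feature_names,
                       label_name=label, params=params, seed=seed)


def _stratified_sample(y: np.ndarray, m: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified sample of size m (largest-remainder split)."""
    n = y.size
    classes, counts = np.unique(y, return_counts=True)
    quotas = counts * m / n
    take = np.floor(quotas).astype(int)
    remainder = m - take.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - take), kind="stable")
        for k in order[:remainder]:
            take[k] += 1
    idx = []
    for cls, t in zip(classes, take):
        members = np.flatnonzero(y == cls)
        idx.extend(rng.choice(members, size=min(t, members.size),
                              replace=False))
    return np.sort(np.asarray(idx, dtype=int))


@dataclass
class DeployReport:
    """Evaluation of a trained model on an unseen dataset."""

    dataset_tag: str
    test_fraction: float
    n_evaluated: int
    metrics: MetricSet
    confusion: pd.DataFrame  # rows true class, columns predicted class

    def as_dict(self) -> dict:
        return {
            "dataset_tag": self.dataset_tag,
            "test_fraction": self.test_fraction,
            "n_evaluated": self.n_evaluated,
            "metrics": {k: v for k, v in self.metrics.as_dict().items()
                        if v is not None},
            "confusion": {str(t): {str(c): int(v) for c, v in row.items()}
                          for t, row in self.confusion.iterrows()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def deploy(model: FittedModel, unseen: FeatureMatrix,
           test_fraction: float = 0.95, seed: int = 0) -> DeployReport:
    """Evaluate on a stratified random ceil(fraction * n) of unseen rows.

    Rows are put into a canonical order (by their unique metadata key)
    before sampling, so the evaluated subset — and hence every metric —
    does not depend on the row order of the input matrix.
    """
    missing = [c for c in model.feature_names
               if c not in unseen.features.columns]
    extra = [c for c in unseen.features.columns
             if c not in model.feature_names]
    if missing or extra:
        raise ValueError(f"feature columns mismatch; missing={missing[:5]} "
                         f"extra={extra[:5]}")
    if not 0 < test_fraction <= 1:
        raise ValueError("test_fraction must be in (0, 1]")

    key_cols = ["gene", "site", "adducted", "replicate", "dataset_tag"]
    order = unseen.meta.sort_values(key_cols, kind="stable").index.to_numpy()
    y_all = unseen.labels(model.label_name).to_numpy()[order]
    feats = unseen.features.loc[order, model.feature_names]

    n = len(feats)
    m = math.ceil(test_fraction * n)
    if m == n:
        idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        idx = _stratified_sample(y_all, m, rng)
    y_true = y_all[idx]
    Xs = feats.iloc[idx]
    y_pred = model.predict(Xs)
    scores = model.predict_proba(Xs)
    metrics = compute_metrics(y_true, y_pred, scores, model.classes_)

    classes = list(model.classes_)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    tag = unseen.meta["dataset_tag"].iloc[0] if n else ""
    return DeployReport(dataset_tag=str(tag), test_fraction=test_fraction,
                        n_evaluated=int(len(idx)), metrics=metrics,
                        confusion=conf)


def window_robustness(train_bundle: TrajectoryBundle,
                      unseen_bundle: TrajectoryBundle,
                      params: RFParams = OPTIMIZED_PARAMS,
                      label: str = "class4",
                      window_fraction: float = 0.10,
                      reduced_fraction: float = 0.10,
                      aggregator: str = "mean",
                      test_fraction: float = 0.95,
                      seed: int = 0) -> dict:
    """Convergence check: how much do deployment metrics move when the
    analysis window is shortened by `reduced_fraction` of the span?

    The baseline run drops the leading `window_fraction`; the reduced
    run additionally drops `reduced_fraction` of the span from the tail.
    Both runs train and deploy with identical seeds, so with
    `reduced_fraction` 0 the deltas are exactly zero.
    """
    def _run(extra_tail: float) -> DeployReport:
        def _window(bundle):
            times = bundle.records[0].times
            t0, t1 = float(times[0]), float(times[-1])
            span = t1 - t0
            start = t0 + window_fraction * span
            end = None if extra_tail == 0 else t1 - extra_tail * span
            if end is not None and end <= start:
                raise ValueError("window excludes all frames")
            # end is exclusive; keep the final frame in the baseline run
            return WindowSpec(start, end)

        Xtr = build_feature_matrix(train_bundle, window=_window(train_bundle),
                                   aggregator=aggregator)
        Xun = build_feature_matrix(unseen_bundle,
                                   window=_window(unseen_bundle),
                                   aggregator=aggregator)
        model = fit_rf(Xtr, label, params, seed)
        return deploy(model, Xun, test_fraction, seed)

    baseline = _run(0.0)
    reduced = _run(reduced_fraction)
    deltas = {
        k: reduced.metrics.as_dict()[k] - baseline.metrics.as_dict()[k]
        for k in ("accuracy", "precision", "recall", "f1")
    }
    return {"baseline": baseline, "reduced": reduced, "deltas": deltas}


_MODEL_FORMAT_VERSION = 1


def save_model(model: FittedModel, path) -> None:
    """Persist a fitted model with params, seed and feature manifest."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "feature_names": model.feature_names,
        "label_name": model.label_name,
        "params": asdict(model.params),
        "seed": model.seed,
    }
    joblib.dump(payload, path)


def load_model(path) -> FittedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    return FittedModel(
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        label_name=payload["label_name"],
        params=RFParams(**payload["params"]),
        seed=payload["seed"],
    )
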