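"""Tri-method feature selection and rank-score consolidation.

Three selectors rank the (base, parameter) features of the adducted
subset of the matrix for their ability to separate hotspot from
nonhotspot duplexes:

* cross-validated random-forest impurity importance,
* recursive feature elimination (fold-averaged importances, last
  eliminated = most important),
* L1-regularized (lasso) logistic regression on standardized features.

Each selector's top 10% of features (36 of 357 for the full schema)
receive integer scores top_n..1 (best first); everything else scores 0
and is excluded.  Per-feature scores are summed across the three
selectors into the consolidated ranking, and the selected set is
summarized by parameter nature (rotational vs translational share).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix, parse_feature_name
from .registry import PARAMETERS
from .rfmodel import OPTIMIZED_PARAMS, RFParams

__all__ = [
    "FeatureRanking",
    "ConsolidatedScores",
    "subset_adducted_binary",
    "rank_rf_importance_cv",
    "rank_rfecv",
    "rank_lasso",
    "consolidate",
    "nature_summary",
]


@dataclass
class FeatureRanking:
    """Total order over features, best first."""

    method: str
    features: list[str]
    importances: np.ndarray  # aligned to `features`
    n_rounds: int | None = None  # elimination rounds (RFE only)

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature names must be unique")
        self.importances = np.asarray(self.importances, dtype=float)
        if self.importances.shape != (len(self.features),):
            raise ValueError("importances must align with features")


def subset_adducted_binary(X: FeatureMatrix) -> FeatureMatrix:
    """Adduct-bound rows only, labelled hotspot/nonhotspot."""
    mask = X.meta["adducted"].to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError("no adducted rows in matrix")
    sub = X.select_rows(mask)
    if sub.meta["hotspot"].nunique() < 2:
        raise ValueError("adducted subset contains a single hotspot class")
    return sub


def _ordered_by_importance(columns, importances) -> tuple[list[str], np.ndarray]:
    """Descending importance; ties broken by column order (stable sort)."""
    importances = np.asarray(importances, dtype=float)
    order = np.argsort(-importances, kind="stable")
    cols = list(columns)
    return [cols[i] for i in order], importances[order]


def rank_rf_importance_cv(X: FeatureMatrix, label: str = "hotspot",
                          folds: int = 10, seed: int = 0,
                          params: RFParams = OPTIMIZED_PARAMS
                          ) -> FeatureRanking:
    """Impurity importances averaged over k-fold refits of the forest."""
    y = X.labels(label).to_numpy()
    Xv = X.features.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    imp = np.zeros(Xv.shape[1])
    for train_idx, _ in cv.split(Xv, y):
        est = params.to_estimator(seed)
        est.fit(Xv[train_idx], y[train_idx])
        imp += est.feature_importances_
    imp /= folds
    feats, vals = _ordered_by_importance(X.features.columns, imp)
    return FeatureRanking("rf_importance_cv", feats, vals)


def rank_rfecv(X: FeatureMatrix, label: str = "hotspot", folds: int = 10,
               seed: int = 0, step: int | float = 1,
               params: RFParams = OPTIMIZED_PARAMS) -> FeatureRanking:
    """Recursive feature elimination with fold-averaged importances.

    Each round refits the forest on the surviving features in every CV
    fold, averages the impurity importances, and eliminates the `step`
    weakest features (a float step is a fraction of the starting
    feature count).  The ranking is the reverse of elimination order;
    features removed in the same round are ordered by their importance
    at removal, so the order is total even with step > 1.
    """
    y = X.labels(label).to_numpy()
    Xv = X.features.to_numpy(dtype=float)
    columns = list(X.features.columns)
    cv = list(StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed).split(Xv, y))

    n_total = Xv.shape[1]
    if isinstance(step, float) and step != int(step):
        if not 0 < step < 1:
            raise ValueError("fractional step must be in (0, 1)")
        step_size = max(1, int(step * n_total))
    else:
        step_size = max(1, int(step))

    surviving = list(range(n_total))
    eliminated: list[tuple[int, float]] = []  # worst first
    n_rounds = 0
    while surviving:
        n_rounds += 1
        imp = np.zeros(len(surviving))
        for train_idx, _ in cv:
            est = params.to_estimator(seed)
            est.fit(Xv[np.ix_(train_idx, surviving)], y[train_idx])
            imp += est.feature_importances_
        imp /= len(cv)
        k = min(step_size, len(surviving))
        # weakest first within the round; ties keep column order
        order = np.argsort(imp, kind="stable")
        drop = order[:k]
        for pos in sorted(drop, key=lambda p: (imp[p], surviving[p])):
            eliminated.append((surviving[pos], float(imp[pos])))
        surviving = [s for i, s in enumerate(surviving) if i not in set(drop)]
    best_first = eliminated[::-1]
    feats = [columns[i] for i, _ in best_first]
    vals = np.array([v for _, v in best_first])
    return FeatureRanking("rfecv", feats, vals, n_rounds=n_rounds)


def rank_lasso(X: FeatureMatrix, label: str = "hotspot", seed: int = 0,
               folds: int = 10, C: float | None = None) -> FeatureRanking:
    """L1-penalized logistic ranking by |coefficient|.

    Features are standardized internally, making the ranking invariant
    to column rescaling.  The penalty strength is chosen by k-fold CV
    unless an explicit `C` is given.  Zero-coefficient features follow
    all nonzero ones, in column order.
    """
    y = X.labels(label).to_numpy()
    Xv = X.features.to_numpy(dtype=float)
    if np.allclose(Xv.std(axis=0), 0):
        raise ValueError("all features are constant")
    Xs = StandardScaler().fit_transform(Xv)
    if C is None:
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear",
            cv=StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=seed),
            Cs=10, random_state=seed, max_iter=5000)
    else:
        model = LogisticRegression(penalty="l1", solver="liblinear", C=C,
                                   random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        # sklearn's in-flight penalty/l1_ratio API migration warns even
        # for the supported penalty="l1" spelling
        warnings.simplefilter("ignore", FutureWarning)
        warnings.filterwarnings("ignore", message=".*penalty.*")
        model.fit(Xs, y)
    coef = np.abs(model.coef_).max(axis=0)
    nonzero = coef > 0
    # stable sort: nonzero by descending |coef|, then zeros in column order
    sort_key = np.where(nonzero, -coef, np.inf)
    order = np.argsort(sort_key, kind="stable")
    cols = list(X.features.columns)
    return FeatureRanking("lasso", [cols[i] for i in order], coef[order])


@dataclass
class ConsolidatedScores:
    """Rank-aggregated feature scores across the three selectors."""

    table: pd.DataFrame  # index feature; per-method scores, total, rank
    top_n: int

    @property
    def selected(self) -> list[str]:
        """Features with nonzero total, in consolidated rank order."""
        sel = self.table[self.table["total"] > 0]
        return list(sel.sort_values("rank").index)

    def nature_summary(self) -> dict:
        return nature_summary(self.selected)


def consolidate(rankings: list[FeatureRanking], top_frac: float = 0.10,
                feature_order: list[str] | None = None) -> ConsolidatedScores:
    """Sum per-selector rank scores into the consolidated ranking.

    top_n = ceil(top_frac * n_features).  Within each selector, the
    best feature scores top_n and the top_n-th scores 1; all other
    features score 0.  The global rank orders by descending total, ties
    broken by `feature_order` (the matrix column order; defaults to the
    first ranking's order).
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = sorted(rankings[0].features)
    for r in rankings[1:]:
        if sorted(r.features) != universe:
            raise ValueError("rankings cover different feature universes")
    if feature_order is None:
        feature_order = list(rankings[0].features)
    elif sorted(feature_order) != universe:
        raise ValueError("feature_order does not match the ranking universe")
    n = len(universe)
    top_n = math.ceil(top_frac * n)

    scores = pd.DataFrame(index=pd.Index(list(feature_order), name="feature"))
    for r in rankings:
        s = pd.Series(0, index=scores.index, dtype=int)
        for rank_pos, feat in enumerate(r.features[:top_n], start=1):
            s[feat] = top_n - rank_pos + 1
        scores[f"score_{r.method}"] = s
    scores["total"] = scores.sum(axis=1)
    order = np.argsort(-scores["total"].to_numpy(), kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    scores["rank"] = rank
    return ConsolidatedScores(table=scores, top_n=top_n)


def nature_summary(selected: list[str]) -> dict:
    """Rotational share and per-parameter shares of a selected set."""
    if not selected:
        raise ValueError("empty feature set")
    natures, params = [], []
    for name in selected:
        _, param = parse_feature_name(name)
        params.append(param)
        natures.append(PARAMETERS[param].nature)
    n = len(selected)
    rotational = sum(1 for x in natures if x == "rotational")
    param_counts = pd.Series(params).value_counts()
    return {
        "n_selected": n,
        "rotational_fraction": rotational / n,
        "translational_fraction": (n - rotational) / n,
        "parameter_shares": {p: c / n for p, c in param_counts.items()},
    }
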