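"""Feature selectors, rank-score consolidation and nature summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from helixclass.features import FeatureMatrix, feature_name
from helixclass.featscore import (FeatureRanking, consolidate,
                                  nature_summary, rank_lasso, rank_rfecv,
                                  rank_rf_importance_cv,
                                  subset_adducted_binary)
from helixclass.rfmodel import RFParams

FAST_RF = RFParams(n_estimators=25, max_depth=4, max_features="sqrt",
                   bootstrap=False)


def toy_matrix(n_per_class=12, n_features=12, informative=(0,), shift=6.0,
               seed=0, duplicate_of=None):
    """Binary hotspot matrix with noise features and planted columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    hot = np.repeat([True, False], n_per_class)
    for j in informative:
        X[hot, j] += shift
    if duplicate_of is not None:
        src, dst = duplicate_of
        X[:, dst] = X[:, src]
    cols = [feature_name(b, p) for b, p in zip(
        range(3, 3 + n_features),
        ["tip", "roll", "shear", "rise", "twist", "buckle", "shift",
         "slide", "stagger", "propeller", "opening", "tilt"][:n_features])]
    features = pd.DataFrame(X, columns=cols)
    meta = pd.DataFrame({
        "gene": "TOY", "site": [f"s{i}" for i in range(n)],
        "sequence": "AAAAACG" + "A" * 18,
        "methylated_positions": "6",
        "adducted": True, "hotspot": hot,
        "replicate": 1, "dataset_tag": "train",
        "class4": np.where(hot, "hotspot_adduct", "nonhotspot_adduct"),
    })
    return FeatureMatrix(features=features, meta=meta)


class TestSubset:
    def test_half_of_reference_matrix_is_adducted(self, tp53_features):
        sub = subset_adducted_binary(tp53_features)
        assert sub.n_samples == 36
        assert set(sub.labels("hotspot")) == {"hotspot", "nonhotspot"}

    def test_all_control_rejected(self, tp53_features):
        controls = tp53_features.select_rows(
            ~tp53_features.meta["adducted"].to_numpy(dtype=bool))
        with pytest.raises(ValueError, match="no adducted"):
            subset_adducted_binary(controls)

    def test_single_hotspot_class_rejected(self, tp53_features):
        mask = (tp53_features.meta["hotspot"]
                | ~tp53_features.meta["adducted"]).to_numpy(dtype=bool)
        with pytest.raises(ValueError, match="single hotspot class"):
            subset_adducted_binary(tp53_features.select_rows(mask))


class TestRFImportance:
    def test_planted_feature_ranked_first(self):
        for seed in range(3):
            X = toy_matrix(seed=seed)
            r = rank_rf_importance_cv(X, folds=4, seed=seed, params=FAST_RF)
            assert r.features[0] == X.feature_names[0]

    def test_constant_feature_has_zero_importance(self):
        X = toy_matrix()
        X.features.iloc[:, 5] = 1.0
        r = rank_rf_importance_cv(X, folds=4, seed=0, params=FAST_RF)
        idx = r.features.index(X.feature_names[5])
        assert r.importances[idx] == 0.0

    def test_importances_are_fold_averages(self):
        """Recompute by hand over the same folds."""
        from sklearn.model_selection import StratifiedKFold
        X = toy_matrix(seed=4)
        folds, seed = 4, 4
        r = rank_rf_importance_cv(X, folds=folds, seed=seed, params=FAST_RF)
        y = X.labels("hotspot").to_numpy()
        Xv = X.features.to_numpy(dtype=float)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        acc = np.zeros(Xv.shape[1])
        for tr, _ in cv.split(Xv, y):
            est = FAST_RF.to_estimator(seed)
            est.fit(Xv[tr], y[tr])
            acc += est.feature_importances_
        acc /= folds
        by_name = dict(zip(r.features, r.importances))
        for j, name in enumerate(X.feature_names):
            assert by_name[name] == pytest.approx(acc[j], abs=1e-12)


class TestRFECV:
    def test_planted_feature_survives_to_last_round(self):
        X = toy_matrix(seed=2)
        r = rank_rfecv(X, folds=4, seed=2, step=1, params=FAST_RF)
        assert r.features[0] == X.feature_names[0]

    def test_step_one_on_ten_features_ten_rounds(self):
        X = toy_matrix(n_features=10)
        r = rank_rfecv(X, folds=4, seed=0, step=1, params=FAST_RF)
        assert r.n_rounds == 10

    def test_duplicated_informative_features_both_top(self):
        X = toy_matrix(seed=3, informative=(0,), duplicate_of=(0, 1))
        r = rank_rfecv(X, folds=4, seed=3, step=1, params=FAST_RF)
        assert set(r.features[:2]) == {X.feature_names[0],
                                       X.feature_names[1]}

    def test_fractional_step_reduces_rounds(self):
        X = toy_matrix(n_features=12)
        r = rank_rfecv(X, folds=4, seed=0, step=0.5, params=FAST_RF)
        assert r.n_rounds == 2
        assert len(r.features) == 12


class TestLasso:
    def test_planted_feature_has_largest_coefficient(self):
        X = toy_matrix(seed=5)
        r = rank_lasso(X, folds=4, seed=5)
        assert r.features[0] == X.feature_names[0]
        assert r.importances[0] == r.importances.max()

    def test_ranking_scale_invariant(self):
        X = toy_matrix(seed=6)
        r1 = rank_lasso(X, folds=4, seed=6)
        scaled = FeatureMatrix(features=X.features * 1000.0,
                               meta=X.meta.copy())
        r2 = rank_lasso(scaled, folds=4, seed=6)
        assert r1.features == r2.features

    def test_full_shrinkage_falls_back_to_column_order(self):
        X = toy_matrix(seed=7)
        r = rank_lasso(X, seed=7, C=1e-8)
        assert r.features == X.feature_names
        assert (r.importances == 0).all()

    def test_all_constant_rejected(self):
        X = toy_matrix()
        X.features.loc[:, :] = 1.0
        with pytest.raises(ValueError, match="constant"):
            rank_lasso(X)


def ranking(method, names, n_total=None, universe=None):
    universe = universe if universe is not None else names
    rest = [f for f in universe if f not in names]
    feats = list(names) + rest
    imp = np.linspace(1, 0, len(feats))
    return FeatureRanking(method, feats, imp)


class TestConsolidate:
    def test_reference_scale_scores(self, tp53_features):
        sub = subset_adducted_binary(tp53_features)
        names = sub.feature_names
        r = ranking("rf_importance_cv", names)
        scores = consolidate([r, ranking("rfecv", names),
                              ranking("lasso", names)], top_frac=0.10)
        assert scores.top_n == 36
        col = scores.table["score_rf_importance_cv"]
        assert col[names[0]] == 36
        assert col[names[35]] == 1
        assert col[names[36]] == 0

    def test_identical_rankings_triple_top_score(self):
        names = [feature_name(b, "tip") for b in range(3, 13)]
        rs = [ranking(m, names) for m in ("a", "b", "c")]
        scores = consolidate(rs, top_frac=0.10)
        assert scores.top_n == 1
        assert scores.table["total"][names[0]] == 3
        assert scores.selected == [names[0]]

    def test_hand_worked_example(self):
        universe = [f"{i}—tip" for i in range(3, 8)]  # f1..f5
        f1, f2, f3 = universe[0], universe[1], universe[2]
        rs = [
            ranking("m1", [f1, f2], universe=universe),
            ranking("m2", [f1, f3], universe=universe),
            ranking("m3", [f2, f1], universe=universe),
        ]
        scores = consolidate(rs, top_frac=0.40)  # top_n = 2
        total = scores.table["total"]
        assert total[f1] == 5 and total[f2] == 3 and total[f3] == 1
        assert set(scores.selected) == {f1, f2, f3}

    def test_totals_match_brute_force_on_random_rankings(self):
        rng = np.random.default_rng(0)
        universe = [feature_name(b, "roll") for b in range(1, 31)]
        for _ in range(50):
            rankings = []
            for m in ("m1", "m2", "m3"):
                order = list(rng.permutation(universe))
                rankings.append(FeatureRanking(m, order,
                                               np.linspace(1, 0, 30)))
            scores = consolidate(rankings, top_frac=0.10)
            top_n = scores.top_n
            expected = {f: 0 for f in universe}
            for r in rankings:
                for pos, f in enumerate(r.features):
                    if pos < top_n:
                        expected[f] += top_n - pos
            for f in universe:
                assert scores.table["total"][f] == expected[f]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        universe = [feature_name(b, "tilt") for b in range(1, 21)]
        rankings = [FeatureRanking(m, list(rng.permutation(universe)),
                                   np.linspace(1, 0, 20))
                    for m in ("m1", "m2", "m3")]
        base = consolidate(rankings, top_frac=0.2, feature_order=universe)
        perm = list(rng.permutation(universe))
        permuted = consolidate(rankings, top_frac=0.2, feature_order=perm)
        for f in universe:
            assert (base.table["total"][f]
                    == permuted.table["total"][f])

    def test_selected_set_size_bounds(self):
        rng = np.random.default_rng(2)
        universe = [feature_name(b, "rise") for b in range(1, 41)]
        for trial in range(10):
            rankings = [FeatureRanking(m, list(rng.permutation(universe)),
                                       np.linspace(1, 0, 40))
                        for m in ("m1", "m2", "m3")]
            scores = consolidate(rankings, top_frac=0.10)
            n_sel = len(scores.selected)
            assert scores.top_n <= n_sel <= 3 * scores.top_n

    def test_mismatched_universes_rejected(self):
        a = ranking("m1", ["3—tip", "4—tip"])
        b = ranking("m2", ["3—tip", "5—tip"])
        with pytest.raises(ValueError, match="universe"):
            consolidate([a, b])


class TestNatureSummary:
    def test_two_thirds_rotational(self):
        out = nature_summary(["10—tip", "11—shift", "14—propeller"])
        assert out["rotational_fraction"] == pytest.approx(2 / 3)

    def test_all_tip_share(self):
        out = nature_summary(["3—tip", "4—tip", "5—tip"])
        assert out["parameter_shares"]["tip"] == 1.0

    def test_counts_match_direct_oracle(self):
        rng = np.random.default_rng(3)
        from helixclass.registry import PARAMETER_ORDER, PARAMETERS
        params = rng.choice(PARAMETER_ORDER, size=40)
        feats = [feature_name(int(b), p)
                 for b, p in zip(rng.integers(3, 24, size=40), params)]
        feats = list(dict.fromkeys(feats))  # dedupe, keep order
        out = nature_summary(feats)
        rot = sum(PARAMETERS[p].nature == "rotational"
                  for _, p in map(
                      lambda f: (f.split("—")[0], f.split("—")[1]), feats))
        assert out["rotational_fraction"] == pytest.approx(rot / len(feats))

    def test_unparseable_name_rejected(self):
        with pytest.raises(ValueError):
            nature_summary(["notafeature"])
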