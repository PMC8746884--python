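"""Recursive ensemble feature selection: labels, Borda, rankings, model."""

import numpy as np
import pandas as pd
import pytest

from gibra.refs import (CLASSIFIER_FAMILIES, RefsConfig, RefsModel,
                        binarize_marbles, binarize_openfield, borda_aggregate,
                        direction_table, rank_features_once,
                        reduction_schedule)

SMALL_CONFIG = RefsConfig(families=("ridge", "logistic", "random_forest"),
                          n_cycles=3, n_repetitions=1, fine_tail=False)


def _planted(n=38, m=12, effect=2.0, seed=0):
    """Noise matrix with one strongly informative feature ('signal')."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame(rng.normal(0, 1, size=(n, m)),
                     columns=[f"f{j}" for j in range(m)])
    # bounded noise keeps the signal feature a true margin separator
    X["signal"] = y * effect + rng.uniform(-0.3, 0.3, n)
    return X, y


# -- label construction -----------------------------------------------------

@pytest.mark.parametrize("count,label", [(9, 0), (10, 1), (0, 0), (20, 1)])
def test_marble_threshold(count, label):
    assert binarize_marbles([count])[0] == label


@pytest.mark.parametrize("entries,label", [(10, 0), (9, 1), (0, 1), (100, 0)])
def test_openfield_threshold_is_inverted(entries, label):
    assert binarize_openfield([entries])[0] == label


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        binarize_marbles([-1])


# -- Borda ------------------------------------------------------------------

def test_borda_single_ranking_point_assignment():
    assert borda_aggregate([["A", "B", "C"]]) == {"A": 3, "B": 2, "C": 1}


def test_borda_reversed_rankings_tie():
    scores = borda_aggregate([["A", "B", "C"], ["C", "B", "A"]])
    assert set(scores.values()) == {4}


def test_borda_single_voter_preserves_order():
    ranking = ["x3", "x1", "x0", "x2"]
    scores = borda_aggregate([ranking])
    assert sorted(ranking, key=lambda f: -scores[f]) == ranking


def test_borda_matches_point_sum_oracle(rng):
    """Random rankings agree with the direct m-k point summation."""
    feats = [f"f{i}" for i in range(8)]
    rankings = [list(rng.permutation(feats)) for _ in range(5)]
    scores = borda_aggregate(rankings)
    for f in feats:
        oracle = sum(len(r) - r.index(f) for r in rankings)
        assert scores[f] == oracle


def test_borda_rejects_mismatched_universe():
    with pytest.raises(ValueError):
        borda_aggregate([["A", "B"], ["A", "C"]])


# -- reduction schedule -----------------------------------------------------

def test_schedule_from_87_matches_ceiling_arithmetic():
    assert reduction_schedule(87, 10) == [87, 70, 56, 45, 36, 29, 24, 20, 16,
                                          13, 11]


def test_schedule_stops_before_degenerating():
    sizes = reduction_schedule(4, 50)
    assert sizes[-1] >= 2
    assert len(sizes) < 51


# -- per-family ranking -----------------------------------------------------

@pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
def test_perfect_separator_ranked_first(family):
    X, y = _planted(n=40, m=5, effect=6.0, seed=7)
    ranking, acc = rank_features_once(X, y, family, cv_folds=5, seed=3)
    assert ranking[0] == "signal"
    # stochastic optimisers (SGD) may drop a single held-out sample even on
    # a margin-separated problem; every family must stay near-perfect
    assert acc >= 0.95


def test_duplicated_column_occupies_adjacent_rank():
    X, y = _planted(n=30, m=5)
    X = X.copy()
    X["signal_dup"] = X["signal"]
    ranking, _ = rank_features_once(X, y, "ridge", cv_folds=5, seed=0)
    i, j = ranking.index("signal"), ranking.index("signal_dup")
    assert abs(i - j) == 1


def test_null_accuracy_near_majority_rate(rng):
    """Labels independent of features: held-out accuracy stays near the
    majority-class rate across replicates."""
    accs = []
    for seed in range(100):
        r = np.random.default_rng(seed)
        X = pd.DataFrame(r.normal(0, 1, size=(38, 10)))
        X.columns = [f"f{j}" for j in range(10)]
        y = np.array([0, 1] * 19)
        _, acc = rank_features_once(X, y, "ridge", cv_folds=5, seed=seed)
        accs.append(acc)
    assert abs(np.mean(accs) - 0.5) < 0.06


def test_foldwise_standardisation_matches_independent_cv_oracle():
    """Accuracy equals a from-scratch fold-wise CV in which the scaler is
    fit on the training folds only — i.e. the pipeline does not leak
    held-out samples into the standardisation."""
    from sklearn.linear_model import RidgeClassifier
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler

    X, y = _planted(n=24, m=4, effect=0.8, seed=7)
    _, acc = rank_features_once(X, y, "ridge", cv_folds=5, seed=5)

    xmat = X.to_numpy()
    splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=5)
    fold_accs = []
    for train, test in splitter.split(xmat, y):
        scaler = StandardScaler().fit(xmat[train])
        clf = RidgeClassifier(random_state=5).fit(
            scaler.transform(xmat[train]), y[train])
        fold_accs.append(clf.score(scaler.transform(xmat[test]), y[test]))
    assert acc == pytest.approx(np.mean(fold_accs), abs=1e-12)


# -- full model -------------------------------------------------------------

def test_fit_is_deterministic_under_seed():
    X, y = _planted(n=30, m=14)
    r1 = RefsModel(X, y, SMALL_CONFIG).fit(seed=9)
    r2 = RefsModel(X, y, SMALL_CONFIG).fit(seed=9)
    pd.testing.assert_frame_equal(r1.accuracy_curve, r2.accuracy_curve)
    assert r1.best_signature == r2.best_signature
    assert r1.auc_mean == r2.auc_mean
    assert r1.best_family == r2.best_family


def test_planted_signal_enters_signature():
    X, y = _planted(n=38, m=19, effect=2.5)
    res = RefsModel(X, y, SMALL_CONFIG).fit(seed=2)
    assert "signal" in res.best_signature
    assert res.best_size == len(res.best_signature)
    assert res.best_size in res.accuracy_curve["n_features"].tolist()


def test_duplicating_best_feature_keeps_its_borda_rank():
    X, y = _planted(n=30, m=10, effect=3.0)
    res = RefsModel(X, y, SMALL_CONFIG).fit(seed=4)
    rank_before = list(res.borda_scores.index).index("signal")
    X2 = X.copy()
    X2["signal_dup"] = X2["signal"]
    res2 = RefsModel(X2, y, SMALL_CONFIG).fit(seed=4)
    rank_after = list(res2.borda_scores.index).index("signal")
    assert rank_after <= rank_before + 1


def test_constant_features_dropped_with_warning():
    X, y = _planted(n=20, m=5)
    X["flat"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        model = RefsModel(X, y, SMALL_CONFIG)
    assert "flat" not in model.X.columns


def test_single_class_labels_rejected():
    X, _ = _planted(n=20, m=5)
    with pytest.raises(ValueError, match="both classes"):
        RefsModel(X, np.zeros(20, dtype=int), SMALL_CONFIG)


def test_config_validation():
    with pytest.raises(ValueError):
        RefsConfig(reduction_fraction=1.5).validate()
    with pytest.raises(ValueError):
        RefsConfig(families=("ridge",)).validate()
    with pytest.raises(ValueError):
        RefsConfig(families=("ridge", "nope")).validate()


def test_null_selection_bias_bounded():
    """Pure-noise tables: signature AUC stays within 0.25 of chance and the
    accuracy curve's maximum within 0.15 of the majority rate."""
    cfg = RefsConfig(families=("ridge", "logistic", "sgd", "random_forest"),
                     n_cycles=4, n_repetitions=1, fine_tail=False)
    aucs, max_accs = [], []
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = pd.DataFrame(r.normal(0, 1, size=(38, 20)),
                         columns=[f"f{j}" for j in range(20)])
        y = np.array([0, 1] * 19)
        res = RefsModel(X, y, cfg).fit(seed=seed)
        aucs.append(res.auc_mean)
        max_accs.append(res.accuracy_curve["accuracy_mean"].max())
    assert abs(np.mean(aucs) - 0.5) < 0.25
    assert np.mean(max_accs) <= 0.5 + 0.15


def test_summary_mentions_key_quantities():
    X, y = _planted(n=30, m=8)
    res = RefsModel(X, y, SMALL_CONFIG).fit(seed=1)
    text = res.summary()
    assert "best signature size" in text
    assert res.best_family in text


# -- direction table --------------------------------------------------------

def test_direction_arrows_follow_planted_sign(rng):
    n = 60
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame({"up_feat": y * 2.0 + rng.normal(0, 0.5, n),
                      "flat": np.ones(n)})
    tab = direction_table(X, y, ["up_feat", "flat"])
    assert tab.set_index("feature").loc["up_feat", "arrow"] == "up"
    assert tab.set_index("feature").loc["flat", "arrow"] == "-"


def test_direction_orientation_flip_is_antisymmetric(rng):
    n = 40
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame({"a": y + rng.normal(0, 0.3, n),
                      "b": -y + rng.normal(0, 0.3, n)})
    t1 = direction_table(X, y, ["a", "b"], orientation="label1_vs_label0")
    t2 = direction_table(X, y, ["a", "b"], orientation="label0_vs_label1")
    flip = {"up": "down", "down": "up", "-": "-"}
    for f in ("a", "b"):
        a1 = t1.set_index("feature").loc[f, "arrow"]
        a2 = t2.set_index("feature").loc[f, "arrow"]
        assert a2 == flip[a1]


def test_direction_requires_signature_features_present():
    X = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        direction_table(X, [0, 1], ["missing"])
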