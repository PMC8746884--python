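"""Recursive ensemble feature selection (REFS) with Borda-count fusion.

Eight scikit-learn classifier families each rank all features by how they
use them (impurity importances for tree ensembles, absolute coefficients on
standardised inputs for linear families); the eight rankings are fused by a
Borda count (position k of m earns m - k points) and the feature set is
recursively shrunk to the top 80% each cycle.  Repeating the whole procedure
under independent seeds yields an accuracy-versus-signature-size curve; the
best signature is the feature set at the curve's maximum, with members
chosen by aggregate Borda score across repetitions.

Exposed statsmodels-style: build a :class:`RefsModel` from a feature matrix
and binary behaviour labels, ``fit()`` it, and read the
:class:`RefsResults` (curve, signature, ROC/AUC, ``summary()``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (BaggingClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import (LogisticRegression,
                                  PassiveAggressiveClassifier, RidgeClassifier,
                                  SGDClassifier)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import FeatureMatrix

__all__ = [
    "CLASSIFIER_FAMILIES",
    "RefsConfig",
    "RefsModel",
    "RefsResults",
    "binarize_marbles",
    "binarize_openfield",
    "borda_aggregate",
    "rank_features_once",
    "reduction_schedule",
    "direction_table",
]

CLASSIFIER_FAMILIES = ("bagging", "random_forest", "logistic",
                       "gradient_boosting", "support_vector", "sgd",
                       "passive_aggressive", "ridge")

_TREE_FAMILIES = {"bagging", "random_forest", "gradient_boosting"}


# ---------------------------------------------------------------------------
# label construction
# ---------------------------------------------------------------------------

def binarize_marbles(counts) -> np.ndarray:
    """Marble-burying label: 1 iff >= 10 marbles buried, else 0."""
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("marble counts must be non-negative")
    return (arr >= 10).astype(int)


def binarize_openfield(entries) -> np.ndarray:
    """Open-field label: 1 iff < 10 centre entries (inverted orientation)."""
    arr = np.asarray(entries)
    if (arr < 0).any():
        raise ValueError("entry counts must be non-negative")
    return (arr < 10).astype(int)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _make_estimator(family: str, seed: int, params: dict | None = None):
    params = params or {}
    if family == "bagging":
        est = BaggingClassifier(n_estimators=10, random_state=seed)
    elif family == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif family == "logistic":
        est = LogisticRegression(max_iter=2000, random_state=seed)
    elif family == "gradient_boosting":
        est = GradientBoostingClassifier(n_estimators=100, random_state=seed)
    elif family == "support_vector":
        # linear kernel mandated so a coefficient ranking exists
        est = SVC(kernel="linear", random_state=seed)
    elif family == "sgd":
        est = SGDClassifier(max_iter=2000, tol=1e-3, random_state=seed)
    elif family == "passive_aggressive":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            est = PassiveAggressiveClassifier(max_iter=2000, random_state=seed)
    elif family == "ridge":
        est = RidgeClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier family: {family!r}")
    est.set_params(**params)
    return est


def _importances(family: str, fitted) -> np.ndarray:
    if family in _TREE_FAMILIES:
        if hasattr(fitted, "feature_importances_"):
            return np.asarray(fitted.feature_importances_, dtype=float)
        return np.mean([t.feature_importances_ for t in fitted.estimators_], axis=0)
    coef = np.atleast_2d(np.asarray(fitted.coef_, dtype=float))
    return np.abs(coef).mean(axis=0)


def _cv_splitter(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    smallest = int(np.bincount(y).min())
    return StratifiedKFold(n_splits=max(2, min(folds, smallest)),
                           shuffle=True, random_state=seed)


def rank_features_once(X: pd.DataFrame, y: np.ndarray, family: str,
                       cv_folds: int, seed: int,
                       params: dict | None = None) -> tuple[list[str], float]:
    """One family's cross-validated feature ranking and held-out accuracy.

    Standardisation is refit inside each training fold (no leakage); the
    importance vector is averaged over folds, and ties are broken by the
    stable input feature order.
    """
    names = list(X.columns)
    xmat = X.to_numpy(dtype=float)
    splitter = _cv_splitter(y, cv_folds, seed)
    accs, imps = [], []
    for train, test in splitter.split(xmat, y):
        pipe = Pipeline([("scale", StandardScaler()),
                         ("clf", _make_estimator(family, seed, params))])
        pipe.fit(xmat[train], y[train])
        accs.append(pipe.score(xmat[test], y[test]))
        imps.append(_importances(family, pipe.named_steps["clf"]))
    mean_imp = np.mean(imps, axis=0)
    order = np.argsort(-mean_imp, kind="stable")
    return [names[i] for i in order], float(np.mean(accs))


def borda_aggregate(rankings: list[list[str]]) -> dict[str, float]:
    """Borda scores: position k (0-based, best first) of m earns m - k points."""
    if not rankings:
        raise ValueError("no rankings to aggregate")
    universe = set(rankings[0])
    scores = {f: 0.0 for f in universe}
    for ranking in rankings:
        if set(ranking) != universe:
            raise ValueError("rankings cover different feature universes")
        m = len(ranking)
        for k, feat in enumerate(ranking):
            scores[feat] += m - k
    return scores


def reduction_schedule(m0: int, cycles: int, fraction: float = 0.8) -> list[int]:
    """Sizes visited by the retain-ceil(fraction*m) loop, start included."""
    sizes = [m0]
    m = m0
    for _ in range(cycles):
        m = math.ceil(fraction * m)
        if m < 2 or m == sizes[-1]:
            break
        sizes.append(m)
    return sizes


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class RefsConfig:
    """REFS hyper-structure: families, cycles, reduction and repetitions."""

    families: tuple[str, ...] = CLASSIFIER_FAMILIES
    n_cycles: int = 10
    reduction_fraction: float = 0.8
    n_repetitions: int = 10
    cv_folds: int = 5
    fine_tail: bool = True     # continue shrinking by 1 below the 0.8 grid
    estimator_params: dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.reduction_fraction < 1):
            raise ValueError("reduction fraction must be in (0, 1)")
        if len(self.families) < 2:
            raise ValueError("need at least two classifier families")
        unknown = set(self.families) - set(CLASSIFIER_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.n_cycles < 1 or self.n_repetitions < 1 or self.cv_folds < 2:
            raise ValueError("cycles/repetitions/folds out of range")


@dataclass
class RefsResults:
    """Fitted REFS output: curve, signature, Borda scores, ROC/AUC."""

    accuracy_curve: pd.DataFrame        # n_features, accuracy_mean, accuracy_sd
    best_size: int
    best_signature: list[str]
    borda_scores: pd.Series             # aggregate scores at the best size
    family_accuracy: pd.Series          # per-family CV accuracy on signature
    best_family: str
    auc_mean: float
    auc_sd: float
    roc_points: pd.DataFrame            # fpr grid, tpr mean over repetitions
    config: RefsConfig
    seed: int
    n_samples: int
    label_balance: float
    dropped_constant: list[str] = field(default_factory=list)
    truncated: bool = False

    @property
    def best_accuracy(self) -> float:
        row = self.accuracy_curve.set_index("n_features")
        return float(row.loc[self.best_size, "accuracy_mean"])

    def summary(self) -> str:
        lines = [
            "Recursive ensemble feature selection",
            "=" * 52,
            f"samples: {self.n_samples}   label-1 fraction: {self.label_balance:.2f}",
            f"families: {len(self.config.families)}   repetitions: "
            f"{self.config.n_repetitions}   cv folds: {self.config.cv_folds}",
            f"best signature size: {self.best_size}",
            f"mean accuracy (all classifiers) at best size: "
            f"{self.best_accuracy:.2f}",
            f"best classifier: {self.best_family}   "
            f"AUC: {self.auc_mean:.2f} +/- {self.auc_sd:.2f}",
            "-" * 52,
            "signature (aggregate Borda order):",
        ]
        for feat in self.best_signature:
            lines.append(f"  {feat}  [{self.borda_scores[feat]:.0f}]")
        return "\n".join(lines)

    def plot_accuracy_curve(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        c = self.accuracy_curve.sort_values("n_features")
        ax.errorbar(c["n_features"], c["accuracy_mean"], yerr=c["accuracy_sd"],
                    marker="o", lw=1)
        ax.axvline(self.best_size, ls="--", color="grey")
        ax.set_xlabel("number of features")
        ax.set_ylabel("mean accuracy (all classifiers)")
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_points["fpr"], self.roc_points["tpr"], lw=2,
                label=f"{self.best_family} (AUC {self.auc_mean:.2f}"
                      f" +/- {self.auc_sd:.2f})")
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


class RefsModel:
    """REFS model over a samples x features matrix and a binary label.

    Parameters
    ----------
    features
        :class:`~gibra.containers.FeatureMatrix` or plain DataFrame.
    labels
        Binary 0/1 vector; defaults to ``features.labels`` for a
        FeatureMatrix.  Both classes must be present.
    config
        :class:`RefsConfig`; defaults follow the procedure's standard shape
        (8 families, 10 cycles at 80% retention, 10 repetitions).
    """

    def __init__(self, features: FeatureMatrix | pd.DataFrame,
                 labels=None, config: RefsConfig | None = None):
        if isinstance(features, FeatureMatrix):
            if labels is None:
                labels = features.labels
            frame = features.values
        else:
            frame = features
        if labels is None:
            raise ValueError("labels are required")
        y = np.asarray(labels).astype(int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("labels must contain both classes 0 and 1")
        std = frame.std(axis=0, ddof=0)
        self.dropped_constant = list(std.index[std == 0])
        if self.dropped_constant:
            warnings.warn(f"dropping constant features: {self.dropped_constant}",
                          stacklevel=2)
        self.X = frame.drop(columns=self.dropped_constant)
        self.y = y
        self.config = config or RefsConfig()
        self.config.validate()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str,
                       threshold: int = 10, orientation: str = "ge",
                       config: RefsConfig | None = None) -> "RefsModel":
        """Build from one frame whose `label_col` holds a behaviour count.

        ``orientation="ge"`` labels counts >= threshold as 1 (marble
        convention); ``"lt"`` labels counts < threshold as 1 (open-field
        convention).
        """
        counts = df[label_col].to_numpy()
        if orientation == "ge":
            y = (counts >= threshold).astype(int)
        elif orientation == "lt":
            y = (counts < threshold).astype(int)
        else:
            raise ValueError("orientation must be 'ge' or 'lt'")
        return cls(df.drop(columns=[label_col]), y, config)

    # -- fitting ----------------------------------------------------------

    def _visited_sizes(self) -> list[int]:
        cfg = self.config
        sizes = reduction_schedule(self.X.shape[1], cfg.n_cycles,
                                   cfg.reduction_fraction)
        if cfg.fine_tail:
            m = sizes[-1]
            while m > 2:
                m -= 1
                sizes.append(m)
        return sizes

    def fit(self, seed: int = 0) -> RefsResults:
        """Run the full recursive selection; deterministic under `seed`."""
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(cfg.n_repetitions + 1)]
        roc_seed = rep_seeds.pop()

        sizes = self._visited_sizes()
        truncated = len(reduction_schedule(self.X.shape[1], cfg.n_cycles,
                                           cfg.reduction_fraction)) < cfg.n_cycles + 1
        acc_records = []          # (repetition, size, family, accuracy)
        borda_at_size: dict[int, list[dict[str, float]]] = {s: [] for s in sizes}

        for rep, rep_seed in enumerate(rep_seeds):
            current = list(self.X.columns)
            fam_ss = np.random.SeedSequence(rep_seed).spawn(len(sizes))
            for step, size in enumerate(sizes):
                current = current[:size]   # sizes shrink monotonically
                sub = self.X[current]
                step_seeds = [int(s % (2 ** 31)) for s in
                              fam_ss[step].generate_state(len(cfg.families))]
                rankings = []
                for family, fam_seed in zip(cfg.families, step_seeds):
                    ranking, acc = rank_features_once(
                        sub, self.y, family, cfg.cv_folds, fam_seed,
                        cfg.estimator_params.get(family))
                    rankings.append(ranking)
                    acc_records.append((rep, size, family, acc))
                scores = borda_aggregate(rankings)
                borda_at_size[size].append(scores)
                order = sorted(current, key=lambda f: (-scores[f], current.index(f)))
                current = order

        acc = pd.DataFrame(acc_records,
                           columns=["repetition", "n_features", "family",
                                    "accuracy"])
        per_rep = (acc.groupby(["repetition", "n_features"])["accuracy"]
                   .mean().reset_index())
        curve = (per_rep.groupby("n_features")["accuracy"]
                 .agg(accuracy_mean="mean", accuracy_sd="std")
                 .fillna(0.0).reset_index())

        # accuracy maximum; ties resolved toward the smaller signature
        best_row = curve.sort_values(["accuracy_mean", "n_features"],
                                     ascending=[False, True]).iloc[0]
        best_size = int(best_row["n_features"])

        agg: dict[str, float] = {}
        for scores in borda_at_size[best_size]:
            for feat, s in scores.items():
                agg[feat] = agg.get(feat, 0.0) + s
        feat_order = sorted(agg, key=lambda f: (-agg[f],
                                                list(self.X.columns).index(f)))
        signature = feat_order[:best_size]
        borda_scores = pd.Series(agg, name="borda").sort_values(ascending=False)

        fam_acc, roc_df, best_family, auc_mean, auc_sd = self._roc_on_signature(
            signature, roc_seed)

        return RefsResults(curve, best_size, signature,
                           borda_scores, fam_acc, best_family,
                           auc_mean, auc_sd, roc_df, cfg, seed,
                           len(self.y), float(self.y.mean()),
                           self.dropped_constant, truncated)

    # -- ROC for the best-performing family -------------------------------

    def _decision_scores(self, family: str, X: np.ndarray, seed: int,
                         fold_seed: int) -> np.ndarray:
        scores = np.empty(len(self.y), dtype=float)
        splitter = _cv_splitter(self.y, self.config.cv_folds, fold_seed)
        for train, test in splitter.split(X, self.y):
            pipe = Pipeline([("scale", StandardScaler()),
                             ("clf", _make_estimator(
                                 family, seed,
                                 self.config.estimator_params.get(family)))])
            pipe.fit(X[train], self.y[train])
            clf = pipe.named_steps["clf"]
            xt = pipe.named_steps["scale"].transform(X[test])
            if hasattr(clf, "decision_function"):
                scores[test] = clf.decision_function(xt)
            else:
                scores[test] = clf.predict_proba(xt)[:, 1]
        return scores

    def _roc_on_signature(self, signature: list[str], seed: int):
        from sklearn.metrics import roc_auc_score, roc_curve

        cfg = self.config
        X = self.X[signature].to_numpy(dtype=float)
        rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in np.random.SeedSequence(seed).spawn(cfg.n_repetitions)]

        fam_acc = {}
        for family in cfg.families:
            accs = []
            for rs in rep_seeds:
                splitter = _cv_splitter(self.y, cfg.cv_folds, rs)
                fold_accs = []
                for train, test in splitter.split(X, self.y):
                    pipe = Pipeline([("scale", StandardScaler()),
                                     ("clf", _make_estimator(
                                         family, rs,
                                         cfg.estimator_params.get(family)))])
                    pipe.fit(X[train], self.y[train])
                    fold_accs.append(pipe.score(X[test], self.y[test]))
                accs.append(np.mean(fold_accs))
            fam_acc[family] = float(np.mean(accs))
        fam_acc = pd.Series(fam_acc, name="accuracy")
        best_family = str(fam_acc.idxmax())

        grid = np.linspace(0, 1, 101)
        tprs, aucs = [], []
        for rs in rep_seeds:
            scores = self._decision_scores(best_family, X, rs, rs)
            aucs.append(roc_auc_score(self.y, scores))
            fpr, tpr, _ = roc_curve(self.y, scores)
            tprs.append(np.interp(grid, fpr, tpr))
        roc_df = pd.DataFrame({"fpr": grid, "tpr": np.mean(tprs, axis=0)})
        return (fam_acc, roc_df, best_family,
                float(np.mean(aucs)), float(np.std(aucs, ddof=1))
                if len(aucs) > 1 else 0.0)


# ---------------------------------------------------------------------------
# direction-of-change table
# ---------------------------------------------------------------------------

def direction_table(X: pd.DataFrame, y, signature: list[str],
                    alpha: float = 0.10,
                    orientation: str = "label1_vs_label0") -> pd.DataFrame:
    """Arrow table for a signature: up/down between label groups, or "-".

    Compares feature means between the two label groups with a two-sided
    rank-sum test; an arrow is shown only when the test supports the sign at
    ``alpha``, otherwise "-".  ``orientation="label0_vs_label1"`` flips every
    arrow (the open-field reporting convention).
    """
    if orientation not in ("label1_vs_label0", "label0_vs_label1"):
        raise ValueError("bad orientation")
    y = np.asarray(y).astype(int)
    rows = []
    for feat in signature:
        if feat not in X.columns:
            raise ValueError(f"signature feature absent: {feat!r}")
        x1 = X.loc[y == 1, feat].to_numpy(dtype=float)
        x0 = X.loc[y == 0, feat].to_numpy(dtype=float)
        diff = x1.mean() - x0.mean()
        if np.ptp(np.concatenate([x0, x1])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x1, x0,
                                         alternative="two-sided").pvalue)
        if p < alpha and diff != 0:
            arrow = "up" if diff > 0 else "down"
            if orientation == "label0_vs_label1":
                arrow = "down" if arrow == "up" else "up"
        else:
            arrow = "-"
        rows.append((feat, diff, p, arrow))
    return pd.DataFrame(rows, columns=["feature", "mean_diff", "p_ranksum",
                                       "arrow"])
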