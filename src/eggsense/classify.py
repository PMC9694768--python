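"""Random-forest nausea detection protocol.

The protocol: stratified 75/25 split of the 68 segments, leave-one-out
cross-validated tuning of ``mtry`` (the number of candidate features per
split) over the grid {2, 9, 17}, a seeded 500-tree forest, evaluation by
confusion-matrix metrics with an exact binomial CI on accuracy, AUCs for
the cross-validated training predictions and the held-out test votes,
and feature importance as the per-feature count of split usages summed
over all trees.  Two noisy-evaluation variants: (1) trained and tested
on the noisy tables; (2) trained on the original table, tested on the
noisy twins of the same held-out rows.

The positive class is the *no-nausea* (majority) level: with 17 test
rows (3 nausea) the reference confusion matrix TP=14, FP=2, FN=0, TN=1
jointly yields accuracy 0.882, kappa 0.452, sensitivity 1.000,
specificity 0.333 and precision 0.875 — the first-factor-level
convention of the upstream tooling.  Reports carry both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import FEATURE_COLUMNS

__all__ = [
    "RfConfig",
    "RfResult",
    "NauseaForest",
    "stratified_partition",
    "tune_mtry",
    "train_rf",
    "evaluate",
    "metrics_from_confusion",
    "clopper_pearson",
    "feature_importance",
    "run_experiments",
]

POSITIVE = "no_nausea"
NEGATIVE = "nausea"


@dataclass(frozen=True)
class RfConfig:
    """Protocol hyper-parameters (defaults reproduce the reference run)."""

    n_trees: int = 500
    mtry_grid: tuple[int, ...] = (2, 9, 17)
    seed: int = 100
    train_fraction: float = 0.75
    positive_class: str = POSITIVE


@dataclass
class RfResult:
    """Metrics of one trained-and-evaluated forest."""

    mtry_selected: int
    tuning_accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    kappa: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    auc_train: float
    auc_test: float
    importance: list[tuple[str, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "mtry_selected", "tuning_accuracy", "tp", "fp", "fn", "tn", "accuracy",
            "kappa", "sensitivity", "specificity", "precision", "recall",
            "auc_train", "auc_test")}
        d["ci95_low"], d["ci95_high"] = self.ci95
        return d


def stratified_partition(
    labels: np.ndarray, fraction: float = 0.75, seed: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split indices, deterministic per seed.

    Per class, round(fraction · n_class) members go to training; with 68
    rows of which 12 positive and fraction 0.75 this gives a 51-row
    training set (9 positive) and a 17-row test set (3 positive).
    """
    labels = np.asarray(labels)
    if not 0.0 < fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def _forest(mtry: int, config: RfConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )


def _loo_votes(X: np.ndarray, y: np.ndarray, mtry: int, config: RfConfig) -> np.ndarray:
    """Leave-one-out cross-validated positive-class vote fractions."""
    votes = np.empty(len(y))
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        clf = _forest(mtry, config).fit(X[keep], y[keep])
        pos = list(clf.classes_).index(config.positive_class)
        votes[i] = clf.predict_proba(X[i : i + 1])[0, pos]
    return votes


def tune_mtry(X: np.ndarray, y: np.ndarray, config: RfConfig = RfConfig()
              ) -> tuple[int, float, dict[int, float], np.ndarray]:
    """LOO-CV accuracy over the mtry grid; argmax, ties → smallest mtry.

    Returns (mtry, its LOO accuracy, the full grid accuracies, and the
    LOO positive-class vote fractions at the selected mtry).
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    grid_acc: dict[int, float] = {}
    grid_votes: dict[int, np.ndarray] = {}
    for mtry in config.mtry_grid:
        votes = _loo_votes(X, y, mtry, config)
        pred = np.where(votes >= 0.5, config.positive_class, _other(y, config.positive_class))
        grid_acc[mtry] = float(np.mean(pred == y))
        grid_votes[mtry] = votes
    best = max(sorted(grid_acc), key=lambda m: grid_acc[m])
    return best, grid_acc[best], grid_acc, grid_votes[best]


def _other(y: np.ndarray, positive: str) -> str:
    rest = [c for c in np.unique(y) if c != positive]
    return rest[0] if rest else positive


def train_rf(X: np.ndarray, y: np.ndarray, mtry: int, config: RfConfig = RfConfig()
             ) -> RandomForestClassifier:
    """Fit the seeded bagged forest with ``mtry`` candidate features per split."""
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    return _forest(mtry, config).fit(X, y)


class NauseaForest(BaseEstimator, ClassifierMixin):
    """sklearn-style classifier bundling mtry tuning and the seeded forest.

    With ``mtry=None`` (default) `fit` runs leave-one-out tuning over
    ``mtry_grid`` and refits the full training set at the winner.

    Attributes (after fit): ``mtry_``, ``tuning_accuracy_``,
    ``grid_accuracies_``, ``loo_votes_``, ``forest_``, ``classes_``,
    ``selection_counts_`` (per-feature split counts over all trees).
    """

    def __init__(self, mtry: int | None = None, n_trees: int = 500,
                 mtry_grid: tuple[int, ...] = (2, 9, 17), seed: int = 100,
                 positive_class: str = POSITIVE):
        self.mtry = mtry
        self.n_trees = n_trees
        self.mtry_grid = mtry_grid
        self.seed = seed
        self.positive_class = positive_class

    def _config(self) -> RfConfig:
        return RfConfig(n_trees=self.n_trees, mtry_grid=tuple(self.mtry_grid),
                        seed=self.seed, positive_class=self.positive_class)

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        cfg = self._config()
        if self.mtry is None:
            self.mtry_, self.tuning_accuracy_, self.grid_accuracies_, self.loo_votes_ = (
                tune_mtry(X, y, cfg)
            )
        else:
            self.mtry_ = int(self.mtry)
            self.loo_votes_ = _loo_votes(X, y, self.mtry_, cfg)
            pred = np.where(self.loo_votes_ >= 0.5, cfg.positive_class,
                            _other(y, cfg.positive_class))
            self.tuning_accuracy_ = float(np.mean(pred == y))
            self.grid_accuracies_ = {self.mtry_: self.tuning_accuracy_}
        self.forest_ = train_rf(X, y, self.mtry_, cfg)
        self.classes_ = self.forest_.classes_
        self.selection_counts_ = feature_importance(self.forest_)
        self.y_train_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(X)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(sst.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sst.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Closed-form metrics from confusion counts (positive class fixed).

    kappa = (p_o − p_e)/(1 − p_e); the 95 % CI on accuracy is exact
    (Clopper–Pearson).  Undefined ratios (single-class margins) are NaN.
    """
    n = tp + fp + fn + tn
    correct = tp + tn
    p_o = correct / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 1.0
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return {
        "accuracy": p_o,
        "kappa": kappa,
        "ci95": clopper_pearson(correct, n),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
    }


def evaluate(
    model: NauseaForest | RandomForestClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    positive_class: str = POSITIVE,
    auc_train: float = float("nan"),
) -> RfResult:
    """Confusion-matrix metrics of a fitted forest on held-out rows.

    The test AUC is computed from the forests' positive-class vote
    fractions; ``auc_train`` (from cross-validated training predictions)
    is passed through.
    """
    y_test = np.asarray(y_test, dtype=object)
    forest = model.forest_ if isinstance(model, NauseaForest) else model
    pred = forest.predict(X_test)
    pos = positive_class
    tp = int(np.sum((pred == pos) & (y_test == pos)))
    fp = int(np.sum((pred == pos) & (y_test != pos)))
    fn = int(np.sum((pred != pos) & (y_test == pos)))
    tn = int(np.sum((pred != pos) & (y_test != pos)))
    m = metrics_from_confusion(tp, fp, fn, tn)
    if len(np.unique(y_test)) == 2:
        pos_idx = list(forest.classes_).index(pos)
        votes = forest.predict_proba(X_test)[:, pos_idx]
        auc_test = float(roc_auc_score((y_test == pos).astype(int), votes))
    else:
        auc_test = float("nan")
    imp: list[tuple[str, int]] = []
    if isinstance(model, NauseaForest):
        counts = model.selection_counts_
        order = np.argsort(-counts)
        imp = [(FEATURE_COLUMNS[i], int(counts[i])) for i in order]
        mtry, tune_acc = model.mtry_, model.tuning_accuracy_
    else:
        mtry, tune_acc = forest.max_features, float("nan")
    return RfResult(
        mtry_selected=mtry, tuning_accuracy=tune_acc,
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=m["accuracy"], kappa=m["kappa"], ci95=m["ci95"],
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        precision=m["precision"], recall=m["recall"],
        auc_train=auc_train, auc_test=auc_test, importance=imp,
    )


def feature_importance(forest: RandomForestClassifier) -> np.ndarray:
    """Per-feature count of split usages summed over all trees."""
    counts = np.zeros(forest.n_features_in_, dtype=int)
    for tree in forest.estimators_:
        feats = tree.tree_.feature
        internal = feats[feats >= 0]
        np.add.at(counts, internal, 1)
    return counts


def _table_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = np.where(table["nausea"].to_numpy() == 1, NEGATIVE, POSITIVE).astype(object)
    return X, y


def run_experiments(
    original: pd.DataFrame,
    noisy_tables: dict[str, pd.DataFrame],
    config: RfConfig = RfConfig(),
) -> dict[str, dict[str, RfResult]]:
    """The two noisy-evaluation variants over aligned feature tables.

    The split is drawn once from the original table's labels and reused
    everywhere.  Variant ``noisy_train``: full protocol (tune, train,
    test) per table, including the original.  Variant ``original_train``:
    the original-table model evaluated on the noisy twins of the same
    test rows.  The training AUC is taken from the LOO-CV votes of each
    trained model.
    """
    orig = original.sort_values(["subject_id", "condition"]).reset_index(drop=True)
    tables = {"original": orig}
    for tag, t in noisy_tables.items():
        t = t.sort_values(["subject_id", "condition"]).reset_index(drop=True)
        if not (orig["subject_id"].equals(t["subject_id"])
                and orig["condition"].equals(t["condition"])):
            raise KeyError(f"table {tag!r} rows do not align with the original table")
        tables[tag] = t

    X0, y0 = _table_xy(orig)
    train_idx, test_idx = stratified_partition(y0, config.train_fraction, config.seed)

    def _auc_train(model: NauseaForest, y_train: np.ndarray) -> float:
        truth = (y_train == config.positive_class).astype(int)
        if len(np.unique(truth)) < 2:
            return float("nan")
        return float(roc_auc_score(truth, model.loo_votes_))

    results: dict[str, dict[str, RfResult]] = {"noisy_train": {}, "original_train": {}}
    base_model: NauseaForest | None = None
    for tag, t in tables.items():
        X, y = _table_xy(t)
        model = NauseaForest(
            n_trees=config.n_trees, mtry_grid=config.mtry_grid, seed=config.seed,
            positive_class=config.positive_class,
        ).fit(X[train_idx], y[train_idx])
        res = evaluate(model, X[test_idx], y[test_idx], config.positive_class,
                       auc_train=_auc_train(model, y[train_idx]))
        res.meta = {"snr_tag": tag, "seed": config.seed, "variant": "noisy_train",
                    "n_train": len(train_idx), "n_test": len(test_idx)}
        results["noisy_train"][tag] = res
        if tag == "original":
            base_model = model

    for tag, t in tables.items():
        if tag == "original":
            continue
        X, y = _table_xy(t)
        res = evaluate(base_model, X[test_idx], y[test_idx], config.positive_class,
                       auc_train=_auc_train(base_model, y0[train_idx]))
        res.meta = {"snr_tag": tag, "seed": config.seed, "variant": "original_train",
                    "n_train": len(train_idx), "n_test": len(test_idx)}
        results["original_train"][tag] = res
    return results
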