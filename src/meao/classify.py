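"""Age classification of well-level feature tables.

Two classifiers predict the age class (DIV) of each well from its 12
activity features:

* a random forest, used both for accuracy and for ranking features by the
  mean decrease in Gini impurity (:class:`RandomForestAge`);
* a one-against-one radial-kernel SVM: one binary machine per unordered pair
  of age classes, each classifying every test point, with the majority vote
  across machines taken as the prediction (:class:`AgeClassifier`).

Both follow the same protocol: a random 2/3–1/3 train/test split, repeated
(default 100 times), with the accuracy averaged over repetitions.  Features
are standardised using the training split's mean/SD before the SVM (radial
kernels are scale-sensitive; mixed-unit features make raw fits pathological).

On top sit the feature-subset accuracy curve (top-n features by importance),
the per-age-pair curves, 10-fold grid-search tuning of (γ, C), and the
well-subsampling study that asks how classification accuracy degrades when
only n ≤ 48 wells per plate are used.

Both model classes expose ``.fit(seed)`` returning a
:class:`ClassifierResult`; module-level functions wrap them for pipeline use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from meao.features import FEATURE_NAMES, prepare_for_classification

__all__ = [
    "SvmConfig",
    "ClassifierResult",
    "RandomForestResult",
    "TuningResult",
    "SubsampleCurve",
    "AgeClassifier",
    "RandomForestAge",
    "split_train_test",
    "svm_accuracy",
    "rf_importance",
    "tune_hyperparameters",
    "feature_subset_curve",
    "pairwise_age_curves",
    "subsample_wells_curve",
]

_KERNELS = {"radial": "rbf", "rbf": "rbf", "linear": "linear", "polynomial": "poly"}


@dataclass(frozen=True)
class SvmConfig:
    """SVM hyperparameters: kernel, kernel width γ and regularisation C."""

    kernel: str = "radial"
    gamma: float = 0.1
    cost: float = 10.0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {sorted(_KERNELS)}")
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be positive")

    def make_svc(self) -> SVC:
        return SVC(kernel=_KERNELS[self.kernel], gamma=self.gamma, C=self.cost)


@dataclass(frozen=True)
class ClassifierResult:
    """Accuracy summary over repeated random train/test splits.

    ``mean_accuracy`` and ``per_repetition`` are percentages; ``confusion``
    is the (true × predicted) count matrix summed over repetitions.
    """

    mean_accuracy: float
    per_repetition: np.ndarray
    confusion: pd.DataFrame
    n_repetitions: int
    classes: tuple

    def summary(self) -> str:
        lines = [
            "Age classification over repeated train/test splits",
            f"  classes: {', '.join(str(c) for c in self.classes)}   "
            f"repetitions: {self.n_repetitions}",
            f"  mean accuracy: {self.mean_accuracy:.1f}%   "
            f"(min {self.per_repetition.min():.1f}, max {self.per_repetition.max():.1f})",
            "  confusion (rows = true, cols = predicted, summed over repetitions):",
        ]
        lines.append(self.confusion.to_string())
        return "\n".join(lines)


def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 2 / 3,
    seed: int | np.random.Generator = 0,
    label_column: str = "div",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random partition into train/test with every class present in both parts.

    The split is reproducible given *seed*; if a draw leaves some class absent
    from either part, the split is redrawn with the same generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = table[label_column].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes to split")
    n = len(table)
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("train_fraction leaves an empty partition")
    for _ in range(1000):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if set(labels[tr]) == set(classes) == set(labels[te]):
            return table.iloc[np.sort(tr)], table.iloc[np.sort(te)]
    raise ValueError("could not produce a split with every class in both parts")


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


class _OneVsOneSvm:
    """One binary SVM per unordered class pair, majority vote over machines.

    Vote ties between exactly two classes are resolved by the directly
    contested pairwise machine; remaining ties fall back to the smallest
    class in sorted order.
    """

    def __init__(self, cfg: SvmConfig):
        self.cfg = cfg
        self.machines: dict[tuple, SVC] = {}
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OneVsOneSvm":
        self.classes_ = np.unique(y)
        self.machines = {}
        for a, b in itertools.combinations(self.classes_, 2):
            mask = (y == a) | (y == b)
            svc = self.cfg.make_svc()
            svc.fit(X[mask], y[mask])
            self.machines[(a, b)] = svc
        return self

    @property
    def n_machines(self) -> int:
        return len(self.machines)

    def predict(self, X: np.ndarray) -> np.ndarray:
        classes = self.classes_
        index = {c: i for i, c in enumerate(classes)}
        votes = np.zeros((len(X), len(classes)), dtype=np.int32)
        pair_pred: dict[tuple, np.ndarray] = {}
        for pair, svc in self.machines.items():
            pred = svc.predict(X)
            pair_pred[pair] = pred
            for c in pair:
                votes[pred == c, index[c]] += 1
        out = np.empty(len(X), dtype=classes.dtype)
        top = votes.max(axis=1)
        for i in range(len(X)):
            tied = classes[votes[i] == top[i]]
            if len(tied) == 1:
                out[i] = tied[0]
            elif len(tied) == 2:
                out[i] = pair_pred[(tied[0], tied[1])][i]
            else:
                out[i] = tied[0]
        return out


_NON_FEATURE_COLUMNS = {"plate_id", "well_id", "div"}


def _resolve_features(table: pd.DataFrame, features) -> list[str]:
    if features is None:
        features = [c for c in FEATURE_NAMES if c in table.columns]
        if not features:  # non-canonical table: every numeric non-key column
            features = [c for c in table.select_dtypes("number").columns
                        if c not in _NON_FEATURE_COLUMNS]
    features = list(features)
    if not features:
        raise ValueError("feature subset is empty")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"feature(s) not in table: {missing}")
    return features


def _check_complete(table: pd.DataFrame, features: list[str]) -> None:
    if table[features].isna().any().any():
        raise ValueError("feature table contains missing values; prepare it first")


class AgeClassifier:
    """One-against-one SVM age classifier over repeated train/test splits.

    Parameters
    ----------
    table:
        Complete (no missing values) feature table with a ``div`` label
        column.
    features:
        Feature subset to use; default: all canonical features present.
    config, train_fraction, n_repetitions:
        SVM hyperparameters and the split protocol.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: list[str] | None = None,
        config: SvmConfig = SvmConfig(),
        train_fraction: float = 2 / 3,
        n_repetitions: int = 100,
        label_column: str = "div",
    ):
        self.features = _resolve_features(table, features)
        _check_complete(table, self.features)
        self.table = table
        self.config = config
        self.train_fraction = train_fraction
        self.n_repetitions = n_repetitions
        self.label_column = label_column
        self.classes = tuple(np.unique(table[label_column]))
        if len(self.classes) < 2:
            raise ValueError("need at least two age classes")

    def fit(self, seed: int = 0) -> ClassifierResult:
        rng = np.random.default_rng(seed)
        accs = np.empty(self.n_repetitions)
        conf = np.zeros((len(self.classes), len(self.classes)), dtype=np.int64)
        labels = list(self.classes)
        for r in range(self.n_repetitions):
            train, test = split_train_test(self.table, self.train_fraction, rng,
                                           self.label_column)
            Xtr = train[self.features].to_numpy(dtype=float)
            Xte = test[self.features].to_numpy(dtype=float)
            Xtr, Xte = _standardize(Xtr, Xte)
            ytr = train[self.label_column].to_numpy()
            yte = test[self.label_column].to_numpy()
            model = _OneVsOneSvm(self.config).fit(Xtr, ytr)
            pred = model.predict(Xte)
            accs[r] = 100.0 * np.mean(pred == yte)
            conf += confusion_matrix(yte, pred, labels=labels)
        confusion = pd.DataFrame(conf, index=labels, columns=labels)
        return ClassifierResult(
            mean_accuracy=float(accs.mean()),
            per_repetition=accs,
            confusion=confusion,
            n_repetitions=self.n_repetitions,
            classes=self.classes,
        )


@dataclass(frozen=True)
class RandomForestResult:
    """Random-forest accuracy plus the Gini-importance ranking.

    ``importance`` is indexed by feature, sorted decreasing, normalised so the
    top feature scores 1.00 (importance averaged over the repetitions before
    normalising).
    """

    result: ClassifierResult
    importance: pd.Series

    def summary(self) -> str:
        lines = [self.result.summary(), "", "Feature importance (Gini, top = 1.00):"]
        for name, score in self.importance.items():
            lines.append(f"  {name:<26s} {score:.2f}")
        return "\n".join(lines)


class RandomForestAge:
    """Random-forest age classifier with Gini feature importance."""

    def __init__(
        self,
        table: pd.DataFrame,
        features: list[str] | None = None,
        n_trees: int = 500,
        train_fraction: float = 2 / 3,
        n_repetitions: int = 100,
        label_column: str = "div",
    ):
        self.features = _resolve_features(table, features)
        _check_complete(table, self.features)
        self.table = table
        self.n_trees = n_trees
        self.train_fraction = train_fraction
        self.n_repetitions = n_repetitions
        self.label_column = label_column
        self.classes = tuple(np.unique(table[label_column]))
        if len(self.classes) < 2:
            raise ValueError("need at least two age classes")

    def fit(self, seed: int = 0) -> RandomForestResult:
        rng = np.random.default_rng(seed)
        accs = np.empty(self.n_repetitions)
        importances = np.zeros(len(self.features))
        conf = np.zeros((len(self.classes), len(self.classes)), dtype=np.int64)
        labels = list(self.classes)
        for r in range(self.n_repetitions):
            train, test = split_train_test(self.table, self.train_fraction, rng,
                                           self.label_column)
            rf = RandomForestClassifier(
                n_estimators=self.n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(train[self.features], train[self.label_column])
            pred = rf.predict(test[self.features])
            yte = test[self.label_column].to_numpy()
            accs[r] = 100.0 * np.mean(pred == yte)
            conf += confusion_matrix(yte, pred, labels=labels)
            importances += rf.feature_importances_
        importances /= self.n_repetitions
        ranking = pd.Series(importances, index=self.features).sort_values(ascending=False)
        ranking = ranking / ranking.iloc[0]
        result = ClassifierResult(
            mean_accuracy=float(accs.mean()),
            per_repetition=accs,
            confusion=pd.DataFrame(conf, index=labels, columns=labels),
            n_repetitions=self.n_repetitions,
            classes=self.classes,
        )
        return RandomForestResult(result=result, importance=ranking)


# ---------------------------------------------------------------------------
# functional wrappers and study-level procedures


def svm_accuracy(
    table: pd.DataFrame,
    feature_subset: list[str] | None = None,
    cfg: SvmConfig = SvmConfig(),
    n_reps: int = 100,
    seed: int = 0,
    train_fraction: float = 2 / 3,
) -> ClassifierResult:
    """Mean one-vs-one SVM accuracy over repeated splits (see :class:`AgeClassifier`)."""
    return AgeClassifier(table, feature_subset, cfg, train_fraction, n_reps).fit(seed)


def rf_importance(
    table: pd.DataFrame,
    n_trees: int = 500,
    n_reps: int = 100,
    seed: int = 0,
    train_fraction: float = 2 / 3,
) -> tuple[pd.Series, ClassifierResult]:
    """Random-forest Gini importance ranking and accuracy (see :class:`RandomForestAge`)."""
    fitted = RandomForestAge(table, None, n_trees, train_fraction, n_reps).fit(seed)
    return fitted.importance, fitted.result


@dataclass(frozen=True)
class TuningResult:
    """Chosen SVM hyperparameters with the cross-validation grid for audit."""

    config: SvmConfig
    cv_accuracy: pd.DataFrame  # index gamma, columns cost, values mean CV accuracy %
    best_accuracy: float


def tune_hyperparameters(
    table: pd.DataFrame,
    gamma_grid=(0.01, 0.1, 1.0),
    cost_grid=(1.0, 10.0, 100.0),
    k_folds: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
    kernel: str = "radial",
) -> TuningResult:
    """Grid-search (γ, C) by stratified k-fold cross-validation accuracy.

    Ties are broken toward the smallest C, then the smallest γ.
    """
    if not len(gamma_grid) or not len(cost_grid):
        raise ValueError("grids must be nonempty")
    features = _resolve_features(table, features)
    _check_complete(table, features)
    X = table[features].to_numpy(dtype=float)
    y = table["div"].to_numpy()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    grid = pd.DataFrame(index=pd.Index(sorted(gamma_grid), name="gamma"),
                        columns=pd.Index(sorted(cost_grid), name="cost"), dtype=float)
    best = (-np.inf, np.inf, np.inf)  # (accuracy, cost, gamma) with tie rule
    best_cfg = None
    for gamma in grid.index:
        for cost in grid.columns:
            cfg = SvmConfig(kernel=kernel, gamma=float(gamma), cost=float(cost))
            accs = []
            for tr, te in folds:
                Xtr, Xte = _standardize(X[tr], X[te])
                model = _OneVsOneSvm(cfg).fit(Xtr, y[tr])
                accs.append(100.0 * np.mean(model.predict(Xte) == y[te]))
            acc = float(np.mean(accs))
            grid.loc[gamma, cost] = acc
            key = (acc, -float(cost), -float(gamma))
            if key > (best[0], -best[1], -best[2]):
                best = (acc, float(cost), float(gamma))
                best_cfg = cfg
    assert best_cfg is not None
    return TuningResult(config=best_cfg, cv_accuracy=grid, best_accuracy=best[0])


def feature_subset_curve(
    table: pd.DataFrame,
    ranking: pd.Series,
    cfg: SvmConfig = SvmConfig(),
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """SVM accuracy using the top-n features, for n = 1 … len(ranking).

    *ranking* is an importance-ordered Series as produced by
    :func:`rf_importance`.  Returns a DataFrame indexed by n with columns
    ``feature_added`` and ``accuracy`` (%).
    """
    ordered = list(ranking.index)
    rows = []
    for n in range(1, len(ordered) + 1):
        res = svm_accuracy(table, ordered[:n], cfg, n_reps, seed)
        rows.append((n, ordered[n - 1], res.mean_accuracy))
    return pd.DataFrame(rows, columns=["n", "feature_added", "accuracy"]).set_index("n")


def pairwise_age_curves(
    table: pd.DataFrame,
    ranking: pd.Series,
    cfg: SvmConfig = SvmConfig(),
    n_reps: int = 100,
    seed: int = 0,
) -> dict[tuple, pd.DataFrame]:
    """Feature-subset curves for every unordered pair of age classes.

    Each curve is a binary classification (chance = 50%) restricted to the two
    classes, using the same global importance ordering.
    """
    classes = sorted(np.unique(table["div"]))
    curves: dict[tuple, pd.DataFrame] = {}
    for a, b in itertools.combinations(classes, 2):
        sub = table[table["div"].isin([a, b])]
        curves[(a, b)] = feature_subset_curve(sub, ranking, cfg, n_reps, seed)
    return curves


@dataclass(frozen=True)
class SubsampleCurve:
    """Accuracy versus wells-per-plate: mean/min/max over random well draws."""

    table: pd.DataFrame  # index n_wells, columns mean/min/max, n_trials
    n_trials: int

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.errorbar(t.index, t["mean"],
                    yerr=[t["mean"] - t["min"], t["max"] - t["mean"]],
                    marker="o", capsize=3)
        ax.axhline(25, color="red", linestyle=":", label="chance (4 classes)")
        ax.set_xlabel("wells sampled per plate")
        ax.set_ylabel("classification accuracy (%)")
        ax.legend()
        return ax


def subsample_wells_curve(
    well_table: pd.DataFrame,
    n_values=(1, 2, 4, 8, 16, 24, 48),
    n_trials: int = 100,
    cfg: SvmConfig = SvmConfig(),
    seed: int = 0,
    same_wells_across_div: bool = True,
) -> SubsampleCurve:
    """How does age-classification accuracy degrade with fewer wells per plate?

    For each n and each trial, n wells are drawn without replacement from each
    plate (by default the *same* wells across that plate's recordings at all
    ages, emulating the assignment of wells to experimental conditions; with
    ``same_wells_across_div=False`` wells are drawn independently per
    recording).  The reduced table goes through the classification
    missing-value policy and a single random 2/3–1/3 split of the one-vs-one
    SVM; mean/min/max accuracy over trials is reported per n.

    *well_table* is the raw well-level feature table (missing values allowed;
    the policy is applied per trial after well removal).  At very small n the
    exclusion policy can leave an age class with fewer than two rows; such
    classes cannot be scored and are dropped from that trial, and a trial
    with fewer than two surviving classes records NaN (ignored in the
    mean/min/max aggregation).
    """
    rng = np.random.default_rng(seed)
    plates = sorted(well_table["plate_id"].unique())
    wells_by_plate = {
        p: sorted(well_table.loc[well_table["plate_id"] == p, "well_id"].unique())
        for p in plates
    }
    recordings = sorted(
        well_table[["plate_id", "div"]].drop_duplicates().itertuples(index=False)
    )
    max_n = min(len(w) for w in wells_by_plate.values())
    n_values = sorted(n_values)
    if n_values[0] < 1 or n_values[-1] > max_n:
        raise ValueError(f"n_values must lie in [1, {max_n}]")

    rows = []
    for n in n_values:
        accs = np.empty(n_trials)
        for t in range(n_trials):
            masks = []
            if same_wells_across_div:
                for p in plates:
                    chosen = rng.choice(wells_by_plate[p], size=n, replace=False)
                    masks.append((well_table["plate_id"] == p)
                                 & well_table["well_id"].isin(chosen))
            else:
                for p, d in recordings:
                    chosen = rng.choice(wells_by_plate[p], size=n, replace=False)
                    masks.append((well_table["plate_id"] == p)
                                 & (well_table["div"] == d)
                                 & well_table["well_id"].isin(chosen))
            sub = well_table[np.logical_or.reduce(masks)]
            kept, _, _ = prepare_for_classification(sub)
            counts = kept["div"].value_counts()
            kept = kept[kept["div"].isin(counts[counts >= 2].index)]
            if kept["div"].nunique() < 2:
                accs[t] = np.nan
                continue
            res = AgeClassifier(kept, config=cfg, n_repetitions=1).fit(
                seed=int(rng.integers(2**31 - 1))
            )
            accs[t] = res.mean_accuracy
        rows.append((n, np.nanmean(accs), np.nanmin(accs), np.nanmax(accs)))
    table = pd.DataFrame(rows, columns=["n_wells", "mean", "min", "max"]).set_index("n_wells")
    return SubsampleCurve(table=table, n_trials=n_trials)
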