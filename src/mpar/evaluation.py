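"""Multi-classifier evaluation harness with repeated random splits.

Five classifier configurations are evaluated, mirroring the study's WEKA
setups on their native scikit-learn equivalents:

==========================  ==========================================
kind (abbreviation)         configuration
==========================  ==========================================
KNN (knn)                   K = 1, Manhattan distance
DecisionTree (j48)          maximum depth 50
RandomForest (rf)           100 trees
InductionRules (ir)         grow/prune ratio 0.95 (reduced-error-style
                            pruned tree: fit on the grow split, pick the
                            cost-complexity alpha scoring best on the
                            held-out prune split)
GradientBoostedTrees (gbt)  100 boosting iterations, depth 50
                            (histogram gradient boosting)
==========================  ==========================================

A feature table is split into disjoint train/test sets at 90-10, 80-20 or
70-30, the split repeated several times (stratified by class by default),
and mean accuracy plus a pooled confusion matrix reported.  Splits are
pooled across subjects — a window-level random split, which is the
emulated protocol; note that windows of one bout can then land on both
sides, so accuracies read higher than a leave-subjects-out design would
give.  ``SplitPlan(by_subject=True)`` offers the stricter alternative.

All randomness derives from the plan's master seed, so any cell of the
evaluation grid can be re-run in isolation and reproduce itself exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .signal_io import ACTIVITY_LABELS, FeatureTable

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierConfig",
    "SplitPlan",
    "EvalResult",
    "make_estimator",
    "split",
    "subsample",
    "train_and_evaluate",
    "run_grid",
    "summarize_grid",
]

#: kind -> abbreviation
CLASSIFIER_KINDS: dict[str, str] = {
    "KNN": "knn",
    "DecisionTree": "j48",
    "RandomForest": "rf",
    "InductionRules": "ir",
    "GradientBoostedTrees": "gbt",
}
_ABBREV_TO_KIND = {v: k for k, v in CLASSIFIER_KINDS.items()}

_DEFAULT_PARAMS: dict[str, dict] = {
    "KNN": {"n_neighbors": 1, "metric": "manhattan"},
    "DecisionTree": {"max_depth": 50},
    "RandomForest": {"n_estimators": 100},
    "InductionRules": {"grow_fraction": 0.95},
    "GradientBoostedTrees": {"n_estimators": 100, "max_depth": 50},
}


class ConfigurationError(ValueError):
    """A classifier configuration cannot be instantiated or fitted."""


class StratificationError(ValueError):
    """A class has too few rows to stratify the requested split."""


class GrowPruneTreeClassifier(BaseEstimator, ClassifierMixin):
    """Rule-induction stand-in: a grow/prune decision tree.

    Emulates reduced-error rule pruning: the training data is split into a
    grow part (``grow_fraction``) and a prune part; an unpruned tree is
    fitted on the grow part and the cost-complexity pruning strength is
    chosen to maximise accuracy on the prune part.  Each root-to-leaf path
    of the pruned tree is one induced rule.
    """

    def __init__(self, grow_fraction: float = 0.95, random_state: int | None = None,
                 max_candidates: int = 16):
        self.grow_fraction = grow_fraction
        self.random_state = random_state
        self.max_candidates = max_candidates

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if not 0.5 < self.grow_fraction < 1.0:
            raise ConfigurationError(
                f"grow_fraction must be in (0.5, 1), got {self.grow_fraction}"
            )
        try:
            Xg, Xp, yg, yp = train_test_split(
                X, y, train_size=self.grow_fraction,
                random_state=self.random_state, stratify=y,
            )
        except ValueError:
            # tiny classes: fall back to an unstratified grow/prune split
            Xg, Xp, yg, yp = train_test_split(
                X, y, train_size=self.grow_fraction,
                random_state=self.random_state,
            )
        grower = DecisionTreeClassifier(random_state=self.random_state)
        grower.fit(Xg, yg)
        alphas = grower.cost_complexity_pruning_path(Xg, yg).ccp_alphas
        alphas = np.unique(np.clip(alphas, 0.0, None))
        if len(alphas) > self.max_candidates:
            picks = np.linspace(0, len(alphas) - 1, self.max_candidates).astype(int)
            alphas = alphas[picks]
        best_score, best_tree = -np.inf, None
        for alpha in alphas:
            tree = DecisionTreeClassifier(
                random_state=self.random_state, ccp_alpha=float(alpha)
            ).fit(Xg, yg)
            score = tree.score(Xp, yp)
            if score > best_score:
                best_score, best_tree = score, tree
        self.tree_ = best_tree
        self.classes_ = best_tree.classes_
        return self

    def predict(self, X):
        return self.tree_.predict(X)


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier kind with its reference hyperparameters.

    ``params`` overrides the per-kind defaults listed in the module
    docstring; ``seed`` feeds every stochastic component (forests,
    boosting, grow/prune splits).
    """

    kind: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        kind = _ABBREV_TO_KIND.get(self.kind, self.kind)
        if kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(
                f"unknown classifier kind {self.kind!r}; expected one of "
                f"{sorted(CLASSIFIER_KINDS) + sorted(_ABBREV_TO_KIND)}"
            )
        object.__setattr__(self, "kind", kind)

    @property
    def abbreviation(self) -> str:
        return CLASSIFIER_KINDS[self.kind]

    @property
    def effective_params(self) -> dict:
        merged = dict(_DEFAULT_PARAMS[self.kind])
        merged.update(self.params)
        return merged


def make_estimator(config: ClassifierConfig):
    """Instantiate the scikit-learn estimator for a configuration."""
    p = config.effective_params
    try:
        if config.kind == "KNN":
            return KNeighborsClassifier(**p)
        if config.kind == "DecisionTree":
            return DecisionTreeClassifier(random_state=config.seed, **p)
        if config.kind == "RandomForest":
            return RandomForestClassifier(random_state=config.seed, **p)
        if config.kind == "InductionRules":
            return GrowPruneTreeClassifier(random_state=config.seed, **p)
        if config.kind == "GradientBoostedTrees":
            return HistGradientBoostingClassifier(
                max_iter=int(p.pop("n_estimators")),
                random_state=config.seed,
                **p,
            )
    except TypeError as exc:
        raise ConfigurationError(f"{config.kind}: {exc}") from exc
    raise ConfigurationError(f"unknown classifier kind {config.kind!r}")


@dataclass(frozen=True)
class SplitPlan:
    """Repeated random train/test split design.

    The default splits pool windows across subjects (the emulated
    protocol).  ``by_subject=True`` keeps every subject's windows on one
    side of the split — the stricter leave-subjects-out design, which
    removes the same-bout leakage of pooled splits; ``stratified`` is
    ignored in that mode.
    """

    train_fraction: float = 0.8
    repeats: int = 10
    seed: int = 0
    stratified: bool = True
    by_subject: bool = False

    def __post_init__(self) -> None:
        if self.train_fraction not in (0.9, 0.8, 0.7):
            raise ValueError(
                f"train_fraction must be 0.9, 0.8 or 0.7, got {self.train_fraction}"
            )
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _derived_state(seed: int, repeat_index: int) -> int:
    # distinct, stable per-repeat RNG stream below 2**31
    return int(
        np.random.default_rng([seed & 0x7FFFFFFF, repeat_index]).integers(0, 2**31 - 1)
    )


def split(
    table: FeatureTable, plan: SplitPlan, repeat_index: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive train/test split of a feature table.

    Deterministic given ``(plan.seed, repeat_index)``.  Stratified mode
    preserves per-class proportions to within one row per class and
    raises :class:`StratificationError` when a class has fewer than two
    rows.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot split an empty feature table")
    if plan.by_subject:
        rng = np.random.default_rng(_derived_state(plan.seed, repeat_index))
        subjects = table.frame["subject_id"].to_numpy()
        order = rng.permutation(np.unique(subjects))
        counts = pd.Series(subjects).value_counts()
        taken, train_subjects = 0, []
        for subject in order:
            if taken >= plan.train_fraction * n:
                break
            train_subjects.append(subject)
            taken += int(counts[subject])
        mask = np.isin(subjects, train_subjects)
        if mask.all() or not mask.any():
            raise ValueError("too few subjects for a by-subject split")
        return table.select(np.flatnonzero(mask)), table.select(np.flatnonzero(~mask))
    y = table.y
    stratify = None
    if plan.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise StratificationError(
                "every class needs >= 2 rows for a stratified split"
            )
        stratify = y
    idx_train, idx_test = train_test_split(
        np.arange(n),
        train_size=plan.train_fraction,
        random_state=_derived_state(plan.seed, repeat_index),
        stratify=stratify,
    )
    return table.select(np.sort(idx_train)), table.select(np.sort(idx_test))


def subsample(table: FeatureTable, n: int, seed: int = 0,
              stratified: bool = True) -> FeatureTable:
    """Seeded random subsample of ``n`` rows, stratified by class by default.

    Desk-scale runs evaluate on a subsample of a large window table; class
    proportions are preserved to within one row per class.
    """
    if n >= len(table):
        return table
    idx_keep, _ = train_test_split(
        np.arange(len(table)),
        train_size=n,
        random_state=seed & 0x7FFFFFFF,
        stratify=table.y if stratified else None,
    )
    return table.select(np.sort(idx_keep))


@dataclass
class EvalResult:
    """Accuracies and pooled confusion counts for one (classifier, plan) cell."""

    classifier: ClassifierConfig
    plan: SplitPlan
    accuracies: np.ndarray  # per repeat
    confusion: pd.DataFrame  # rows true class, columns predicted, counts
    labels: tuple[str, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def total(self) -> int:
        """Test rows summed over repeats (the confusion-matrix mass)."""
        return int(self.confusion.to_numpy().sum())

    @property
    def pooled_accuracy(self) -> float:
        """Trace over total of the pooled confusion matrix."""
        m = self.confusion.to_numpy()
        return float(np.trace(m) / m.sum())

    @property
    def per_class_recall(self) -> pd.Series:
        m = self.confusion.to_numpy(dtype=float)
        row = m.sum(axis=1)
        recall = np.divide(np.diag(m), row, out=np.zeros_like(row), where=row > 0)
        return pd.Series(recall, index=self.confusion.index, name="recall")

    def confusion_normalized(self) -> pd.DataFrame:
        """Row-normalised confusion matrix (per-class rates)."""
        m = self.confusion.to_numpy(dtype=float)
        row = m.sum(axis=1, keepdims=True)
        rates = np.divide(m, row, out=np.zeros_like(m), where=row > 0)
        return pd.DataFrame(rates, index=self.confusion.index,
                            columns=self.confusion.columns)


def _confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, labels: Sequence[str]
) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return m


def _present_labels(y: np.ndarray) -> tuple[str, ...]:
    present = set(y)
    ordered = [lab for lab in ACTIVITY_LABELS if lab in present]
    ordered += sorted(present.difference(ordered))
    return tuple(ordered)


def train_and_evaluate(
    table: FeatureTable, classifier: ClassifierConfig, plan: SplitPlan
) -> EvalResult:
    """Fit and score one classifier over the plan's repeated splits.

    Each repeat fits a fresh estimator on the train split and predicts the
    disjoint test split; accuracies are averaged over repeats and
    confusion counts pooled.
    """
    y_all = table.y
    if len(np.unique(y_all)) < 2:
        raise ValueError("need at least two classes to evaluate")
    labels = _present_labels(y_all)
    accuracies = np.empty(plan.repeats)
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for r in range(plan.repeats):
        train, test = split(table, plan, r)
        est = make_estimator(
            ClassifierConfig(
                classifier.kind,
                classifier.params,
                seed=_derived_state(classifier.seed, r),
            )
        )
        try:
            est.fit(train.X, train.y)
        except Exception as exc:  # noqa: BLE001 - annotate with the kind
            raise ConfigurationError(
                f"classifier {classifier.kind} failed to fit: {exc}"
            ) from exc
        pred = est.predict(test.X)
        accuracies[r] = float(np.mean(pred == test.y))
        confusion += _confusion_counts(test.y, pred, labels)
    frame = pd.DataFrame(confusion, index=list(labels), columns=list(labels))
    frame.index.name = "true"
    frame.columns.name = "predicted"
    return EvalResult(classifier, plan, accuracies, frame, labels)


def run_grid(
    tables: Mapping[tuple[float, bool], FeatureTable],
    classifiers: Iterable[ClassifierConfig],
    plans: Iterable[SplitPlan],
) -> dict[tuple[float, bool, str, float], EvalResult]:
    """Evaluate the full windowing x classifier x split Cartesian product.

    Keys are ``(window_seconds, overlapped, classifier_kind,
    train_fraction)``.  Each cell is exactly what a standalone
    :func:`train_and_evaluate` call with the same seed produces.
    """
    classifiers = list(classifiers)
    plans = list(plans)
    if not (tables and classifiers and plans):
        raise ValueError("grid needs at least one table, classifier and plan")
    grid: dict[tuple[float, bool, str, float], EvalResult] = {}
    for (window_seconds, overlapped), table in tables.items():
        for clf in classifiers:
            for plan in plans:
                key = (window_seconds, overlapped, clf.kind, plan.train_fraction)
                grid[key] = train_and_evaluate(table, clf, plan)
    return grid


def summarize_grid(
    grid: Mapping[tuple[float, bool, str, float], EvalResult]
) -> pd.DataFrame:
    """Flat summary of mean accuracy per grid cell, best cell first."""
    rows = [
        {
            "window_seconds": w,
            "overlapped": ov,
            "classifier": kind,
            "train_fraction": frac,
            "mean_accuracy": res.mean_accuracy,
            "std_accuracy": float(np.std(res.accuracies)),
            "repeats": res.plan.repeats,
        }
        for (w, ov, kind, frac), res in grid.items()
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values("mean_accuracy", ascending=False, ignore_index=True)


def best_cell(
    grid: Mapping[tuple[float, bool, str, float], EvalResult]
) -> tuple[tuple[float, bool, str, float], EvalResult]:
    """The grid cell with the highest mean accuracy."""
    key = max(grid, key=lambda k: grid[k].mean_accuracy)
    return key, grid[key]
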