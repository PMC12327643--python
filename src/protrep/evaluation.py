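"""Classifier evaluation harness.

Binary tasks are scored by stratified 10-fold cross-validated ROC AUC
(stratified 90-10 splits, data shuffled once before splitting). Classifier
families mirror the benchmark's comparison set: logistic regression, random
forest and linear/RBF support-vector machines, each with a hyper-parameter
grid of fixed cardinality (10 LR, 30 SVM, 27 RF). Single-split evaluation
covers TAPE-style tasks: multinomial logistic accuracy for multi-class
problems and linear-regression Spearman rho for regression problems.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

_GRID_SCHEMAS = {
    "logistic_regression": {"C", "max_iter"},
    "random_forest": {"n_estimators", "max_depth", "min_samples_leaf"},
    "svm_linear": {"C", "kernel"},
    "svm_rbf": {"C", "gamma", "kernel"},
}


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier family plus a concrete hyper-parameter setting."""

    family: str
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in _GRID_SCHEMAS:
            raise ValueError(f"unknown classifier family {self.family!r}")
        allowed = _GRID_SCHEMAS[self.family]
        unknown = {name for name, _ in self.hyperparameters} - allowed
        if unknown:
            raise ValueError(
                f"hyperparameters {sorted(unknown)} not valid for family {self.family!r}"
            )

    @property
    def params(self) -> dict[str, object]:
        return dict(self.hyperparameters)

    def build(self, seed: int = 0):
        """Instantiate the scikit-learn estimator for this configuration."""
        p = self.params
        if self.family == "logistic_regression":
            return LogisticRegression(max_iter=int(p.get("max_iter", 1000)),
                                      C=float(p.get("C", 1.0)))
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(p.get("n_estimators", 100)),
                max_depth=p.get("max_depth"),
                min_samples_leaf=int(p.get("min_samples_leaf", 1)),
                random_state=seed,
            )
        if self.family == "svm_linear":
            return SVC(kernel="linear", C=float(p.get("C", 1.0)))
        return SVC(kernel="rbf", C=float(p.get("C", 1.0)), gamma=p.get("gamma", "scale"))


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation scores for one configuration."""

    per_fold_scores: list[float]
    metric: str
    config: ClassifierConfig
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.per_fold_scores, dtype=float)
        self.mean = float(scores.mean())
        self.sd = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0

    @property
    def k(self) -> int:
        return len(self.per_fold_scores)

    def summary(self) -> str:
        return (
            f"{self.config.family} ({dict(self.config.hyperparameters)}): "
            f"{self.metric} = {self.mean:.3f} +/- {self.sd:.3f} "
            f"over {self.k} folds (seed {self.seed})"
        )


def _fold_scores(estimator, X, y, cv, metric: str) -> list[float]:
    scores = []
    for train, test in cv:
        est = estimator()
        est.fit(X[train], y[train])
        if metric == "auc":
            if hasattr(est, "predict_proba"):
                dec = est.predict_proba(X[test])[:, 1]
            else:
                dec = est.decision_function(X[test])
            scores.append(float(roc_auc_score(y[test], dec)))
        else:  # accuracy
            scores.append(float(accuracy_score(y[test], est.predict(X[test]))))
    return scores


def stratified_cv(
    values: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    k: int = 10,
    seed: int = 0,
    metric: str = "auc",
) -> CVResult:
    """Stratified k-fold CV of one classifier configuration.

    Rows are shuffled once with ``seed`` before the stratified split. AUC
    uses predicted class probabilities (or decision values for SVMs, which
    rank identically). Each class must have at least k members.
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    config = config or ClassifierConfig("logistic_regression")
    classes, counts = np.unique(y, return_counts=True)
    if metric == "auc" and len(classes) != 2:
        raise ValueError("AUC scoring needs binary labels")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = _fold_scores(lambda: config.build(seed), X, y, skf.split(X, y), metric)
    return CVResult(per_fold_scores=scores, metric=metric, config=config, seed=seed)


def default_grids() -> dict[str, list[ClassifierConfig]]:
    """Hyper-parameter grids of fixed size: 10 for LR, 30 for SVM, 27 for RF.

    LR varies the inverse regularisation strength C over 10 log-spaced
    values. SVM pools 5 linear-kernel C values with a 5x5 C-by-gamma RBF
    grid. RF crosses trees {100,300,500} x max-depth {None,10,20} x
    min-leaf {1,3,5}.
    """
    lr = [
        ClassifierConfig("logistic_regression", (("C", float(c)),))
        for c in np.logspace(-3, 3, 10)
    ]
    svm_c = [0.01, 0.1, 1.0, 10.0, 100.0]
    svm = [ClassifierConfig("svm_linear", (("C", c),)) for c in svm_c]
    for c in svm_c:
        for g in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            svm.append(ClassifierConfig("svm_rbf", (("C", c), ("gamma", g))))
    rf = [
        ClassifierConfig(
            "random_forest",
            (("n_estimators", n), ("max_depth", d), ("min_samples_leaf", leaf)),
        )
        for n in (100, 300, 500)
        for d in (None, 10, 20)
        for leaf in (1, 3, 5)
    ]
    return {"logistic_regression": lr, "svm": svm, "random_forest": rf}


def grid_search(
    values: np.ndarray,
    labels: np.ndarray,
    families: list[str] | None = None,
    grids: dict[str, list[ClassifierConfig]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[dict[str, CVResult], CVResult]:
    """Evaluate every grid configuration; return the best per family and overall.

    Best = highest mean AUC, ties broken by smaller sd then earlier grid
    order. All configurations share one seed so fold assignments match.
    """
    grids = grids or default_grids()
    families = families or list(grids)
    best_per_family: dict[str, CVResult] = {}
    for fam in families:
        if fam not in grids:
            raise ValueError(f"no grid for family {fam!r}")
        best: CVResult | None = None
        for config in grids[fam]:
            res = stratified_cv(values, labels, config, k=k, seed=seed)
            if best is None or (res.mean, -res.sd) > (best.mean, -best.sd):
                best = res
        best_per_family[fam] = best
    overall = max(
        best_per_family.values(),
        key=lambda r: (r.mean, -r.sd),
    )
    return best_per_family, overall


def single_split_eval(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    test_values: np.ndarray,
    test_labels: np.ndarray,
    task_type: str,
    seed: int = 0,
) -> float:
    """Single curated train/test split evaluation (TAPE-style).

    ``task_type="multiclass"`` fits a multinomial logistic classifier and
    returns test accuracy; ``"regression"`` fits an ordinary linear
    regressor and returns the Spearman rho of predictions vs targets.
    Constant predictions make rho undefined: NaN is returned with a
    warning rather than coercing to 0.
    """
    Xtr = np.asarray(train_values, dtype=float)
    Xte = np.asarray(test_values, dtype=float)
    if len(Xte) == 0:
        raise ValueError("empty test set")
    if task_type == "multiclass":
        ytr = np.asarray(train_labels)
        yte = np.asarray(test_labels)
        unseen = set(np.unique(yte)) - set(np.unique(ytr))
        if unseen:
            raise ValueError(f"test labels unseen in training: {sorted(unseen)}")
        clf = LogisticRegression(max_iter=1000)
        clf.fit(Xtr, ytr)
        return float(accuracy_score(yte, clf.predict(Xte)))
    if task_type == "regression":
        ytr = np.asarray(train_labels, dtype=float)
        yte = np.asarray(test_labels, dtype=float)
        reg = LinearRegression()
        reg.fit(Xtr, ytr)
        pred = reg.predict(Xte)
        if np.ptp(pred) == 0 or np.ptp(yte) == 0:
            logger.warning("constant predictions or targets: Spearman rho undefined")
            return float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(pred, yte).statistic
        return float(rho)
    raise ValueError(f"task_type must be 'multiclass' or 'regression', got {task_type!r}")


def make_cv_evaluator(k: int = 10, seed: int = 0, config: ClassifierConfig | None = None):
    """A ``(values, labels) -> mean AUC`` callable for the random-feature null."""

    def evaluate(values: np.ndarray, labels: np.ndarray) -> float:
        return stratified_cv(values, labels, config, k=k, seed=seed).mean

    return evaluate
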