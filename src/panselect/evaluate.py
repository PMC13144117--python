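"""Model evaluation over repeated stratified 90/10 shuffle splits.

Each method is scored by refitting on 100 random stratified partitions
(90% train / 10% test) and averaging four metrics across iterations:

* ROC AUC on the held-out split, using the model's continuous decision
  score (class probability for lr/rf, margin for the SVM);
* F1-score on the held-out split, with the second group level as the
  positive class;
* k-fold cross-validation accuracy (default k = 10) computed on the
  training portion of each iteration;
* plain accuracy on the held-out split.

All randomness derives from a single seed; splits are drawn per
iteration from an independent stream so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .pangenome import LabeledPangenome
from .selectors import SelectorConfig

__all__ = ["MetricsSummary", "evaluate_method", "metrics_report"]

METRIC_COLUMNS = ("roc_auc", "f1", "cv_accuracy", "accuracy")


@dataclass
class MetricsSummary:
    method: str
    mean_roc_auc: float
    mean_f1: float
    mean_cv_accuracy: float
    mean_accuracy: float
    n_iterations: int
    per_iteration_table: pd.DataFrame  # one row per iteration, METRIC_COLUMNS


def _make_model(config: SelectorConfig, random_state: int):
    if config.method == "lr":
        # L2 penalty is the default regularization
        return LogisticRegression(
            solver="lbfgs",
            max_iter=config.lr_max_internal_iterations,
        )
    if config.method == "svm":
        # adaptive schedule: see selectors._fit_importances
        return SGDClassifier(
            loss="hinge",
            penalty="l2",
            learning_rate="adaptive",
            eta0=0.01,
            random_state=random_state,
        )
    if config.method == "rf":
        return RandomForestClassifier(
            n_estimators=config.rf_estimators_per_iteration,
            criterion="gini",
            random_state=random_state,
            n_jobs=1,
        )
    raise ValueError(f"unknown method {config.method!r}")


def _decision_score(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving group proportions; at least one test point per group."""
    test_idx: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def evaluate_method(
    pangenome: LabeledPangenome,
    config: SelectorConfig,
    n_iterations: int = 100,
    test_fraction: float = 0.1,
    cv_folds: int | None = 10,
    seed: int | None = None,
) -> MetricsSummary:
    """Average ROC AUC / F1 / CV accuracy / accuracy over shuffled partitions.

    ``cv_folds=None`` skips the cross-validation column (reported as NaN),
    which roughly halves the cost when only held-out metrics are needed.
    """
    counts = pangenome.group_counts()
    if min(counts.values()) < 2:
        raise ValueError("each group needs at least 2 genomes for a stratified split")
    X = pangenome.matrix.to_numpy(dtype=np.float32)
    y = pangenome.binary_labels()
    base_seed = config.seed if seed is None else seed

    rows = []
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 7919, it]))
        model_seed = int(rng.integers(2**31))
        train, test = _stratified_split(y, test_fraction, rng)
        if len(np.unique(y[test])) < 2:
            train, test = _stratified_split(y, test_fraction, rng)
            if len(np.unique(y[test])) < 2:
                raise ValueError(f"iteration {it}: test split contains one class")

        model = _make_model(config, model_seed)
        model.fit(X[train], y[train])
        y_pred = model.predict(X[test])
        row = {
            "iteration": it,
            "roc_auc": roc_auc_score(y[test], _decision_score(model, X[test])),
            "f1": f1_score(y[test], y_pred),
            "accuracy": accuracy_score(y[test], y_pred),
        }
        if cv_folds is not None:
            folds = StratifiedKFold(
                n_splits=cv_folds, shuffle=True, random_state=model_seed % (2**31)
            )
            row["cv_accuracy"] = float(
                np.mean(
                    cross_val_score(
                        clone(model), X[train], y[train], cv=folds, scoring="accuracy"
                    )
                )
            )
        else:
            row["cv_accuracy"] = np.nan
        rows.append(row)

    table = pd.DataFrame(rows).set_index("iteration")[list(METRIC_COLUMNS)]
    return MetricsSummary(
        method=config.method,
        mean_roc_auc=float(table["roc_auc"].mean()),
        mean_f1=float(table["f1"].mean()),
        mean_cv_accuracy=float(table["cv_accuracy"].mean()),
        mean_accuracy=float(table["accuracy"].mean()),
        n_iterations=n_iterations,
        per_iteration_table=table,
    )


def metrics_report(summaries: list[MetricsSummary]) -> pd.DataFrame:
    """One row per method: ROC AUC, F1-score, Cross-validation, Accuracy.

    Values are rounded to four decimals; input order is preserved.
    """
    rows = [
        {
            "method": s.method,
            "ROC AUC": round(s.mean_roc_auc, 4),
            "F1-score": round(s.mean_f1, 4),
            "Cross-validation": round(s.mean_cv_accuracy, 4),
            "Accuracy": round(s.mean_accuracy, 4),
        }
        for s in summaries
    ]
    columns = ["method", "ROC AUC", "F1-score", "Cross-validation", "Accuracy"]
    return pd.DataFrame(rows, columns=columns)
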