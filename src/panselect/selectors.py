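"""Stability-based discriminative feature selection over the binary matrix.

Three supervised classifiers rank gene families by how strongly they
separate the two genome groups:

* **rf** — random forests (100 trees per fit, Gini impurity) refit over
  ``rf_external_iterations`` stratified 90% subsamples of the genomes;
  within one fit, a family "appears" when the z-score of its Gini
  importance against that fit's importance distribution exceeds
  ``rf_per_iteration_zscore`` (default 3).  A looser
  ``positive_importance`` mode (any strictly positive importance counts
  as an appearance) is available, but with many trees per fit nearly
  every family is touched by some split, which floods the stability
  rule with weakly-used families.
* **svm** — a linear SVM trained by stochastic gradient descent with an
  L2 penalty, likewise refit over external iterations; because
  L2-penalized linear weights are dense, a family "appears" in one fit
  only when the z-score of its absolute weight against that fit's weight
  distribution exceeds ``svm_per_iteration_zscore`` (default 3).
* **lr** — a single L2-penalized logistic regression (LBFGS, solver cap
  300 iterations) fit on the full matrix; families are ranked by their
  share of the total absolute coefficient mass.

For rf and svm, the retained set is the stability-selection rule:
families that appeared in at least ``appearance_threshold`` (default
40%) of the external iterations.  For lr, two readings of the
"contribution exceeds 0.3%" rule are offered: ``individual_share``
(default) keeps families whose own share of the coefficient mass
exceeds the threshold; ``cumulative_prefix`` keeps the shortest prefix
of the ranking whose summed share exceeds it.  The two readings give
very different set sizes (at most 1/threshold families can pass the
individual rule); see the package docs for the trade-off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, SGDClassifier

from .pangenome import LabeledPangenome

logger = logging.getLogger(__name__)

__all__ = [
    "SelectorConfig",
    "IterationRecord",
    "MethodSelection",
    "run_external_iterations",
    "per_iteration_select",
    "stability_retain",
    "lr_select",
    "run_selector",
    "write_iteration_log",
    "write_selection_tsv",
]

METHODS = ("lr", "svm", "rf")


@dataclass(frozen=True)
class SelectorConfig:
    """All knobs for one selection method; ``method`` picks which apply."""

    method: str = "rf"
    # logistic regression
    lr_max_internal_iterations: int = 300
    lr_contribution_threshold: float = 0.003
    lr_contribution_mode: str = "individual_share"  # or "cumulative_prefix"
    # linear SVM via SGD
    svm_external_iterations: int = 100
    svm_per_iteration_zscore: float = 3.0
    # random forest
    rf_external_iterations: int = 100
    rf_estimators_per_iteration: int = 100
    rf_appearance_rule: str = "importance_zscore"  # or "positive_importance"
    rf_per_iteration_zscore: float = 3.0
    # stability rule shared by rf/svm
    appearance_threshold: float = 0.40
    subsample_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        for name in ("appearance_threshold", "subsample_fraction", "lr_contribution_threshold"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value!r}")
        for name in (
            "lr_max_internal_iterations",
            "svm_external_iterations",
            "rf_external_iterations",
            "rf_estimators_per_iteration",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lr_contribution_mode not in ("individual_share", "cumulative_prefix"):
            raise ValueError(
                f"unknown lr_contribution_mode {self.lr_contribution_mode!r}"
            )
        if self.rf_appearance_rule not in ("importance_zscore", "positive_importance"):
            raise ValueError(
                f"unknown rf_appearance_rule {self.rf_appearance_rule!r}"
            )

    @property
    def n_external_iterations(self) -> int:
        return (
            self.rf_external_iterations
            if self.method == "rf"
            else self.svm_external_iterations
        )


@dataclass
class IterationRecord:
    """Audit record of one external iteration (one refit on a subsample)."""

    iteration_index: int
    selected_families: set[str]
    importance_summary: pd.Series
    subsample_seed: int


@dataclass
class MethodSelection:
    """One selector's output over the family universe."""

    method: str
    appearance_frequency: pd.Series  # per-family frequency (rf/svm) or share (lr)
    retained: set[str]
    config_echo: SelectorConfig


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # One stream per (config seed, iteration index); reproducible and
    # independent across iterations.
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a stratified subsample preserving group proportions.

    The group coded 0 (group A) has its count rounded down on fractional
    ties; the other group is rounded up, keeping the total close to
    ``fraction`` of the genomes.
    """
    idx_a = np.flatnonzero(y == 0)
    idx_b = np.flatnonzero(y == 1)
    n_a = int(np.floor(fraction * len(idx_a)))
    n_b = int(np.ceil(fraction * len(idx_b)))
    n_b = min(n_b, len(idx_b))
    take_a = rng.choice(idx_a, size=n_a, replace=False)
    take_b = rng.choice(idx_b, size=n_b, replace=False)
    return np.sort(np.concatenate([take_a, take_b]))


def _fit_importances(
    X: np.ndarray, y: np.ndarray, config: SelectorConfig, random_state: int
) -> np.ndarray:
    if config.method == "rf":
        model = RandomForestClassifier(
            n_estimators=config.rf_estimators_per_iteration,
            criterion="gini",
            random_state=random_state,
            n_jobs=1,
        )
        model.fit(X, y)
        return model.feature_importances_
    if config.method == "svm":
        # Adaptive step-size schedule: the default 'optimal' schedule takes
        # large early steps on high-dimensional binary rows and can settle
        # on a slightly off hyperplane even for separable inputs.
        model = SGDClassifier(
            loss="hinge",
            penalty="l2",
            learning_rate="adaptive",
            eta0=0.01,
            random_state=random_state,
        )
        model.fit(X, y)
        return np.abs(model.coef_.ravel())
    raise ValueError(f"external iterations are defined for rf/svm, not {config.method}")


def _zscore_mask(values: np.ndarray, cutoff: float) -> np.ndarray:
    std = values.std()
    if std == 0:
        return np.zeros(values.shape, dtype=bool)
    return (values - values.mean()) / std > cutoff


def per_iteration_select(importances: pd.Series, config: SelectorConfig) -> set[str]:
    """Which families "appeared" in one external iteration.

    Both rf (Gini importances) and svm (absolute linear weights) produce
    dense score vectors, so by default a family counts as appearing only
    when its score is an outlier of the iteration's score distribution
    (z-score above the configured cutoff, default 3).  The rf
    ``positive_importance`` mode instead counts any strictly positive
    importance.  All-zero (or constant) scores select nothing.
    """
    values = importances.to_numpy(dtype=float)
    if config.method == "rf":
        if config.rf_appearance_rule == "positive_importance":
            mask = values > 0
        else:
            mask = _zscore_mask(values, config.rf_per_iteration_zscore)
    elif config.method == "svm":
        mask = _zscore_mask(values, config.svm_per_iteration_zscore)
    else:
        raise ValueError(f"per-iteration selection undefined for {config.method}")
    return set(importances.index[mask])


def run_external_iterations(
    pangenome: LabeledPangenome, config: SelectorConfig
) -> list[IterationRecord]:
    """Refit the configured model on stratified subsamples, once per iteration."""
    if config.method not in ("rf", "svm"):
        raise ValueError("external iterations apply to rf and svm only")
    X = pangenome.matrix.to_numpy(dtype=np.float32)
    y = pangenome.binary_labels()
    families = pangenome.matrix.columns

    records: list[IterationRecord] = []
    for it in range(config.n_external_iterations):
        rng = _iteration_rng(config.seed, it)
        sub_seed = int(rng.integers(2**31))
        idx = _stratified_subsample(y, config.subsample_fraction, rng)
        if len(np.unique(y[idx])) < 2:
            idx = _stratified_subsample(y, config.subsample_fraction, rng)
            if len(np.unique(y[idx])) < 2:
                raise ValueError(
                    f"iteration {it}: subsample contains a single class; "
                    "input is too small for stratified resampling"
                )
        importances = pd.Series(
            _fit_importances(X[idx], y[idx], config, random_state=sub_seed % (2**31)),
            index=families,
        )
        records.append(
            IterationRecord(
                iteration_index=it,
                selected_families=per_iteration_select(importances, config),
                importance_summary=importances,
                subsample_seed=sub_seed,
            )
        )
    return records


def stability_retain(
    records: list[IterationRecord],
    appearance_threshold: float = 0.40,
    config: SelectorConfig | None = None,
) -> MethodSelection:
    """Keep families that appeared in at least the threshold fraction of iterations."""
    if not records:
        raise ValueError("at least one iteration record is required")
    if config is None:
        config = SelectorConfig(appearance_threshold=appearance_threshold)
    universe = records[0].importance_summary.index
    counts = pd.Series(0, index=universe, dtype=float)
    for rec in records:
        counts.loc[list(rec.selected_families)] += 1
    frequency = counts / len(records)
    retained = set(frequency.index[frequency >= appearance_threshold])
    return MethodSelection(
        method=config.method,
        appearance_frequency=frequency,
        retained=retained,
        config_echo=replace(config, appearance_threshold=appearance_threshold),
    )


def lr_select(pangenome: LabeledPangenome, config: SelectorConfig) -> MethodSelection:
    """Single logistic-regression fit; retain by coefficient-mass share.

    The contribution share of family *f* is |coef_f| / sum|coef|.  Under
    ``individual_share`` a family is retained when its own share exceeds
    the threshold; under ``cumulative_prefix`` the families are sorted by
    decreasing |coef| and the shortest prefix whose summed share exceeds
    the threshold is retained.  A fit that hits the solver cap without
    converging is kept, with a warning (the cap is a hard budget).
    """
    X = pangenome.matrix.to_numpy(dtype=np.float32)
    y = pangenome.binary_labels()
    # L2 penalty is LogisticRegression's default regularization
    model = LogisticRegression(
        solver="lbfgs",
        max_iter=config.lr_max_internal_iterations,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        logger.warning(
            "logistic regression did not converge within %d iterations; "
            "coefficients retained as-is",
            config.lr_max_internal_iterations,
        )

    coefs = np.abs(model.coef_.ravel())
    total = coefs.sum()
    shares = pd.Series(
        coefs / total if total > 0 else np.zeros_like(coefs),
        index=pangenome.matrix.columns,
    )
    if total == 0:
        retained: set[str] = set()
    elif config.lr_contribution_mode == "individual_share":
        retained = set(shares.index[shares > config.lr_contribution_threshold])
    else:  # cumulative_prefix
        order = shares.sort_values(ascending=False, kind="stable")
        cumulative = order.cumsum()
        # shortest prefix whose summed share exceeds the threshold
        n_keep = int(np.searchsorted(cumulative.to_numpy(), config.lr_contribution_threshold, side="left")) + 1
        n_keep = min(n_keep, len(order))
        retained = set(order.index[:n_keep])
    return MethodSelection(
        method="lr",
        appearance_frequency=shares,
        retained=retained,
        config_echo=config,
    )


def run_selector(pangenome: LabeledPangenome, config: SelectorConfig) -> MethodSelection:
    """Dispatch: lr is a single fit; rf/svm run stability selection."""
    if config.method == "lr":
        return lr_select(pangenome, config)
    records = run_external_iterations(pangenome, config)
    return stability_retain(records, config.appearance_threshold, config=config)


def write_iteration_log(records: list[IterationRecord], path) -> None:
    """JSON-lines audit log: one object per external iteration."""
    import json

    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "iteration": rec.iteration_index,
                        "subsample_seed": rec.subsample_seed,
                        "selected_families": sorted(rec.selected_families),
                    }
                )
                + "\n"
            )


def write_selection_tsv(selection: MethodSelection, path) -> None:
    """family_id, appearance frequency (or coefficient share), retained flag."""
    out = pd.DataFrame(
        {
            "family_id": selection.appearance_frequency.index,
            "appearance_frequency": selection.appearance_frequency.to_numpy(),
            "retained": [
                int(f in selection.retained)
                for f in selection.appearance_frequency.index
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
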