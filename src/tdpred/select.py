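"""Per-fold feature selection: frequency filtering, correlation pruning, RFE.

Three stages run on training-fold rows only, in order: (1) target-annotation
columns kept only when annotated for at least ``min_count`` training
compounds; (2) greedy Pearson-correlation pruning (|r| > threshold against an
already-retained column drops the later column; constant columns drop); (3)
recursive feature elimination with a gradient-boosted-tree estimator down to a
fixed budget (400 features for three-family models, 300 for two, 200 for one).
Held-out rows are only ever masked by the fitted :class:`SelectionMask`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from xgboost import XGBClassifier

from .featurize import Family, FeatureMatrix

#: published feature budgets by number of feature families in the model
BUDGET_BY_N_FAMILIES = {1: 200, 2: 300, 3: 400}


def default_budget(matrix: FeatureMatrix) -> int:
    n_fam = len(set(matrix.families))
    return BUDGET_BY_N_FAMILIES.get(n_fam, BUDGET_BY_N_FAMILIES[3])


@dataclass
class SelectionMask:
    """Ordered retained feature names plus a per-stage provenance log."""

    retained: list[str]
    stage_log: list[dict] = field(default_factory=list)
    fold_id: str = ""
    seed: int = 0
    elimination_order: list[str] = field(default_factory=list)  # RFE drops, first-out first

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        return matrix.select_columns(self.retained)

    def to_json(self) -> str:
        return json.dumps({
            "retained": self.retained, "stage_log": self.stage_log,
            "fold_id": self.fold_id, "seed": self.seed,
            "elimination_order": self.elimination_order,
        })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, payload: str) -> "SelectionMask":
        return cls(**json.loads(payload))


def filter_target_frequency(matrix: FeatureMatrix, min_count: int = 2) -> FeatureMatrix:
    """Drop TARGET columns annotated for fewer than ``min_count`` compounds."""
    keep = []
    for j, meta in enumerate(matrix.metas):
        if meta.family == Family.TARGET and matrix.values[:, j].sum() < min_count:
            continue
        keep.append(meta.name)
    return matrix.select_columns(keep)


def correlation_filter(matrix: FeatureMatrix, threshold: float = 0.8) -> FeatureMatrix:
    """Greedy pruning of highly correlated columns in stable input order.

    A column is dropped when its |Pearson r| with any already-retained column
    exceeds ``threshold``; constant columns (undefined r) are dropped outright.
    """
    X = matrix.values
    n, p = X.shape
    std = X.std(axis=0)
    centered = X - X.mean(axis=0)
    z = centered / np.where(std > 0, std, 1.0)
    retained_idx: list[int] = []
    for j in range(p):
        if std[j] == 0:
            continue
        if retained_idx:
            r = z[:, retained_idx].T @ z[:, j] / n
            if np.any(np.abs(r) > threshold):
                continue
        retained_idx.append(j)
    return matrix.select_columns([matrix.metas[j].name for j in retained_idx])


def _rfe_estimator(seed: int, config: dict | None = None) -> XGBClassifier:
    params = dict(n_estimators=100, max_depth=4, learning_rate=0.1,
                  objective="binary:logistic", eval_metric="auc",
                  random_state=seed, n_jobs=1, verbosity=0)
    if config:
        params.update(config)
    return XGBClassifier(**params)


def rfe(matrix: FeatureMatrix, labels: Sequence[int], budget: int,
        step: float | int = 0.05, seed: int = 0,
        estimator_config: dict | None = None) -> SelectionMask:
    """Recursive feature elimination with a gradient-boosted-tree ranker.

    Repeatedly fits the estimator on the surviving columns, ranks by gain
    importance and removes the lowest-ranked ``step`` columns (a float step is
    a fraction of the current column count, min 1; the final step truncates to
    land exactly on the budget).  Identity when budget >= column count.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    y = np.asarray(labels)
    names = list(matrix.names)
    eliminated: list[str] = []
    current = names
    while len(current) > budget:
        sub = matrix.select_columns(current)
        est = _rfe_estimator(seed, estimator_config)
        est.fit(sub.values, y)
        importances = est.feature_importances_
        k = step if isinstance(step, int) else max(1, int(round(step * len(current))))
        k = min(k, len(current) - budget)
        # lowest importance out; ties broken by later column position (stable)
        order = np.argsort(importances, kind="stable")
        drop = set(order[:k].tolist())
        eliminated.extend(current[j] for j in sorted(drop))
        current = [nm for j, nm in enumerate(current) if j not in drop]
    return SelectionMask(retained=current, seed=seed, elimination_order=eliminated)


def select_features(matrix: FeatureMatrix, labels: Sequence[int],
                    budget: int | None = None, min_count: int = 2,
                    threshold: float = 0.8, step: float | int = 0.05,
                    seed: int = 0, fold_id: str = "") -> SelectionMask:
    """The full staged pipeline on training rows; returns the fitted mask."""
    budget = budget if budget is not None else default_budget(matrix)
    log = [{"stage": "input", "n_columns": len(matrix.metas)}]
    m1 = filter_target_frequency(matrix, min_count=min_count)
    log.append({"stage": "target_frequency", "n_columns": len(m1.metas)})
    m2 = correlation_filter(m1, threshold=threshold)
    log.append({"stage": "correlation", "n_columns": len(m2.metas)})
    mask = rfe(m2, labels, budget=budget, step=step, seed=seed)
    log.append({"stage": "rfe", "n_columns": len(mask.retained)})
    mask.stage_log = log
    mask.fold_id = fold_id
    return mask
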