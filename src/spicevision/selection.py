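"""Sequential forward selection of efficient features.

The criterion is the cross-validated fit deviance: for a candidate feature
subset, fit an intercept + linear least-squares model of the one-hot class
indicators on the (z-scored) features of the training folds and accumulate
the residual sum of squares on the held-out folds; the criterion is the
mean held-out RSS over stratified CV folds.  Forward search accepts, at
each step, the unselected feature with the smallest criterion, provided it
improves on the current value by more than a relative tolerance; ties break
toward the lowest feature index.  Standardization statistics come from the
training folds only, so the criterion never peeks at held-out samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable


@dataclass
class SelectionResult:
    selected: list[int]
    selected_names: list[str]
    criterion_trajectory: list[float]
    baseline_criterion: float
    cv_folds: int
    seed: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "selected_indices": self.selected,
                "selected_names": self.selected_names,
                "criterion_trajectory": self.criterion_trajectory,
                "baseline_criterion": self.baseline_criterion,
                "cv_folds": self.cv_folds,
                "seed": self.seed,
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(selected=d["selected_indices"], selected_names=d["selected_names"],
                   criterion_trajectory=d["criterion_trajectory"],
                   baseline_criterion=d["baseline_criterion"],
                   cv_folds=d["cv_folds"], seed=d["seed"])


def _one_hot(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    return (labels[:, None] == classes[None, :]).astype(float)


def cv_deviance(X: np.ndarray, Y: np.ndarray, subset: list[int],
                folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean held-out RSS of the linear one-hot fit on a feature subset."""
    rss = []
    for tr, te in folds:
        if subset:
            mu = X[tr][:, subset].mean(axis=0)
            sd = X[tr][:, subset].std(axis=0)
            sd[sd == 0] = 1.0
            a_tr = np.column_stack([np.ones(len(tr)), (X[tr][:, subset] - mu) / sd])
            a_te = np.column_stack([np.ones(len(te)), (X[te][:, subset] - mu) / sd])
        else:
            a_tr = np.ones((len(tr), 1))
            a_te = np.ones((len(te), 1))
        beta, *_ = np.linalg.lstsq(a_tr, Y[tr], rcond=None)
        resid = Y[te] - a_te @ beta
        rss.append(float((resid ** 2).sum()))
    return float(np.mean(rss))


def make_folds(labels: np.ndarray, cv_folds: int, seed: int
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def sfs_select(
    table: FeatureTable,
    cv_folds: int = 5,
    max_features: int = 20,
    tol: float = 1e-6,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward selection under the cross-validated deviance criterion."""
    X = table.features.to_numpy(dtype=float)
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("selection needs at least two classes")
    if table.n_samples <= cv_folds:
        raise ValueError("need more samples than CV folds")
    if max_features > X.shape[1]:
        raise ValueError(f"max_features={max_features} exceeds the "
                         f"{X.shape[1]} available features")
    Y = _one_hot(labels)
    folds = make_folds(labels, cv_folds, seed)

    selected: list[int] = []
    trajectory: list[float] = []
    current = cv_deviance(X, Y, selected, folds)
    baseline = current
    remaining = list(range(X.shape[1]))
    while len(selected) < max_features and remaining:
        best_idx, best_crit = None, None
        for j in remaining:
            crit = cv_deviance(X, Y, selected + [j], folds)
            if best_crit is None or crit < best_crit:  # strict: lowest index wins ties
                best_idx, best_crit = j, crit
        if best_crit >= current - tol * abs(current):
            break
        selected.append(best_idx)
        remaining.remove(best_idx)
        current = best_crit
        trajectory.append(current)

    names = table.feature_names
    return SelectionResult(
        selected=selected,
        selected_names=[names[j] for j in selected],
        criterion_trajectory=trajectory,
        baseline_criterion=baseline,
        cv_folds=cv_folds,
        seed=seed,
    )


def report_efficient_features(result: SelectionResult, table: FeatureTable
                              ) -> pd.DataFrame:
    """Per-level mean of each selected feature (one column per level)."""
    if not result.selected:
        return pd.DataFrame(columns=["feature"])
    if table.levels is not None:
        groups = table.levels
        col_names = [f"{v:g}" for v in sorted(np.unique(groups))]
    else:
        groups = table.labels
        col_names = [f"class_{c}" for c in sorted(np.unique(groups))]
    rows = []
    for j, name in zip(result.selected, result.selected_names):
        vals = table.features.iloc[:, j].to_numpy()
        means = [float(vals[groups == g].mean()) for g in sorted(np.unique(groups))]
        rows.append([name] + means)
    return pd.DataFrame(rows, columns=["feature"] + col_names)
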