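"""ANN structure sweep and one-vs-one Gaussian-kernel SVM classification.

Two protocols operate on a selected feature table:

* An artificial neural network with one hidden layer; both the hidden and
  output layers use the hyperbolic-tangent sigmoid (tansig).  The network
  is trained to minimize mean squared error against one-hot 0/1 targets,
  with early stopping on the validation partition.  A sweep trains one
  network per hidden-layer size (default 1..20) and picks the structure
  with the highest overall correct-classification rate, ties broken by
  lower validation error and then smaller hidden layer.
* A one-vs-one soft-margin SVM with Gaussian (RBF) kernel: K(K-1)/2 binary
  classifiers, prediction by majority vote with ties broken by the largest
  summed decision margin and then the lowest class index.

Both classifiers standardize features with training-set statistics, so they
are invariant to affine rescaling of any single feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .features import FeatureTable


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (validation may be 0)."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        tr, va, te = self.fractions
        if min(self.fractions) < 0 or abs(tr + va + te - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        if tr <= 0:
            raise ValueError("training fraction must be positive")


def split_dataset(table: FeatureTable, spec: SplitSpec
                  ) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Disjoint, exhaustive (and by default stratified) partitions."""
    n = table.n_samples
    idx = np.arange(n)
    tr_f, va_f, te_f = spec.fractions
    strat = table.labels if spec.stratified else None

    if te_f > 0:
        rest, test_idx = train_test_split(
            idx, test_size=te_f, random_state=spec.seed, stratify=strat)
    else:
        rest, test_idx = idx, np.array([], dtype=int)
    if va_f > 0:
        strat_rest = table.labels[rest] if spec.stratified else None
        train_idx, val_idx = train_test_split(
            rest, test_size=va_f / (tr_f + va_f),
            random_state=spec.seed, stratify=strat_rest)
    else:
        train_idx, val_idx = rest, np.array([], dtype=int)
    return (table.take(np.sort(train_idx)),
            table.take(np.sort(val_idx)),
            table.take(np.sort(test_idx)))


# ---------------------------------------------------------------------------
# Feature standardization shared by both classifiers
# ---------------------------------------------------------------------------

@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(mean=X.mean(axis=0), std=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _xy(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    return table.features.to_numpy(dtype=float), table.labels


def one_hot_targets(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """0/1 one-hot coding of 1-based class labels."""
    return (labels[:, None] == np.arange(1, n_classes + 1)[None, :]).astype(float)


# ---------------------------------------------------------------------------
# Neural network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes_to_sweep: tuple[int, ...] = tuple(range(1, 21))
    max_epochs: int = 400
    patience: int = 30
    learning_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes_to_sweep) == 0:
            raise ValueError("sweep must be nonempty")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class MLPModel:
    """Single-hidden-layer tanh/tanh network with its scaler and training log."""

    w1: np.ndarray = field(repr=False)
    b1: np.ndarray = field(repr=False)
    w2: np.ndarray = field(repr=False)
    b2: np.ndarray = field(repr=False)
    scaler: _Scaler = field(repr=False)
    n_classes: int = 0
    log: pd.DataFrame = field(default=None, repr=False)
    best_epoch: int = 0
    best_validation_error: float = np.nan

    @property
    def hidden_size(self) -> int:
        return self.w1.shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = np.tanh(self.scaler.transform(X) @ self.w1 + self.b1)
        return np.tanh(h @ self.w2 + self.b2)

    def predict(self, table_or_X) -> np.ndarray:
        X = table_or_X.features.to_numpy(dtype=float) \
            if isinstance(table_or_X, FeatureTable) else np.asarray(table_or_X, dtype=float)
        return np.argmax(self.forward(X), axis=1) + 1


def train_mlp(train: FeatureTable, validation: FeatureTable | None,
              hidden_size: int, cfg: MLPConfig) -> MLPModel:
    """Train one network; early stopping on validation MSE with patience."""
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    if train.n_samples == 0:
        raise ValueError("empty training partition")
    X, y = _xy(train)
    n_classes = int(max(y.max(), 1))
    scaler = _Scaler.fit(X)
    Xs = scaler.transform(X)
    Y = one_hot_targets(y, n_classes)

    has_val = validation is not None and validation.n_samples > 0
    if has_val:
        Xv, yv = _xy(validation)
        Xvs = scaler.transform(Xv)
        Yv = one_hot_targets(yv, n_classes)

    rng = np.random.default_rng((cfg.seed, hidden_size))
    d = X.shape[1]
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden_size))
    b1 = np.zeros(hidden_size)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_size), size=(hidden_size, n_classes))
    b2 = np.zeros(n_classes)

    # full-batch Adam on the MSE objective
    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best = {"err": np.inf, "epoch": 0, "weights": [p.copy() for p in params]}
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        h = np.tanh(Xs @ w1 + b1)
        o = np.tanh(h @ w2 + b2)
        train_mse = float(((o - Y) ** 2).mean())

        do = 2.0 * (o - Y) / o.size * (1.0 - o ** 2)
        gw2 = h.T @ do
        gb2 = do.sum(axis=0)
        dh = (do @ w2.T) * (1.0 - h ** 2)
        gw1 = Xs.T @ dh
        gb1 = dh.sum(axis=0)
        for p, g, mi, vi in zip(params, [gw1, gb1, gw2, gb2], m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g * g
            mhat = mi / (1 - beta1 ** epoch)
            vhat = vi / (1 - beta2 ** epoch)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        if has_val:
            hv = np.tanh(Xvs @ w1 + b1)
            ov = np.tanh(hv @ w2 + b2)
            val_mse = float(((ov - Yv) ** 2).mean())
        else:
            val_mse = train_mse
        rows.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
        if val_mse < best["err"] - 1e-12:
            best = {"err": val_mse, "epoch": epoch,
                    "weights": [p.copy() for p in params]}
        elif has_val and epoch - best["epoch"] >= cfg.patience:
            break

    w1, b1, w2, b2 = best["weights"]
    return MLPModel(w1=w1, b1=b1, w2=w2, b2=b2, scaler=scaler,
                    n_classes=n_classes, log=pd.DataFrame(rows),
                    best_epoch=best["epoch"],
                    best_validation_error=best["err"])


@dataclass
class SweepResult:
    records: pd.DataFrame
    chosen_hidden_size: int
    chosen_model: MLPModel = field(repr=False)


def sweep_structures(train: FeatureTable, validation: FeatureTable,
                     test: FeatureTable, cfg: MLPConfig) -> SweepResult:
    """One model per hidden size; choose by overall CCR, then validation
    error, then smaller hidden layer."""
    from .evaluate import overall_correlation

    all_X = np.vstack([t.features.to_numpy(dtype=float)
                       for t in (train, validation, test) if t.n_samples])
    all_y = np.concatenate([t.labels for t in (train, validation, test)
                            if t.n_samples])
    n_classes = int(all_y.max())
    targets = one_hot_targets(all_y, n_classes)

    records = []
    models = {}
    for hs in cfg.hidden_sizes_to_sweep:
        model = train_mlp(train, validation, hs, cfg)
        models[hs] = model
        outputs = model.forward(all_X)
        pred = np.argmax(outputs, axis=1) + 1
        ccr = float((pred == all_y).mean())
        records.append({
            "hidden_size": hs,
            "best_validation_error": model.best_validation_error,
            "overall_correlation": overall_correlation(targets, outputs),
            "overall_ccr": ccr,
        })
    df = pd.DataFrame(records)
    order = df.sort_values(
        by=["overall_ccr", "best_validation_error", "hidden_size"],
        ascending=[False, True, True], kind="stable")
    chosen = int(order.iloc[0]["hidden_size"])
    return SweepResult(records=df, chosen_hidden_size=chosen,
                       chosen_model=models[chosen])


# ---------------------------------------------------------------------------
# One-vs-one SVM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMConfig:
    C: float = 1000.0
    gamma: float | None = None     # None -> 1 / (n_features * mean train variance)
    tol: float = 1e-7              # solver tolerance (the toolbox "lambda")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class SVMOvOModel:
    """K(K-1)/2 binary RBF classifiers with vote/margin/lowest-index prediction."""

    classifiers: dict[tuple[int, int], SVC] = field(repr=False)
    scaler: _Scaler = field(repr=False)
    classes: np.ndarray = field(default=None)

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    def predict(self, table_or_X) -> np.ndarray:
        X = table_or_X.features.to_numpy(dtype=float) \
            if isinstance(table_or_X, FeatureTable) else np.asarray(table_or_X, dtype=float)
        Xs = self.scaler.transform(X)
        n = len(Xs)
        k = len(self.classes)
        votes = np.zeros((n, k))
        margins = np.zeros((n, k))
        pos = {c: i for i, c in enumerate(self.classes)}
        for (ci, cj), clf in self.classifiers.items():
            dec = clf.decision_function(Xs)  # positive -> class cj (larger label)
            win = np.where(dec > 0, pos[cj], pos[ci])
            votes[np.arange(n), win] += 1
            margins[np.arange(n), win] += np.abs(dec)
        # lexicographic: votes, then summed margin, then lowest class index
        order = np.lexsort((np.arange(k)[None, :].repeat(n, axis=0),
                            -margins, -votes), axis=1)
        return self.classes[order[:, 0]]


def train_svm_ovo(train: FeatureTable, cfg: SVMConfig = SVMConfig()) -> SVMOvOModel:
    X, y = _xy(train)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("SVM training needs at least two classes")
    scaler = _Scaler.fit(X)
    Xs = scaler.transform(X)
    gamma = cfg.gamma
    if gamma is None:
        mv = float(Xs.var(axis=0).mean())
        gamma = 1.0 / (X.shape[1] * mv) if mv > 0 else 1.0 / X.shape[1]
    classifiers = {}
    for ci, cj in combinations(classes.tolist(), 2):
        mask = (y == ci) | (y == cj)
        clf = SVC(kernel="rbf", C=cfg.C, gamma=gamma, tol=cfg.tol,
                  random_state=cfg.seed)
        clf.fit(Xs[mask], y[mask])
        classifiers[(ci, cj)] = clf
    return SVMOvOModel(classifiers=classifiers, scaler=scaler, classes=classes)
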