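"""Shared evaluation machinery: splits, cross-validated accuracy, tuning.

All strategies score candidate variable subsets the same way: categorical
and cluster-id predictors are one-hot encoded, continuous and ordinal
predictors are standardized with training-fold statistics, and a support
vector machine (libsvm via scikit-learn) supplies the classifier.  The
concordance statistic is the normalized Mann-Whitney U over all
positive-negative pairs, with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.svm import SVC

from .datagen import Dataset

__all__ = [
    "TuningConfig",
    "EvalProtocol",
    "ConfusionCounts",
    "accuracy",
    "c_statistic",
    "FeatureEncoding",
    "encode_features",
    "CVEvaluator",
    "cv_accuracy",
    "tune",
    "default_grid",
    "split_train_test",
    "holdout_accuracy",
]


@dataclass(frozen=True)
class TuningConfig:
    """SVM hyperparameters: kernel family, cost C, and RBF width gamma."""

    kernel: str = "rbf"
    C: float = 10.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel == "rbf" and self.gamma <= 0:
            raise ValueError("gamma must be > 0 for the rbf kernel")

    def make_svm(self) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=self.C, cache_size=256)
        return SVC(kernel="rbf", C=self.C, gamma=self.gamma, cache_size=256)


@dataclass(frozen=True)
class EvalProtocol:
    """Train/test split fraction, CV fold count, and the seed policy."""

    test_fraction: float = 0.2
    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if counts.total <= 0:
        raise ValueError("accuracy undefined for zero evaluated subjects")
    return (counts.tp + counts.tn) / counts.total


def c_statistic(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).

    Computed from midranks (Mann-Whitney U), equivalent to the area under
    the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("c_statistic requires both outcome classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

@dataclass
class FeatureEncoding:
    """Encoded design matrix with per-variable column blocks.

    ``blocks[name]`` gives the column indices of that variable; one-hot
    columns of categorical/cluster-id variables stay 0/1, every other
    column is flagged in ``scale_mask`` for training-fold standardization.
    """

    X: np.ndarray
    y: np.ndarray
    blocks: dict[str, np.ndarray]
    scale_mask: np.ndarray

    def columns_for(self, features: Iterable[str]) -> np.ndarray:
        return np.concatenate([self.blocks[f] for f in features])


def encode_features(data: Dataset) -> FeatureEncoding:
    """One-hot categorical/cluster-id variables; pass others through."""
    cols: list[np.ndarray] = []
    blocks: dict[str, np.ndarray] = {}
    scale: list[bool] = []
    start = 0
    for var in data.variables:
        values = data.frame[var.name]
        if var.kind in ("categorical", "cluster-id"):
            dummies = pd.get_dummies(values, dtype=float)
            dummies = dummies.reindex(sorted(dummies.columns), axis=1)
            block = dummies.to_numpy()
            scale.extend([False] * block.shape[1])
        else:
            block = values.to_numpy(dtype=float)[:, None]
            scale.append(True)
        cols.append(block)
        blocks[var.name] = np.arange(start, start + block.shape[1])
        start += block.shape[1]
    X = np.hstack(cols)
    y = data.frame[data.outcome_name].to_numpy(dtype=int)
    return FeatureEncoding(X, y, blocks, np.asarray(scale))


def _canonical_order(data: Dataset) -> np.ndarray:
    """Row permutation keyed on the patient ID when present.

    Keying folds on a canonical ordering makes CV results invariant to how
    the rows happen to be stored.
    """
    if "ID" in data.frame.columns and data.frame["ID"].is_unique:
        return np.argsort(data.frame["ID"].to_numpy(), kind="stable")
    return np.arange(len(data.frame))


class CVEvaluator:
    """Seeded k-fold evaluator reused across many candidate subsets.

    Folds and per-fold standardization statistics are computed once; each
    ``accuracy_of(features)`` call only slices columns and fits the SVM.
    """

    def __init__(self, data: Dataset, protocol: EvalProtocol):
        self.protocol = protocol
        self.encoding = encode_features(data)
        order = _canonical_order(data)
        y = self.encoding.y
        if protocol.stratified:
            splitter = StratifiedKFold(n_splits=protocol.n_folds, shuffle=True,
                                       random_state=protocol.seed)
        else:
            splitter = KFold(n_splits=protocol.n_folds, shuffle=True,
                             random_state=protocol.seed)
        self.folds: list[tuple[np.ndarray, np.ndarray]] = []
        for tr, te in splitter.split(order[:, None], y[order]):
            self.folds.append((order[tr], order[te]))
        for _, te in self.folds:
            held = y[te]
            if not protocol.stratified and held.min() == held.max():
                raise ValueError(
                    "a CV fold holds a single outcome class; use stratified folds"
                )
        # per-fold training means / sds over all columns (sliced per subset)
        X = self.encoding.X
        self._stats = []
        for tr, _ in self.folds:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            self._stats.append((mu, sd))
        self.n_evaluations = 0

    def _standardize(self, X: np.ndarray, cols: np.ndarray, mu, sd) -> np.ndarray:
        Z = X[:, cols].copy()
        mask = self.encoding.scale_mask[cols]
        Z[:, mask] = (Z[:, mask] - mu[cols][mask]) / sd[cols][mask]
        return Z

    def accuracy_of(self, features: Sequence[str],
                    tuning: TuningConfig) -> float:
        """Mean k-fold accuracy of the SVM on the given variable subset."""
        if not features:
            raise ValueError("feature subset must be nonempty")
        cols = self.encoding.columns_for(features)
        X, y = self.encoding.X, self.encoding.y
        accs = []
        for (tr, te), (mu, sd) in zip(self.folds, self._stats):
            clf = tuning.make_svm()
            clf.fit(self._standardize(X[tr], cols, mu, sd), y[tr])
            pred = clf.predict(self._standardize(X[te], cols, mu, sd))
            accs.append(float(np.mean(pred == y[te])))
        self.n_evaluations += 1
        return float(np.mean(accs))


def cv_accuracy(data: Dataset, features: Sequence[str], tuning: TuningConfig,
                protocol: EvalProtocol) -> float:
    """Mean stratified k-fold CV accuracy of the SVM on ``features``."""
    y = data.frame[data.outcome_name]
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    return CVEvaluator(data, protocol).accuracy_of(features, tuning)


def default_grid() -> list[TuningConfig]:
    """Canonical tuning grid: linear before rbf, ascending C, ascending gamma."""
    grid = [TuningConfig("linear", C) for C in (0.1, 1.0, 10.0)]
    grid += [TuningConfig("rbf", C, g) for C in (0.1, 1.0, 10.0)
             for g in (0.1, 1.0)]
    return grid


def tune(data: Dataset, features: Sequence[str], grid: Sequence[TuningConfig],
         protocol: EvalProtocol) -> TuningConfig:
    """Grid point minimizing CV mean squared error of the 0/1 predictions.

    For binary labels and hard predictions the MSE equals the
    misclassification rate, so this maximizes CV accuracy; ties keep the
    earliest grid point.
    """
    if not grid:
        raise ValueError("tuning grid must be nonempty")
    evaluator = CVEvaluator(data, protocol)
    best, best_err = None, np.inf
    for cfg in grid:
        err = 1.0 - evaluator.accuracy_of(features, cfg)
        if err < best_err:
            best, best_err = cfg, err
    return best


def split_train_test(data: Dataset, protocol: EvalProtocol) -> tuple[Dataset, Dataset]:
    """Seeded, stratified, disjoint and exhaustive 80/20-style split."""
    y = data.frame[data.outcome_name].to_numpy()
    idx = data.frame.index.to_numpy()
    if len(idx) < max(5, int(np.ceil(1 / min(protocol.test_fraction,
                                             1 - protocol.test_fraction)))):
        raise ValueError("dataset too small to split")
    strat = y if protocol.stratified else None
    tr, te = train_test_split(idx, test_size=protocol.test_fraction,
                              random_state=protocol.seed, stratify=strat)
    train, test = data.subset_rows(np.sort(tr)), data.subset_rows(np.sort(te))
    for part in (train, test):
        if part.frame[data.outcome_name].nunique() < 2:
            raise ValueError("split left a part with a single outcome class")
    return train, test


def holdout_accuracy(train: Dataset, test: Dataset, features: Sequence[str],
                     tuning: TuningConfig) -> float:
    """Fit on the training part and score accuracy on the held-out part."""
    enc_tr = encode_features(train)
    enc_te = encode_features(test)
    # align one-hot blocks: rebuild test blocks on the train dataset's levels
    Xtr, Xte = _aligned_matrices(train, test, features)
    ytr = enc_tr.y
    yte = enc_te.y
    clf = tuning.make_svm()
    clf.fit(Xtr, ytr)
    return float(np.mean(clf.predict(Xte) == yte))


def _aligned_matrices(train: Dataset, test: Dataset,
                      features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode train and test on the union of observed category levels,
    standardizing with training statistics."""
    tr_cols, te_cols = [], []
    for name in features:
        var = train.meta(name)
        a = train.frame[name]
        b = test.frame[name]
        if var.kind in ("categorical", "cluster-id"):
            levels = sorted(set(a.unique()) | set(b.unique()))
            da = pd.get_dummies(a, dtype=float).reindex(columns=levels, fill_value=0.0)
            db = pd.get_dummies(b, dtype=float).reindex(columns=levels, fill_value=0.0)
            tr_cols.append(da.to_numpy())
            te_cols.append(db.to_numpy())
        else:
            mu, sd = a.mean(), a.std(ddof=0)
            sd = sd if sd > 0 else 1.0
            tr_cols.append(((a - mu) / sd).to_numpy()[:, None])
            te_cols.append(((b - mu) / sd).to_numpy()[:, None])
    return np.hstack(tr_cols), np.hstack(te_cols)
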