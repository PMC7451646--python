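"""Shared dataset builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from stepsvm.datagen import Dataset, VariableMeta


def make_continuous_dataset(X: np.ndarray, y: np.ndarray,
                            names: list[str] | None = None) -> Dataset:
    """Wrap a numeric matrix and binary labels as a Dataset of continuous
    predictors (with a synthetic ID column for canonical row ordering)."""
    n, m = X.shape
    names = names or [f"v{i:02d}" for i in range(1, m + 1)]
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "ID", np.arange(1, n + 1))
    frame["remission"] = np.asarray(y, dtype=int)
    return Dataset(frame, [VariableMeta(nm, "continuous") for nm in names])


def planted_margin_dataset(n: int = 1000, n_noise: int = 7, seed: int = 0,
                           margin: float = 0.4) -> Dataset:
    """Three signal variables determine the class through a separating
    margin; the remaining variables are independent noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(4 * n, 3 + n_noise))
    s = X[:, :3].sum(axis=1) / np.sqrt(3)
    keep = np.abs(s) > margin
    X, s = X[keep][:n], s[keep][:n]
    names = [f"sig{i}" for i in (1, 2, 3)] + [f"noise{i}" for i in range(1, n_noise + 1)]
    return make_continuous_dataset(X, (s > 0).astype(int), names)


def staircase_dataset(n: int = 500, m: int = 26, seed: int = 0) -> Dataset:
    """Five nested signal variables of decreasing strength, so each forward
    stage of a selection run has a strictly better candidate."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    coef = np.zeros(m)
    coef[:5] = [1.0, 0.9, 0.7, 0.55, 0.45]
    s = X @ coef + rng.normal(0, 0.15, n)
    return make_continuous_dataset(X, (s > 0).astype(int))


def xor_dataset(n: int = 240, n_noise: int = 0, seed: int = 0) -> Dataset:
    """Class = XOR of the signs of the first two variables: invisible to a
    linear decision function, easy for an RBF kernel."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2 + n_noise))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
    names = ["xa", "xb"] + [f"noise{i}" for i in range(1, n_noise + 1)]
    return make_continuous_dataset(X, y, names)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_cstat(scores, labels) -> float:
    """All-pairs concordance: wins count 1, ties 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_rfe_order(data: Dataset, C: float) -> list[str]:
    """Re-fit-and-rank RFE written from scratch for all-continuous data:
    standardize with full-data statistics, fit a linear SVC on the
    survivors, drop the column with the smallest squared weight."""
    names = list(data.predictor_names)
    X = data.frame[names].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    y = data.frame[data.outcome_name].to_numpy(dtype=int)
    surviving = list(range(len(names)))
    order = []
    while len(surviving) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, surviving], y)
        w2 = clf.coef_.ravel() ** 2
        worst = surviving[int(np.argmin(w2))]
        surviving.remove(worst)
        order.append(names[worst])
    order.append(names[surviving[0]])
    return order
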