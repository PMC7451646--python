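"""Comparator strategies: SVM-RFE and stepwise logistic regression.

SVM-RFE fits a linear-kernel SVM on the surviving variables, ranks each
variable by the sum of squared weights over its encoded column block,
removes the lowest-ranked variable, and repeats until none remain; the
variables eliminated last are the selected ones.

The stepwise logistic regression is the conventional AIC-driven forward
selection with backward checks, fitted to the aggregate data (no
multilevel terms), and summarized by the concordance statistic of the
fitted linear predictor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datagen import Dataset
from .evaluation import (
    EvalProtocol,
    TuningConfig,
    c_statistic,
    encode_features,
)

__all__ = ["RFERanking", "LogisticPath", "svm_rfe", "stepwise_logistic"]

log = logging.getLogger(__name__)


@dataclass
class RFERanking:
    """Elimination order (first eliminated first) and the retained top k."""

    elimination_order: list[str]
    selected_top_k: list[str]


@dataclass
class LogisticPath:
    """Variables in entry order with the criterion value after each entry."""

    steps: list[tuple[str, float]]
    final_c_statistic: float

    @property
    def selected(self) -> list[str]:
        return [name for name, _ in self.steps]


def svm_rfe(data: Dataset, k: int, tuning: TuningConfig,
            protocol: EvalProtocol | None = None) -> RFERanking:
    """Recursive feature elimination with a linear SVM.

    One variable is removed per iteration.  Multi-column (one-hot)
    variables are ranked by the sum of squared weights over their block;
    on a tied minimum the variable earliest in roster order is eliminated
    (first-minimum rule), so runs are deterministic.
    """
    if tuning.kernel != "linear":
        raise ValueError("svm_rfe requires a linear kernel (weight vector needed)")
    names = data.predictor_names
    if not 0 <= k <= len(names):
        raise ValueError("k must lie in [0, m]")

    enc = encode_features(data)
    X, y = enc.X.copy(), enc.y
    # standardize scalable columns once with full-data statistics
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    m = enc.scale_mask
    X[:, m] = (X[:, m] - mu[m]) / sd[m]

    surviving = list(names)
    eliminated: list[str] = []
    while surviving:
        if len(surviving) == 1:
            eliminated.append(surviving.pop())
            break
        cols = enc.columns_for(surviving)
        clf = tuning.make_svm()
        clf.fit(X[:, cols], y)
        w = np.zeros(X.shape[1])
        w[cols] = clf.coef_.ravel()
        scores = np.array([np.sum(w[enc.blocks[name]] ** 2) for name in surviving])
        worst = int(np.argmin(scores))  # first minimum -> earliest in roster order
        eliminated.append(surviving.pop(worst))
    selected = eliminated[len(eliminated) - k:][::-1] if k else []
    return RFERanking(eliminated, selected)


def _logit_design(data: Dataset, features: list[str]) -> pd.DataFrame:
    """Regression design in the aggregate-data convention: categorical
    variables enter as dummy blocks, ordinal/continuous as numeric columns,
    and cluster identifiers as their (uninformative) numeric codes — the way
    an integer ID column enters a plain GLM formula."""
    cols = []
    for name in features:
        var = data.meta(name)
        s = data.frame[name]
        if var.kind == "categorical":
            d = pd.get_dummies(s, prefix=name, drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(s.astype(float).to_frame(name))
    out = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=data.frame.index)
    out.insert(0, "const", 1.0)
    return out


def _fit_aic(data: Dataset, features: list[str]) -> tuple[float, np.ndarray]:
    """AIC and fitted probabilities of the logistic model on ``features``."""
    X = _logit_design(data, features)
    y = data.frame[data.outcome_name].astype(float)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=50)
        aic = float(res.aic)
        fitted = np.asarray(res.fittedvalues)
    if not np.isfinite(aic):
        raise ValueError("non-finite AIC (likely separation)")
    return aic, fitted


def stepwise_logistic(data: Dataset, max_size: int = 5) -> LogisticPath:
    """Forward AIC selection with backward checks, capped at ``max_size``.

    A candidate whose fit fails (separation, non-convergence) is skipped
    with a warning.  The final concordance statistic uses the fitted
    linear predictor on the full data.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    y = data.frame[data.outcome_name]
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")

    selected: list[str] = []
    steps: list[tuple[str, float]] = []
    current_aic, current_fit = _fit_aic(data, [])

    while len(selected) < max_size:
        best_name, best_aic, best_fit = None, current_aic, None
        for name in data.predictor_names:
            if name in selected:
                continue
            try:
                aic, fit = _fit_aic(data, selected + [name])
            except Exception as exc:  # skip non-convergent candidates
                log.warning("skipping candidate %s: %s", name, exc)
                continue
            if aic < best_aic - 1e-9:
                best_name, best_aic, best_fit = name, aic, fit
        if best_name is None:
            break
        selected.append(best_name)
        current_aic, current_fit = best_aic, best_fit
        steps.append((best_name, best_aic))

        # backward check: drop any earlier entry whose removal lowers AIC
        improved = True
        while improved and len(selected) > 1:
            improved = False
            for name in selected[:-1]:
                reduced = [v for v in selected if v != name]
                try:
                    aic, fit = _fit_aic(data, reduced)
                except Exception:
                    continue
                if aic < current_aic - 1e-9:
                    selected = reduced
                    current_aic, current_fit = aic, fit
                    steps = [s for s in steps if s[0] != name]
                    improved = True
                    break

    if selected:
        # fitted probabilities are rank-equivalent to the linear predictor
        cstat = c_statistic(current_fit, y.to_numpy())
    else:
        cstat = 0.5
    return LogisticPath(steps, cstat)
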