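import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_cstat, make_continuous_dataset, xor_dataset
from stepsvm.datagen import Dataset
from stepsvm.evaluation import (
    ConfusionCounts,
    EvalProtocol,
    TuningConfig,
    accuracy,
    c_statistic,
    cv_accuracy,
    split_train_test,
    tune,
)


@pytest.mark.parametrize("counts, expected", [
    (ConfusionCounts(5, 5, 0, 0), 1.0),
    (ConfusionCounts(0, 0, 5, 5), 0.0),
    (ConfusionCounts(3, 4, 2, 1), 0.7),
])
def test_accuracy_examples(counts, expected):
    assert accuracy(counts) == pytest.approx(expected)
    # invariant under relabelling the positive class
    swapped = ConfusionCounts(counts.tn, counts.tp, counts.fn, counts.fp)
    assert accuracy(swapped) == pytest.approx(expected)


def test_accuracy_undefined_for_no_subjects():
    with pytest.raises(ValueError):
        accuracy(ConfusionCounts(0, 0, 0, 0))


def test_c_statistic_extremes():
    assert c_statistic([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert c_statistic([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    scores = (0.1, 0.4, 0.35, 0.8)
    labels = (0, 0, 1, 1)
    assert c_statistic(scores, labels) == pytest.approx(
        brute_force_cstat(scores, labels))
    with pytest.raises(ValueError):
        c_statistic([1, 2, 3], [1, 1, 1])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.data())
def test_c_statistic_matches_all_pairs_enumeration(data):
    n = data.draw(st.integers(4, 50))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    labels = np.zeros(n, dtype=int)
    labels[: data.draw(st.integers(1, n - 1))] = 1
    rng.shuffle(labels)
    assert c_statistic(scores, labels) == pytest.approx(
        brute_force_cstat(scores, labels))


def _separable_dataset(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) * 0.3 + np.where(y[:, None] == 1, 2.0, -2.0)
    return make_continuous_dataset(X, y)


def test_cv_accuracy_on_linearly_separable_data_is_one():
    ds = _separable_dataset()
    acc = cv_accuracy(ds, ["v01", "v02"], TuningConfig("linear", 1.0),
                      EvalProtocol(n_folds=5, seed=0))
    assert acc == 1.0


def test_cv_accuracy_majority_floor_with_uninformative_features():
    rng = np.random.default_rng(1)
    y = (rng.random(300) < 0.1).astype(int)
    X = rng.normal(size=(300, 3))
    ds = make_continuous_dataset(X, y)
    acc = cv_accuracy(ds, ["v01", "v02", "v03"], TuningConfig("rbf", 10, 1.0),
                      EvalProtocol(n_folds=5, seed=0))
    assert acc == pytest.approx(1 - y.mean(), abs=0.05)


def test_cv_accuracy_deterministic_and_row_order_invariant():
    ds = xor_dataset(n=200, seed=2)
    prot = EvalProtocol(n_folds=5, seed=4)
    tuning = TuningConfig("rbf", 10, 1.0)
    a = cv_accuracy(ds, ["xa", "xb"], tuning, prot)
    b = cv_accuracy(ds, ["xa", "xb"], tuning, prot)
    assert a == b
    shuffled = Dataset(ds.frame.sample(frac=1, random_state=9).reset_index(drop=True),
                       list(ds.variables))
    c = cv_accuracy(shuffled, ["xa", "xb"], tuning, prot)
    assert c == a


def test_tune_prefers_rbf_on_xor_interaction():
    ds = xor_dataset(n=300, seed=3)
    grid = [TuningConfig("linear", 0.1), TuningConfig("rbf", 10.0, 1.0)]
    best = tune(ds, ["xa", "xb"], grid, EvalProtocol(n_folds=5, seed=0))
    assert best.kernel == "rbf"


def test_tune_singleton_and_tie_break():
    ds = _separable_dataset(seed=5)
    prot = EvalProtocol(n_folds=4, seed=1)
    only = TuningConfig("linear", 0.5)
    assert tune(ds, ["v01", "v02"], [only], prot) == only
    # two grid points with identical CV error: the earlier one wins
    dup = [TuningConfig("linear", 1.0), TuningConfig("linear", 1.0 + 1e-12)]
    assert tune(ds, ["v01", "v02"], dup, prot) == dup[0]
    with pytest.raises(ValueError):
        tune(ds, ["v01"], [], prot)


def test_split_train_test_partition_and_determinism(small_hierarchy):
    prot = EvalProtocol(test_fraction=0.2, seed=8)
    train, test = split_train_test(small_hierarchy, prot)
    n = small_hierarchy.n
    assert test.n == int(np.ceil(0.2 * n))
    assert train.n + test.n == n
    ids = set(train.frame["ID"]) | set(test.frame["ID"])
    assert len(ids) == n
    assert not set(train.frame["ID"]) & set(test.frame["ID"])
    train2, test2 = split_train_test(small_hierarchy, prot)
    assert list(train2.frame["ID"]) == list(train.frame["ID"])
    # stratification keeps prevalence aligned between the parts
    p_all = small_hierarchy.frame["remission"].mean()
    assert abs(test.frame["remission"].mean() - p_all) < 0.05


def test_split_rejects_tiny_datasets():
    ds = make_continuous_dataset(np.zeros((3, 2)), [0, 1, 0])
    with pytest.raises(ValueError):
        split_train_test(ds, EvalProtocol(test_fraction=0.2, seed=0))


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        TuningConfig("poly", 1.0)
    with pytest.raises(ValueError):
        TuningConfig("rbf", -1.0)
    with pytest.raises(ValueError):
        TuningConfig("rbf", 1.0, gamma=0.0)
    with pytest.raises(ValueError):
        EvalProtocol(test_fraction=1.2)
    with pytest.raises(ValueError):
        EvalProtocol(n_folds=1)
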