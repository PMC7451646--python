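import itertools

import numpy as np
import pytest

from helpers import (
    make_continuous_dataset,
    planted_margin_dataset,
    staircase_dataset,
    xor_dataset,
)
from stepsvm.datagen import Dataset
from stepsvm.evaluation import CVEvaluator, EvalProtocol, TuningConfig, cv_accuracy
from stepsvm.selection import (
    StepSVMConfig,
    count_stage_candidates,
    count_total_models,
    forward_step,
    select_best_pair,
    stepsvm,
)

RBF = TuningConfig("rbf", 10.0, 1.0)


@pytest.mark.parametrize("m, stage, expected", [
    (26, 1, 325), (26, 2, 24), (26, 3, 23), (26, 4, 22), (3, 1, 3), (10, 2, 8),
])
def test_count_stage_candidates(m, stage, expected):
    assert count_stage_candidates(m, stage) == expected


def test_count_stage_candidates_domain_errors():
    with pytest.raises(ValueError):
        count_stage_candidates(1, 1)
    with pytest.raises(ValueError):
        count_stage_candidates(5, 5)


@pytest.mark.parametrize("m, method, expected", [
    (26, "svm_rfe", 26),
    (26, "stepwise_logistic", 351),
    (26, "stepsvm", 625),
    (2, "stepsvm", 1),
])
def test_count_total_models(m, method, expected):
    assert count_total_models(m, method) == expected


def test_count_total_models_unknown_method():
    with pytest.raises(ValueError):
        count_total_models(5, "ridge")


def test_select_best_pair_finds_planted_xor_pair():
    ds = xor_dataset(n=300, n_noise=4, seed=6)
    cfg = StepSVMConfig(tuning=RBF, protocol=EvalProtocol(n_folds=5, seed=0))
    pair, value = select_best_pair(ds, cfg)
    assert set(pair) == {"xa", "xb"}
    # the chosen pair's CV accuracy dominates every other pair (brute force)
    for other in itertools.combinations(ds.predictor_names, 2):
        if set(other) == set(pair):
            continue
        assert cv_accuracy(ds, list(other), RBF, cfg.protocol) <= value


def test_select_best_pair_m2_and_tie_break_determinism():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    y = (x + rng.normal(0, 0.5, 200) > 0).astype(int)
    X = np.column_stack([x, x, rng.normal(size=200)])  # duplicated signal
    ds = make_continuous_dataset(X, y, ["a", "b", "c"])
    cfg = StepSVMConfig(tuning=TuningConfig("linear", 1.0),
                        protocol=EvalProtocol(n_folds=4, seed=1))
    p1, _ = select_best_pair(ds, cfg)
    p2, _ = select_best_pair(ds, cfg)
    assert p1 == p2  # duplicated columns tie; canonical order decides

    two = make_continuous_dataset(X[:, :2], y, ["a", "b"])
    pair, _ = select_best_pair(two, cfg)
    assert pair == ("a", "b")
    with pytest.raises(ValueError):
        select_best_pair(make_continuous_dataset(X[:, :1], y, ["a"]), cfg)


def test_forward_step_adds_planted_third_variable():
    ds = planted_margin_dataset(n=600, n_noise=5, seed=4)
    cfg = StepSVMConfig(tuning=RBF, protocol=EvalProtocol(n_folds=3, seed=0))
    evaluator = CVEvaluator(ds, cfg.protocol)
    base = evaluator.accuracy_of(["sig1", "sig2"], RBF)
    var, value = forward_step(ds, ["sig1", "sig2"], cfg, current_value=base,
                              evaluator=evaluator)
    assert var == "sig3"
    assert value > base


def test_forward_step_stops_without_strict_improvement():
    ds = planted_margin_dataset(n=600, n_noise=5, seed=4)
    cfg = StepSVMConfig(tuning=RBF, protocol=EvalProtocol(n_folds=3, seed=0))
    var, value = forward_step(ds, ["sig1", "sig2", "sig3"], cfg,
                              current_value=1.1)  # nothing can beat this
    assert var is None


def test_forward_step_exhausted_and_validation():
    ds = xor_dataset(n=120, seed=1)
    cfg = StepSVMConfig(tuning=RBF, protocol=EvalProtocol(n_folds=3, seed=0))
    with pytest.raises(LookupError):
        forward_step(ds, ["xa", "xb"], cfg)
    with pytest.raises(ValueError):
        forward_step(ds, [], cfg)


def test_stepsvm_cap_at_initial_pair():
    ds = xor_dataset(n=200, n_noise=2, seed=7)
    cfg = StepSVMConfig(max_size=2, tuning=RBF,
                        protocol=EvalProtocol(n_folds=4, seed=2))
    path = stepsvm(ds, cfg)
    assert len(path.selected) == 2
    assert path.stopped_reason == "max_size"
    assert len(path.steps) == 1


def test_stepsvm_path_invariants_and_determinism():
    ds = staircase_dataset(n=300, m=8, seed=3)
    cfg = StepSVMConfig(max_size=5, tuning=TuningConfig("linear", 1.0),
                        protocol=EvalProtocol(n_folds=3, seed=5))
    path = stepsvm(ds, cfg)
    assert len(path.selected) <= 5
    values = [v for _, v in path.steps]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert len(path.steps[0][0]) == 2
    assert all(len(added) == 1 for added, _ in path.steps[1:])
    again = stepsvm(ds, cfg)
    assert again.steps == path.steps

    # evaluation count decomposes into the per-stage candidate counts
    m, n_sel = 8, len(path.selected)
    expected = count_stage_candidates(m, 1)
    expected += sum(count_stage_candidates(m, s) for s in range(2, n_sel))
    if path.stopped_reason in ("no_improvement",):
        expected += count_stage_candidates(m, n_sel)  # the refused stage
    assert path.n_evaluations == expected


def test_select_best_pair_matches_exhaustive_oracle():
    """On small m the selected pair must equal the argmax over an
    independent enumeration of all pairs via cv_accuracy."""
    for seed in (0, 1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(150, 6))
        y = (X[:, 0] - X[:, 3] + rng.normal(0, 1.0, 150) > 0).astype(int)
        ds = make_continuous_dataset(X, y)
        prot = EvalProtocol(n_folds=3, seed=seed)
        cfg = StepSVMConfig(tuning=TuningConfig("linear", 1.0), protocol=prot)
        pair, value = select_best_pair(ds, cfg)
        best_val, best_pair = -1.0, None
        for cand in itertools.combinations(ds.predictor_names, 2):
            v = cv_accuracy(ds, list(cand), cfg.tuning, prot)
            if v > best_val:
                best_val, best_pair = v, cand
        assert pair == best_pair
        assert value == pytest.approx(best_val)


def test_variable_order_permutation_only_affects_tie_breaks():
    ds = planted_margin_dataset(n=500, n_noise=4, seed=9)
    cfg = StepSVMConfig(max_size=4, tuning=RBF,
                        protocol=EvalProtocol(n_folds=3, seed=0))
    path = stepsvm(ds, cfg)
    perm = list(reversed(ds.variables))
    permuted = Dataset(ds.frame, perm)
    path_p = stepsvm(permuted, cfg)
    assert set(path_p.selected) == set(path.selected)
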