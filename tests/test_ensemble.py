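import itertools

import numpy as np
import pytest

from ahtpscreen.ensemble import (BaseModelSpec, ConfusionCounts, PipelineConfig,
                                 WeightSet, cross_validate,
                                 ensemble_probability, evaluate_metrics,
                                 optimize_weights, roc_auc, train_base_models,
                                 train_ensemble, _weight_grid)


# ---------------------------------------------------------------------------
# metric algebra
# ---------------------------------------------------------------------------

def brute_metrics(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else None
    sp = tn / (tn + fp) if tn + fp else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / denom ** 0.5 if denom else 0.0
    return acc, sn, sp, mcc


@pytest.mark.parametrize("tp,tn,fp,fn", [
    (50, 50, 0, 0),     # perfect classifier
    (50, 0, 50, 0),     # everything called positive
    (8, 7, 3, 2),       # ACC 0.75, Sn 0.8, Sp 0.7, MCC ~ 0.5025
    (0, 10, 0, 10),     # everything called negative
    (3, 9, 4, 1), (1, 1, 1, 1), (10, 0, 0, 5),
])
def test_metrics_match_brute_force(tp, tn, fp, fn):
    got = evaluate_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
    acc, sn, sp, mcc = brute_metrics(tp, tn, fp, fn)
    assert got["ACC"] == pytest.approx(acc, abs=1e-12)
    assert (got["Sn"] is None) == (sn is None)
    if sn is not None:
        assert got["Sn"] == pytest.approx(sn, abs=1e-12)
    if sp is not None:
        assert got["Sp"] == pytest.approx(sp, abs=1e-12)
    assert got["MCC"] == pytest.approx(mcc, abs=1e-12)


def test_worked_confusion_example():
    m = evaluate_metrics(ConfusionCounts(TP=8, FN=2, TN=7, FP=3))
    assert m["ACC"] == 0.75
    assert m["Sn"] == pytest.approx(0.8)
    assert m["Sp"] == pytest.approx(0.7)
    assert m["MCC"] == pytest.approx(50 / np.sqrt(11 * 10 * 10 * 9))


def test_degenerate_predictor_metrics():
    m = evaluate_metrics(ConfusionCounts(TP=50, FP=50, TN=0, FN=0))
    assert (m["Sn"], m["Sp"], m["MCC"]) == (1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        evaluate_metrics(ConfusionCounts())


def test_mcc_symmetries():
    rng = np.random.default_rng(0)
    for _ in range(30):
        tp, tn, fp, fn = rng.integers(0, 40, 4)
        if tp + tn + fp + fn == 0:
            continue
        m = evaluate_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        assert -1.0 - 1e-12 <= m["MCC"] <= 1.0 + 1e-12
        swapped = evaluate_metrics(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
        assert swapped["MCC"] == pytest.approx(m["MCC"], abs=1e-12)
        flipped = evaluate_metrics(ConfusionCounts(TP=fn, TN=fp, FP=tn, FN=tp))
        assert flipped["MCC"] == pytest.approx(-m["MCC"], abs=1e-12)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

from oracles import mann_whitney_auc


def test_auc_perfect_and_random():
    y = np.array([0, 1] * 20)
    auc, fpr, tpr = roc_auc(y.astype(float), y)
    assert auc == 1.0
    rng = np.random.default_rng(123)
    y = (rng.random(1000) < 0.5).astype(int)
    scores = rng.random(1000)
    auc, _, _ = roc_auc(scores, y)
    assert auc == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError, match="both classes"):
        roc_auc(scores[:5], np.ones(5))


def test_auc_equals_rank_statistic_oracle():
    rng = np.random.default_rng(7)
    y = np.array([1] * 15 + [0] * 15)
    scores = np.round(rng.random(30), 1)  # rounding forces ties
    auc, _, _ = roc_auc(scores, y)
    assert auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-12)


# ---------------------------------------------------------------------------
# weighted voting algebra
# ---------------------------------------------------------------------------

def test_weightset_invariants():
    ws = WeightSet((0.2, 0.4, 0.2, 0.4, 0.2, 0.4))
    assert max(ws.w) == 1.0
    with pytest.raises(ValueError):
        WeightSet((0, 0, 0, 0, 0, 0))
    with pytest.raises(ValueError):
        WeightSet((1, 1, 1, 1, 1, -0.1))


@pytest.mark.parametrize("model_idx", [0, 1, 2])
def test_degenerate_weights_reduce_to_single_model(model_idx):
    rng = np.random.default_rng(1)
    P = rng.random((50, 3))
    w = [0.0] * 6
    w[2 * model_idx] = w[2 * model_idx + 1] = 1.0
    prob = ensemble_probability(P, WeightSet(tuple(w)))
    np.testing.assert_allclose(prob, P[:, model_idx], atol=1e-12)


def test_equal_weights_average_probabilities():
    rng = np.random.default_rng(2)
    P = rng.random((50, 3))
    prob = ensemble_probability(P, WeightSet((1,) * 6))
    np.testing.assert_allclose(prob, P.mean(1), atol=1e-12)


def test_probability_bounds_and_monotonicity():
    rng = np.random.default_rng(3)
    ws = WeightSet(tuple(rng.random(6) + 0.05))
    P = rng.random((200, 3))
    prob = ensemble_probability(P, ws)
    assert np.all((prob >= 0) & (prob <= 1))
    for j in range(3):
        P2 = P.copy()
        P2[:, j] = np.minimum(1.0, P2[:, j] + 0.05)
        prob2 = ensemble_probability(P2, ws)
        assert np.all(prob2 >= prob - 1e-12)


# ---------------------------------------------------------------------------
# weight optimisation
# ---------------------------------------------------------------------------

def test_weight_grid_prunes_by_normalisation():
    grid = _weight_grid(0.5)
    assert np.allclose(grid.max(1), 1.0)
    assert len(grid) == 3 ** 6 - 2 ** 6


def test_optimize_weights_single_candidate_and_determinism():
    rng = np.random.default_rng(4)
    P = rng.random((60, 3))
    y = (rng.random(60) < 0.5).astype(int)
    cand = np.array([[1.0, 0.5, 0.2, 0.1, 0.3, 0.4]])
    assert optimize_weights(P, y, grid=cand).w == WeightSet(tuple(cand[0])).w
    a = optimize_weights(P, y, seed=2, grid=_weight_grid(0.25))
    b = optimize_weights(P, y, seed=2, grid=_weight_grid(0.25))
    assert a.w == b.w
    with pytest.raises(ValueError, match="empty"):
        optimize_weights(P, y, grid=np.empty((0, 6)))


def test_optimizer_prefers_the_perfect_model():
    rng = np.random.default_rng(5)
    n = 200
    y = (rng.random(n) < 0.5).astype(int)
    P = np.column_stack([
        np.clip(y + rng.normal(0, 0.05, n), 0, 1),  # RF nearly perfect
        rng.random(n),                              # XGB coin flip
        rng.random(n),                              # SVM coin flip
    ])
    ws = optimize_weights(P, y, grid=_weight_grid(0.25), seed=0)
    assert max(ws.w[0], ws.w[1]) == 1.0
    prob = ensemble_probability(P, ws)
    ens_acc = ((prob >= 0.5) == (y == 1)).mean()
    rf_acc = ((P[:, 0] >= 0.5) == (y == 1)).mean()
    assert ens_acc >= rf_acc - 1e-12


# ---------------------------------------------------------------------------
# base models and cross-validation
# ---------------------------------------------------------------------------

def _separable(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.standard_normal((n, 2)) + (2 * y - 1)[:, None] * 2.0
    return X, y


def test_base_models_learn_separable_data():
    X, y = _separable()
    models, subsets = train_base_models(X, y, seed=0)
    for kind, model in models.items():
        acc = (model.predict(X[:, subsets[kind]]) == y).mean()
        assert acc >= 0.95, kind


def test_base_models_deterministic():
    X, y = _separable(seed=1)
    probe = np.random.default_rng(2).standard_normal((20, 2))
    m1, s1 = train_base_models(X, y, seed=3)
    m2, s2 = train_base_models(X, y, seed=3)
    for kind in m1:
        p1 = m1[kind].predict_proba(probe)
        p2 = m2[kind].predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)


def test_base_models_guards():
    X, y = _separable()
    with pytest.raises(ValueError, match="both classes"):
        train_base_models(X, np.zeros_like(y))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        train_base_models(X, y)


def test_shuffled_labels_give_chance_accuracy():
    rng = np.random.default_rng(11)
    X, y = _separable(n=200, seed=11)
    y_shuf = rng.permutation(y)
    Xtr, Xte = X[:140], X[140:]
    ytr, yte = y_shuf[:140], y_shuf[140:]
    models, subsets = train_base_models(Xtr, ytr, seed=0)
    for kind, model in models.items():
        acc = (model.predict(Xte[:, subsets[kind]]) == yte).mean()
        assert 0.3 <= acc <= 0.7, kind


FAST_CFG = PipelineConfig(relieff_n_samples=80, rfe_step=4,
                          weight_resolution=0.25)


def test_cross_validate_pipeline_on_separable_data():
    X, y = _separable(n=150, seed=6)
    X = np.hstack([X, np.random.default_rng(8).standard_normal((150, 6))])
    res = cross_validate(X, y, config=FAST_CFG, folds=5, seed=0)
    c = res["pooled_counts"]
    assert c.TP + c.TN + c.FP + c.FN == 150
    assert res["pooled"]["ACC"] >= 0.9
    assert res["AUC"] >= 0.9
    assert len(res["per_fold"]) == 5


def test_cross_validate_fold_assignment_reproducible():
    X, y = _separable(n=120, seed=9)
    r1 = cross_validate(X, y, config=FAST_CFG, folds=4, seed=5)
    r2 = cross_validate(X, y, config=FAST_CFG, folds=4, seed=5)
    assert r1["pooled"] == r2["pooled"]


def test_ensemble_save_load_roundtrip(tmp_path):
    X, y = _separable(n=120, seed=10)
    model = train_ensemble(X, y, config=FAST_CFG, schema_hash="abc", seed=0)
    res1 = model.predict_matrix(X[:10])
    model.save(tmp_path / "bundle")
    from ahtpscreen.ensemble import EnsembleModel
    back = EnsembleModel.load(tmp_path / "bundle")
    assert back.weights.w == model.weights.w
    res2 = back.predict_matrix(X[:10])
    np.testing.assert_array_equal(res1["P_ensemble"], res2["P_ensemble"])


def test_predict_vector_refuses_schema_mismatch(tmp_path):
    X, y = _separable(n=120, seed=12)
    model = train_ensemble(X, y, config=FAST_CFG, schema_hash="good", seed=0)

    class FakeVec:
        values = X[0]

        class schema:
            hash = "bad"

    with pytest.raises(ValueError, match="schema hash"):
        model.predict_vector(FakeVec())
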