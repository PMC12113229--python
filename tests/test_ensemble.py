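"""Ensemble SDM machinery: metric oracles, AUC-weighted averaging,
holdout splits, learners on separable data, and map/contribution outputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecoreserve as er
from ecoreserve.ensemble import (confusion_metrics, ensemble_weights,
                                 evaluate, fit_base_model, max_tss_threshold,
                                 model_layer_names, response_curve,
                                 split_sample, variable_contribution)


# ------------------------------------------------------------- metric oracles

def test_confusion_metric_hand_oracle():
    # tp=8 fn=2 tn=7 fp=3: sens=0.8, spec=0.7
    m = confusion_metrics(tp=8, fn=2, tn=7, fp=3)
    assert m["tss"] == pytest.approx(0.5, abs=1e-12)
    assert m["omission_rate"] == pytest.approx(0.2, abs=1e-12)
    assert m["prop_correct"] == pytest.approx(0.75, abs=1e-12)
    # kappa oracle: po=0.75, pe=(11/20)(10/20)+(9/20)(10/20)=0.5
    assert m["kappa"] == pytest.approx(0.5, abs=1e-12)


def test_confusion_requires_both_classes():
    with pytest.raises(ValueError):
        confusion_metrics(tp=5, fn=0, tn=0, fp=0)


def test_perfect_and_random_classifier_extremes():
    perfect = confusion_metrics(tp=10, fn=0, tn=10, fp=0)
    assert perfect["tss"] == 1.0 and perfect["kappa"] == 1.0
    chance = confusion_metrics(tp=5, fn=5, tn=5, fp=5)
    assert chance["tss"] == 0.0 and chance["kappa"] == 0.0


def test_rank_auc_matches_all_pairs_count():
    """AUC on a small set equals the fraction of presence/absence pairs
    ranked correctly (ties count half) — brute-force all-pairs oracle."""
    rng = np.random.default_rng(3)
    scores = np.round(rng.random(24), 1)  # rounding forces some ties
    labels = rng.integers(0, 2, 24)
    labels[:2] = [0, 1]  # both classes present
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    oracle = wins / (len(pos) * len(neg))
    m = evaluate(scores, labels)
    assert m.auc == pytest.approx(oracle, abs=1e-12)


def test_max_tss_threshold_on_separable_scores():
    scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
    labels = np.array([0, 0, 0, 1, 1, 1])
    t = max_tss_threshold(scores, labels)
    assert 0.3 < t < 0.8
    m = evaluate(scores, labels)
    assert m.tss == 1.0 and m.omission_rate == 0.0 and m.prop_correct == 1.0


def test_evaluate_rejects_single_class():
    with pytest.raises(ValueError):
        evaluate(np.array([0.2, 0.4]), np.array([1, 1]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_max_tss_threshold_is_optimal(seed):
    rng = np.random.default_rng(seed)
    n = 30
    scores = rng.random(n)
    labels = rng.integers(0, 2, n)
    labels[:2] = [0, 1]
    t = max_tss_threshold(scores, labels)

    def tss_at(th):
        pred = scores > th
        pos = labels == 1
        return (pred & pos).sum() / pos.sum() \
            + ((~pred) & (~pos)).sum() / (~pos).sum() - 1.0

    best = max(tss_at(th) for th in np.concatenate([scores - 1e-9, scores]))
    assert tss_at(t) == pytest.approx(best, abs=1e-9)


# ------------------------------------------------------- AUC-share weighting

def test_weights_are_auc_shares_of_passing_models():
    w = ensemble_weights([0.9, 0.85, 0.75], auc_gate=0.8)
    total = 0.9 + 0.85
    np.testing.assert_allclose(w, [0.9 / total, 0.85 / total, 0.0],
                               atol=1e-15)
    assert w.sum() == pytest.approx(1.0, abs=1e-15)


def test_gate_is_strict():
    w = ensemble_weights([0.8, 0.9], auc_gate=0.8)
    assert w[0] == 0.0 and w[1] == 1.0


def test_all_models_failing_gate_errors():
    with pytest.raises(ValueError, match="no base model exceeds"):
        ensemble_weights([0.6, 0.7, 0.79], auc_gate=0.8)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(aucs=st.lists(st.floats(0.5, 1.0), min_size=1, max_size=6))
def test_weights_sum_to_one_and_preserve_order(aucs):
    if max(aucs) <= 0.8:
        with pytest.raises(ValueError):
            ensemble_weights(aucs)
        return
    w = ensemble_weights(aucs)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(w >= 0)
    passing = [(a, wi) for a, wi in zip(aucs, w) if a > 0.8]
    order_a = np.argsort([a for a, _ in passing], kind="stable")
    order_w = np.argsort([wi for _, wi in passing], kind="stable")
    assert list(order_a) == list(order_w)


# -------------------------------------------------------------------- splits

def test_split_preserves_class_fractions():
    labels = np.array([1] * 40 + [0] * 60)
    splits = split_sample(labels, train_fraction=0.8, n_rounds=10, seed=1)
    assert len(splits) == 10
    for tr, te in splits:
        assert len(tr) == 80 and len(te) == 20
        assert labels[tr].sum() == 32  # 80% of 40 presences
        assert labels[te].sum() == 8
        assert not set(tr) & set(te)


def test_split_requires_minimum_class_counts():
    with pytest.raises(ValueError, match="at least 5"):
        split_sample(np.array([1] * 3 + [0] * 50))


# ------------------------------------------------------------- base learners

@pytest.mark.parametrize("kind", ["maxent_like", "random_forest", "svm"])
def test_each_learner_separates_a_clean_gradient(kind):
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 3))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    fit = fit_base_model(kind, X[:160], y[:160], seed=0)
    p = fit.predict_prob(X[160:])
    assert p.min() >= 0.0 and p.max() <= 1.0
    assert evaluate(p, y[160:]).auc > 0.9


def test_unknown_learner_rejected():
    with pytest.raises(ValueError):
        fit_base_model("neural_net", np.zeros((10, 2)),
                       np.array([0, 1] * 5))


# --------------------------------------------------------------- full fits

def test_model_layers_exclude_raw_masks_and_circular(small_stack):
    cont, cat = model_layer_names(small_stack)
    assert "road_mask" not in cont and "water_mask" not in cont
    assert "aspect" not in cont  # replaced by eastness/southness
    assert {"eastness", "southness"} <= set(cont)
    assert cat == ["landuse"]


def test_fit_is_deterministic_under_seed(small_stack, occurrences):
    reduced, _ = er.collinearity_filter(small_stack, occurrences.records)
    cfg = er.EnsembleConfig(n_rounds=2, seed=9)
    a = er.fit_ensemble(reduced, occurrences, cfg)
    b = er.fit_ensemble(reduced, occurrences, cfg)
    ma = er.predict_ensemble(a, reduced).values
    mb = er.predict_ensemble(b, reduced).values
    np.testing.assert_array_equal(ma[reduced.mask], mb[reduced.mask])
    assert a.mean_metrics().as_dict() == b.mean_metrics().as_dict()


def test_round_weights_are_auc_shares_of_round_aucs(fitted_ensemble):
    _, fit = fitted_ensemble
    for rnd in fit.rounds:
        aucs = [rnd.model_metrics[k].auc for k in fit.config.learners]
        expected = ensemble_weights(aucs, fit.config.auc_gate)
        got = np.array([rnd.weights[k] for k in fit.config.learners])
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_suitability_map_in_unit_interval_and_masked(fitted_ensemble):
    stack, fit = fitted_ensemble
    m = er.predict_ensemble(fit, stack)
    vals = m.values[stack.mask]
    assert np.all((vals >= 0) & (vals <= 1))
    assert np.isnan(m.values[~stack.mask]).all() or (~stack.mask).sum() == 0


def test_suitability_correlates_with_true_probability(fitted_ensemble, niche):
    from scipy.stats import spearmanr
    stack, fit = fitted_ensemble
    m = er.predict_ensemble(fit, stack)
    truth = niche.probability(stack)
    rho = spearmanr(m.values[stack.mask], truth[stack.mask]).statistic
    assert rho > 0.5


def test_contributions_sum_to_100_and_signal_beats_noise(fitted_ensemble):
    stack, fit = fitted_ensemble
    contrib = variable_contribution(fit, stack, n_permutations=3, seed=0)
    assert contrib.sum() == pytest.approx(100.0, abs=1e-9)
    assert (contrib >= 0).all()
    # aspect reported once, not as its components
    assert "eastness" not in contrib.index
    # dem is a strong true driver in the default niche
    assert contrib["dem"] > 100.0 / len(contrib)


def test_response_curve_shape_and_reference_holding(fitted_ensemble):
    stack, fit = fitted_ensemble
    rc = response_curve(fit, stack, "evi", n_points=50)
    assert list(rc.columns) == ["value", "value_norm", "probability"]
    assert len(rc) == 50
    assert rc.value_norm.iloc[0] == 0.0 and rc.value_norm.iloc[-1] == 1.0
    assert rc.probability.between(0, 1).all()
    with pytest.raises(KeyError):
        response_curve(fit, stack, "landuse")


def test_predict_on_stack_missing_covariate_errors(fitted_ensemble):
    stack, fit = fitted_ensemble
    partial = stack.subset([n for n in stack.names if n != "evi"])
    with pytest.raises(KeyError, match="missing fitted covariates"):
        er.predict_ensemble(fit, partial)
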