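"""Forward predictors: worked examples, limits, and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autrel import MODEL_NAMES, delta_closed_form, predict
from autrel.models import (
    LatentPrediction,
    predict_iiab,
    predict_no_update,
    _iiab_forward,
)

bits_strategy = st.lists(st.integers(0, 1), min_size=0, max_size=60)
unit = st.floats(0.0, 1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# LatentPrediction container
# ---------------------------------------------------------------------------

def test_latent_prediction_validates_weights_and_means():
    with pytest.raises(ValueError, match="sum to 1"):
        LatentPrediction([np.array([0.2, 0.8])], [np.array([0.5, 0.4])])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        LatentPrediction(np.array([1.5]))


def test_latent_prediction_mixture_mean():
    pred = LatentPrediction([np.array([0.0, 1.0])], [np.array([0.25, 0.75])])
    assert pred.mixture_mean() == pytest.approx([0.75])
    assert not pred.is_point


# ---------------------------------------------------------------------------
# Bayesian
# ---------------------------------------------------------------------------

def test_bayesian_posterior_means():
    pred = predict("bayesian", [1, 0], {"p": 1, "q": 1})
    assert pred.point_means() == pytest.approx([2 / 3, 1 / 2])


def test_bayesian_empty_sequence():
    assert len(predict("bayesian", [], {"p": 1, "q": 1})) == 0


def test_bayesian_requires_positive_prior():
    with pytest.raises(ValueError, match="positive"):
        predict("bayesian", [1], {"p": 0.0, "q": 1.0})


@given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=40), data=st.data())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bayesian_final_mean_is_permutation_invariant(bits, data):
    perm = data.draw(st.permutations(bits))
    params = {"p": 2.0, "q": 1.5}
    a = predict("bayesian", bits, params).point_means()[-1]
    b = predict("bayesian", perm, params).point_means()[-1]
    assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# Delta rule and closed form
# ---------------------------------------------------------------------------

def test_delta_single_update():
    pred = predict("delta", [1], {"r0": 0.5, "alpha": 0.2})
    assert pred.point_means() == pytest.approx([0.6])


@pytest.mark.parametrize(
    "alpha,expected",
    [(0.0, [0.5, 0.5, 0.5]), (1.0, [1.0, 0.0, 1.0])],
)
def test_delta_learning_rate_limits(alpha, expected):
    pred = predict("delta", [1, 0, 1], {"r0": 0.5, "alpha": alpha})
    assert pred.point_means() == pytest.approx(expected)


def test_delta_closed_form_base_case():
    assert delta_closed_form([1, 0], {"r0": 0.3, "alpha": 0.4}, 0) == pytest.approx(0.3)


def test_delta_closed_form_weights_telescope():
    alpha, t = 0.37, 12
    weights = alpha * (1 - alpha) ** np.arange(t)
    assert weights.sum() + (1 - alpha) ** t == pytest.approx(1.0)


@given(bits=bits_strategy, r0=unit, alpha=unit)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_delta_iterative_equals_closed_form(bits, r0, alpha):
    params = {"r0": r0, "alpha": alpha}
    iterative = predict("delta", bits, params).point_means()
    for t in range(1, len(bits) + 1):
        assert abs(iterative[t - 1] - delta_closed_form(bits, params, t)) < 1e-12


def test_delta_is_recency_sensitive():
    params = {"r0": 0.5, "alpha": 0.3}
    up = predict("delta", [0, 0, 1, 1], params).point_means()[-1]
    down = predict("delta", [1, 1, 0, 0], params).point_means()[-1]
    assert up > down  # same outcome counts, different orders


# ---------------------------------------------------------------------------
# Two-kernel delta rule
# ---------------------------------------------------------------------------

def test_two_kernel_hand_iteration():
    pred = predict(
        "two_kernel", [1, 1],
        {"r0": 0.5, "alpha_slow": 0.1, "alpha_fast": 0.5, "threshold": 0.15},
    )
    assert pred.point_means() == pytest.approx([0.75, 0.875])


@given(bits=bits_strategy, r0=unit, a_slow=unit, a_fast=unit)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_two_kernel_threshold_one_reduces_to_slow_delta(bits, r0, a_slow, a_fast):
    two = predict(
        "two_kernel",
        bits,
        {"r0": r0, "alpha_slow": a_slow, "alpha_fast": a_fast, "threshold": 1.0},
    )
    one = predict("delta", bits, {"r0": r0, "alpha": a_slow})
    np.testing.assert_array_equal(two.point_means(), one.point_means())


@given(bits=bits_strategy, r0=unit, alpha=unit, threshold=unit)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_two_kernel_equal_rates_reduce_to_delta(bits, r0, alpha, threshold):
    two = predict(
        "two_kernel",
        bits,
        {"r0": r0, "alpha_slow": alpha, "alpha_fast": alpha, "threshold": threshold},
    )
    one = predict("delta", bits, {"r0": r0, "alpha": alpha})
    np.testing.assert_array_equal(two.point_means(), one.point_means())


def test_two_kernel_zero_threshold_tracks_fast_when_kernels_differ():
    bits = [1, 1, 1, 0, 0]
    params = {"r0": 0.5, "alpha_slow": 0.05, "alpha_fast": 0.6, "threshold": 0.0}
    two = predict("two_kernel", bits, params).point_means()
    fast = predict("delta", bits, {"r0": 0.5, "alpha": 0.6}).point_means()
    slow = predict("delta", bits, {"r0": 0.5, "alpha": 0.05}).point_means()
    differs = fast != slow
    np.testing.assert_array_equal(two[differs], fast[differs])


# ---------------------------------------------------------------------------
# Memory sampling models
# ---------------------------------------------------------------------------

def test_recency_sampling_components():
    pred = predict("sampling_recency", [1, 0], {"r0": 0.3, "alpha_sampling": 0.5})
    comp = dict(zip(pred.means[1], pred.weights[1]))
    assert comp[0.0] == pytest.approx(0.5)
    assert comp[1.0] == pytest.approx(0.25)
    assert comp[0.3] == pytest.approx(0.25)


def test_recency_sampling_degenerates_to_last_outcome():
    pred = predict("sampling_recency", [1, 0, 1], {"r0": 0.5, "alpha_sampling": 1.0})
    assert pred.mixture_mean() == pytest.approx([1.0, 0.0, 1.0])


@given(bits=bits_strategy, r0=unit, alpha=unit)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_recency_sampling_mean_equals_delta(bits, r0, alpha):
    mix = predict("sampling_recency", bits, {"r0": r0, "alpha_sampling": alpha})
    delta = predict("delta", bits, {"r0": r0, "alpha": alpha})
    np.testing.assert_allclose(mix.mixture_mean(), delta.point_means(), atol=1e-12)


def test_last_average_sampling_running_average():
    pred = predict(
        "sampling_last_average", [1, 1, 0],
        {"r0": 0.5, "weight_r0": 1.0, "prob_last": 0.4},
    )
    # A_3 = (1*0.5 + 2) / (1 + 3)
    assert pred.means[2][1] == pytest.approx(0.625)
    assert pred.weights[2] == pytest.approx([0.4, 0.6])


def test_last_average_sampling_limits():
    last_only = predict(
        "sampling_last_average", [1, 0, 1],
        {"r0": 0.5, "weight_r0": 3.0, "prob_last": 1.0},
    )
    assert last_only.mixture_mean() == pytest.approx([1.0, 0.0, 1.0])
    mean_only = predict(
        "sampling_last_average", [1, 0, 1],
        {"r0": 0.9, "weight_r0": 0.0, "prob_last": 0.0},
    )
    assert mean_only.mixture_mean() == pytest.approx([1.0, 0.5, 2 / 3])


def test_contingent_matching_history_average():
    # history (1,1) previously followed once by 1 and once by 0 -> 0.5
    bits = [1, 1, 1, 1, 0, 1, 1]
    pred = predict("contingent", bits, {"r0": 0.7, "m": 2})
    # at t=7 the current history (1,1) matched at outcomes 3 (ac=1) and 5 (ac=0)
    # plus outcome 4 (ac=1): matches at positions with history (1,1)
    matches = []
    for o in range(2, 7):  # outcomes bits[o] following bits[o-2:o]
        if tuple(bits[o - 2 : o]) == (1, 1):
            matches.append(bits[o])
    assert pred.means[6][0] == pytest.approx(np.mean(matches))


def test_contingent_before_history_uses_r0():
    pred = predict("contingent", [1, 0, 1, 1], {"r0": 0.42, "m": 3})
    assert pred.mixture_mean()[:3] == pytest.approx([0.42] * 3)


def test_contingent_all_correct_predicts_one():
    pred = predict("contingent", [1] * 10, {"r0": 0.2, "m": 2})
    assert pred.mixture_mean()[4:] == pytest.approx([1.0] * 6)


def test_contingent_rejects_bad_history_length():
    with pytest.raises(ValueError, match="m"):
        predict("contingent", [1, 0], {"r0": 0.5, "m": 0})


# ---------------------------------------------------------------------------
# IIAB
# ---------------------------------------------------------------------------

IIAB_PARAMS = {
    "T1": 0.5, "T2": 1.0, "p": 1.0, "q": 1.0,
    "p_changepoint": 1.0, "q_changepoint": 9.0,
}


def test_iiab_infinite_threshold_equals_bayesian():
    bits = np.tile([1, 1, 0, 1], 20)
    params = dict(IIAB_PARAMS, T1=np.inf, p=2.0, q=1.5)
    iiab = predict("iiab", bits, params).point_means()
    bayes = predict("bayesian", bits, {"p": 2.0, "q": 1.5}).point_means()
    np.testing.assert_allclose(iiab, bayes, atol=1e-12)


def test_iiab_empty_sequence():
    assert len(predict("iiab", [], IIAB_PARAMS)) == 0


def test_iiab_detects_abrupt_reliability_drop():
    bits = np.array([1] * 40 + [0] * 40)
    pred, cps = predict_iiab(bits, IIAB_PARAMS, return_trace=True)
    assert pred.point_means()[-1] < 0.2
    assert any(38 <= c <= 44 for c in cps)


def test_iiab_jit_matches_python_reference():
    rng = np.random.default_rng(1)
    bits = rng.integers(0, 2, size=120)
    for seed in range(5):
        r = np.random.default_rng(seed)
        params = {
            "T1": r.uniform(0.1, 5), "T2": r.uniform(0.5, 10),
            "p": r.uniform(0.1, 5), "q": r.uniform(0.1, 5),
            "p_changepoint": r.uniform(0.1, 5), "q_changepoint": r.uniform(0.1, 5),
        }
        pred, cps = predict_iiab(bits, params, return_trace=True)
        est_py, cps_py = _iiab_forward(
            bits, params["T1"], params["T2"], params["p"], params["q"],
            params["p_changepoint"], params["q_changepoint"],
        )
        np.testing.assert_allclose(pred.point_means(), est_py, atol=1e-12)
        assert cps == list(cps_py)


# ---------------------------------------------------------------------------
# No-updating baseline and global invariants
# ---------------------------------------------------------------------------

def test_no_update_is_constant_and_ignores_bits():
    pred = predict_no_update({"r0": 0.7}, 3)
    assert pred.point_means() == pytest.approx([0.7, 0.7, 0.7])
    assert len(predict_no_update({"r0": 0.7}, 0)) == 0
    via_registry = predict("no_update", [1, 0, 1], {"r0": 0.7})
    assert via_registry.point_means() == pytest.approx([0.7, 0.7, 0.7])


EXAMPLE_PARAMS = {
    "bayesian": {"p": 2.0, "q": 1.0},
    "delta": {"r0": 0.5, "alpha": 0.3},
    "two_kernel": {"r0": 0.5, "alpha_slow": 0.03, "alpha_fast": 0.4, "threshold": 0.2},
    "sampling_recency": {"r0": 0.5, "alpha_sampling": 0.4},
    "sampling_last_average": {"r0": 0.5, "weight_r0": 2.0, "prob_last": 0.5},
    "contingent": {"r0": 0.5, "m": 2},
    "iiab": IIAB_PARAMS,
    "no_update": {"r0": 0.5},
}


@pytest.mark.parametrize("model", MODEL_NAMES)
@given(bits=bits_strategy)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_all_latent_means_in_unit_interval(model, bits):
    pred = predict(model, bits, EXAMPLE_PARAMS[model])
    assert len(pred) == len(bits)
    if len(bits):
        assert pred.flat_means.min() >= 0.0
        assert pred.flat_means.max() <= 1.0
        np.testing.assert_allclose(
            np.add.reduceat(pred.flat_weights, pred.offsets), 1.0, atol=1e-10
        )


def test_unknown_model_rejected():
    with pytest.raises(ValueError, match="unknown model"):
        predict("kalman", [1], {})
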