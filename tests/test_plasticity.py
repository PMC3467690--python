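"""STDP rules, learning-rate/bound formulas, normalization, weight init."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synchain.plasticity import (OnlineStdp, STDPParams, WeightSet, compute_learning_rates,
                                 compute_wmax_ff, init_weights, normalize_lateral,
                                 pair_sum_oracle, stdp_window)


def _params(mode, a_p=0.1, bias=1.05, tau_p=20.0, tau_d=20.0):
    return STDPParams(a_p, -a_p * (tau_p / tau_d) * bias, tau_p, tau_d, mode)


# ---------------------------------------------------------------------------
# window and rate formulas

def test_window_branches():
    f = stdp_window([0.0, 20.0, -20.0], 0.1, -0.105)
    assert f[0] == pytest.approx(0.1)                    # tau = 0 potentiates
    assert f[1] == pytest.approx(0.1 * np.exp(-1))
    assert f[2] == pytest.approx(-0.105 * np.exp(-1))


def test_wmax_ff_values_and_scaling():
    # additive reading reproduces (theta/(tau_m <r> dt) + A)/N exactly
    add = compute_wmax_ff(1.0, 10.0, 64.0, 0.1, 20.0, 1000, form="additive")
    assert add == pytest.approx((1 / (10 * 0.064 * 0.1) + 20) / 1000)
    assert add == pytest.approx(0.035625)
    prod = compute_wmax_ff(1.0, 10.0, 64.0, 0.1, 20.0, 1000, form="product")
    assert prod == pytest.approx(0.3125)
    # halving dt doubles the rate-balance term
    add2 = compute_wmax_ff(1.0, 10.0, 64.0, 0.05, 20.0, 1000, form="additive")
    assert add2 * 1000 - 20 == pytest.approx(2 * (add * 1000 - 20))
    # A = 0, N = 1 limit of the additive form
    assert compute_wmax_ff(1.0, 10.0, 64.0, 0.1, 1e-300, 1, form="additive") == \
        pytest.approx(1 / (10 * 0.064 * 0.1), rel=1e-6)


def test_wmax_ff_rejects_bad_args():
    with pytest.raises(ValueError):
        compute_wmax_ff(1.0, 10.0, 0.0, 0.1, 20.0, 1000)


def test_learning_rates_tied_to_bound():
    a_p, a_d = compute_learning_rates(0.035625)
    assert a_p == pytest.approx(7.125e-5)
    assert a_d == pytest.approx(-1.05 * a_p)
    a_p, a_d = compute_learning_rates(1.0)
    assert a_p == pytest.approx(0.002)
    # tau_p != tau_d scales the depression amplitude
    a_p, a_d = compute_learning_rates(1.0, tau_p=10.0, tau_d=20.0)
    assert a_d == pytest.approx(-0.002 * 0.5 * 1.05)


# ---------------------------------------------------------------------------
# pairing schemes: hand-computed cases

def test_oracle_single_pair_each_branch():
    p = _params("nearest_neighbor")
    assert pair_sum_oracle([0.0], [10.0], p) == pytest.approx(p.a_p * np.exp(-0.5))
    # pre 20 ms after the only post -> pure depression
    assert pair_sum_oracle([20.0], [0.0], p) == pytest.approx(p.a_d * np.exp(-1.0))
    assert pair_sum_oracle([0.0, 0.0], [], p) == 0.0
    # coincident pre/post potentiates at full amplitude
    assert pair_sum_oracle([5.0], [5.0], p) == pytest.approx(p.a_p)


def test_all_to_all_sums_over_pairs():
    p = _params("all_to_all")
    got = pair_sum_oracle([0.0, 20.0], [5.0], p)
    want = p.a_p * np.exp(-0.25) + p.a_d * np.exp(-0.75)
    assert got == pytest.approx(want)
    got = pair_sum_oracle([-5.0, -25.0], [0.0], p)
    assert got == pytest.approx(p.a_p * (np.exp(-0.25) + np.exp(-1.25)))


def test_nearest_neighbor_takes_single_closest_pre():
    p = _params("nearest_neighbor")
    # two posts before a pre: each post pairs with the pre only if it is
    # its closest candidate; the pre after the later post depresses it
    got = pair_sum_oracle([0.0], [-10.0, -30.0], p)
    assert got == pytest.approx(p.a_d * np.exp(-0.5))
    # pre closer before than after -> potentiation wins
    got = pair_sum_oracle([8.0, 15.0], [10.0], p)
    assert got == pytest.approx(p.a_p * np.exp(-2.0 / 20.0))


def test_nearest_magnitude_bounded_by_all_to_all_potentiation():
    rng = np.random.default_rng(0)
    for _ in range(50):
        pre = np.sort(rng.uniform(0, 100, 10))
        post = np.sort(rng.uniform(0, 100, 3))
        nn = _params("nearest_neighbor", bias=1e-9)
        aa = _params("all_to_all", bias=1e-9)
        # with depression switched off, nn pairs a subset of the a2a pairs
        assert pair_sum_oracle(pre, post, nn) <= pair_sum_oracle(pre, post, aa) + 1e-12


@settings(deadline=None, max_examples=150)
@given(
    pre=st.lists(st.floats(0, 500), max_size=25),
    post=st.lists(st.floats(0, 500), max_size=25),
    mode=st.sampled_from(["nearest_neighbor", "all_to_all"]),
)
def test_online_trace_equals_pair_sum_oracle(pre, post, mode):
    """The event-driven bookkeeping reproduces the explicit pair enumeration."""
    p = _params(mode)
    events = sorted([(t, 0) for t in pre] + [(t, 1) for t in post])
    o = OnlineStdp(p)
    total = 0.0
    for t, kind in events:
        total += o.on_pre(t) if kind == 0 else o.on_post(t)
    total += o.flush()
    ref = pair_sum_oracle(pre, post, p)
    assert total == pytest.approx(ref, abs=1e-9, rel=1e-9)


def test_depression_dominates_on_uncorrelated_trains():
    """Independent Poisson pre/post trains depress on average (both modes)."""
    rng = np.random.default_rng(42)
    for mode in ("nearest_neighbor", "all_to_all"):
        p = _params(mode, bias=1.4)
        tot = 0.0
        for _ in range(60):
            pre = np.sort(rng.uniform(0, 2000, rng.poisson(128)))
            post = np.sort(rng.uniform(0, 2000, rng.poisson(16)))
            tot += pair_sum_oracle(pre, post, p)
        assert tot < 0


# ---------------------------------------------------------------------------
# normalization and initialization

def test_normalize_lateral_branches():
    assert np.allclose(normalize_lateral([30.0, 30.0], 50.0), [25.0, 25.0])
    assert np.allclose(normalize_lateral([10.0, 20.0], 50.0), [10.0, 20.0])
    out = normalize_lateral([50.0, 50.0, 0.0], 50.0)
    assert np.allclose(out, [25.0, 25.0, 0.0])
    with pytest.raises(ValueError):
        normalize_lateral([-1.0, 2.0], 50.0)


@given(w=st.lists(st.floats(0, 100), min_size=1, max_size=30), cap=st.floats(1, 200))
@settings(deadline=None, max_examples=100)
def test_normalize_lateral_invariants(w, cap):
    out = normalize_lateral(w, cap)
    assert out.sum() <= cap * (1 + 1e-9)
    w = np.asarray(w)
    if w.sum() <= cap:
        assert np.allclose(out, w)
    else:
        # proportional rescale: out = w * (cap / sum)
        assert np.allclose(out, w * (cap / w.sum()), rtol=1e-12, atol=0)


def test_init_weights_distribution(rng):
    ws = init_weights(rng, 2000, 20, 0.3125, 50.0)
    ws.validate()
    assert ws.w_ff.mean() == pytest.approx(0.3125 / 2, rel=0.02)
    assert np.all(np.diag(ws.w_lat) == 0.0)
    assert ws.w_ff.min() > 0
    assert ws.incoming_lateral_sums().max() <= 19 * 50.0 / 20


def test_weightset_validate_catches_violations():
    ws = WeightSet(np.full((4, 2), 0.1), np.zeros((2, 2)), 0.3, 50.0)
    ws.validate()
    ws.w_lat[0, 1] = 60.0
    with pytest.raises(ValueError):
        ws.validate()
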