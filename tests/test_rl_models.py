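import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlmvpa._errors import InputError, ParameterError
from rlmvpa.rl_models import (
    MODEL_SPECS,
    AgentParams,
    ModelSpec,
    from_unconstrained,
    negloglik,
    rw_update,
    simulate_agent,
    softmax_probs,
    to_unconstrained,
    value_series,
)
from rlmvpa.task_env import TaskConfig


class TestModelSpec:
    def test_four_variants(self):
        assert {s.name for s in MODEL_SPECS} == {"A-RS-", "A+RS-", "A-RS+", "A+RS+"}

    def test_param_counts(self):
        assert ModelSpec(False, False).n_params == 2
        assert ModelSpec(True, True).n_params == 3

    def test_from_name_round_trip(self):
        for s in MODEL_SPECS:
            assert ModelSpec.from_name(s.name) == s
        with pytest.raises(ParameterError):
            ModelSpec.from_name("B+RS-")


class TestRwUpdate:
    def test_basic_step(self):
        V = rw_update(np.zeros(3), 0, +1.0, AgentParams(0.5, 0.5, 1.0), ModelSpec())
        assert np.allclose(V, [0.5, 0, 0])

    def test_counterfactual_step(self):
        V = rw_update(
            np.zeros(3), 0, +1.0, AgentParams(0.5, 0.5, 1.0), ModelSpec(True, False)
        )
        assert np.allclose(V, [0.5, -0.5, -0.5])

    def test_null_learning(self):
        for spec in MODEL_SPECS:
            V = rw_update(
                np.array([0.2, -0.1, 0.0]), 1, -1.0, AgentParams(0.0, 0.0, 1.0), spec
            )
            assert np.allclose(V, [0.2, -0.1, 0.0])

    def test_risk_sensitive_gating(self):
        p = AgentParams(0.5, 0.1, 1.0)
        spec = ModelSpec(False, True)
        up = rw_update(np.zeros(3), 0, +1.0, p, spec)
        down = rw_update(np.zeros(3), 0, -1.0, p, spec)
        assert up[0] == pytest.approx(0.5)  # positive delta -> alpha_pos
        assert down[0] == pytest.approx(-0.1)  # negative delta -> alpha_neg

    def test_counterfactual_zero_outcome_asymmetry(self):
        # r=0 is a no-op for unchosen arms only when their values are 0
        p = AgentParams(0.5, 0.5, 1.0)
        spec = ModelSpec(True, False)
        V0 = rw_update(np.zeros(3), 0, 0.0, p, spec)
        assert np.allclose(V0, 0.0)
        V1 = rw_update(np.array([0.0, 0.4, 0.0]), 0, 0.0, p, spec)
        assert V1[1] == pytest.approx(0.2)  # pulled toward -r = 0

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            rw_update(np.array([np.nan, 0, 0]), 0, 1.0, AgentParams(0.5, 0.5, 1.0), ModelSpec())


class TestSoftmax:
    def test_beta_zero_uniform(self):
        assert np.allclose(softmax_probs(np.array([3.0, -1.0, 0.5]), 0.0), 1 / 3)

    def test_equal_values_uniform(self):
        assert np.allclose(softmax_probs(np.full(3, 0.7), 5.0), 1 / 3)

    def test_direct_formula(self):
        # frozen from the closed form: e^2/(e^2+2), 1/(e^2+2)
        p = softmax_probs(np.array([1.0, 0.0, 0.0]), 2.0)
        e2 = math.exp(2.0)
        assert np.allclose(p, [e2 / (e2 + 2), 1 / (e2 + 2), 1 / (e2 + 2)], atol=1e-12)
        assert np.round(p, 3).tolist() == [0.787, 0.107, 0.107]

    def test_negative_beta_rejected(self):
        with pytest.raises(ParameterError):
            softmax_probs(np.zeros(3), -1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        v=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        beta=st.floats(0, 50),
        shift=st.floats(-10, 10),
    )
    def test_sums_to_one_and_shift_invariant(self, v, beta, shift):
        v = np.array(v)
        p = softmax_probs(v, beta)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.allclose(p, softmax_probs(v + shift, beta), atol=1e-9)


def _reference_nll(params, spec, trials, n_arms=3):
    """Straight-line independent recomputation (oracle for negloglik)."""
    V = [0.0] * n_arms
    nll = 0.0
    for t in trials:
        exps = [math.exp(params.beta * v) for v in V]
        nll -= math.log(exps[t.arm] / sum(exps))
        delta = t.outcome - V[t.arm]
        if spec.risk_sensitive and delta < 0:
            a = params.alpha_neg
        else:
            a = params.alpha_pos
        V[t.arm] += a * delta
        if spec.counterfactual:
            for u in range(n_arms):
                if u == t.arm:
                    continue
                du = -t.outcome - V[u]
                if spec.risk_sensitive and du < 0:
                    au = params.alpha_neg
                else:
                    au = params.alpha_pos
                V[u] += au * du
    return nll


class TestNegloglik:
    def test_uniform_policy_closed_form(self):
        recs = simulate_agent(AgentParams(0.3, 0.3, 2.0), ModelSpec(), seed=0)
        nll = negloglik(AgentParams(0.3, 0.3, 0.0), ModelSpec(), recs)
        assert nll == pytest.approx(90 * math.log(3), rel=1e-12)

    def test_nonnegative_and_bounded(self):
        recs = simulate_agent(AgentParams(0.5, 0.2, 4.0), ModelSpec(True, True), seed=1)
        for spec in MODEL_SPECS:
            nll = negloglik(AgentParams(0.5, 0.2, 4.0), spec, recs)
            assert 0.0 <= nll < np.inf

    def test_matches_reference_recomputation(self, rng):
        for i in range(5):
            spec = MODEL_SPECS[i % 4]
            params = AgentParams(rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9), rng.uniform(0.5, 8))
            recs = simulate_agent(params, spec, seed=100 + i)
            assert negloglik(params, spec, recs) == pytest.approx(
                _reference_nll(params, spec, recs), abs=1e-10
            )

    def test_unordered_trials_rejected(self):
        recs = simulate_agent(AgentParams(0.3, 0.3, 2.0), ModelSpec(), seed=2)
        with pytest.raises(InputError):
            negloglik(AgentParams(0.3, 0.3, 2.0), ModelSpec(), recs[::-1])

    def test_continuity_in_parameters(self):
        recs = simulate_agent(AgentParams(0.4, 0.4, 3.0), ModelSpec(True, True), seed=3)
        spec = ModelSpec(True, True)
        base = negloglik(AgentParams(0.4, 0.3, 3.0), spec, recs)
        eps = 1e-6
        for bumped in (
            AgentParams(0.4 + eps, 0.3, 3.0),
            AgentParams(0.4, 0.3 + eps, 3.0),
            AgentParams(0.4, 0.3, 3.0 + eps),
        ):
            assert abs(negloglik(bumped, spec, recs) - base) < 1e-3


class TestSimulateAgent:
    def test_exploitation_beats_chance(self):
        hits = 0
        for seed in range(200):
            recs = simulate_agent(AgentParams(0.3, 0.3, 20.0), ModelSpec(), seed=seed)
            frac = np.mean([r.p_arm == 0.8 for r in recs])
            hits += frac > 1 / 3
        assert hits >= 190  # >= 95% of 200 runs

    def test_beta_zero_uniform_choices(self):
        cfg = TaskConfig(n_trials=9990, block_length=30)
        recs = simulate_agent(AgentParams(0.3, 0.3, 0.0), ModelSpec(), cfg, seed=5)
        from scipy.stats import chisquare

        counts = np.bincount([r.arm for r in recs], minlength=3)
        assert chisquare(counts).pvalue > 0.01

    def test_tied_rates_reduce_to_rs_minus(self):
        tied = AgentParams(0.35, 0.35, 3.0)
        for cf in (False, True):
            a = simulate_agent(tied, ModelSpec(cf, True), seed=6)
            b = simulate_agent(tied, ModelSpec(cf, False), seed=6)
            assert [(r.arm, r.outcome) for r in a] == [(r.arm, r.outcome) for r in b]


class TestTransforms:
    @settings(max_examples=40, deadline=None)
    @given(
        a1=st.floats(0.01, 0.99),
        a2=st.floats(0.01, 0.99),
        b=st.floats(0.01, 50),
        rs=st.booleans(),
    )
    def test_round_trip(self, a1, a2, b, rs):
        spec = ModelSpec(False, rs)
        p = AgentParams(a1, a2 if rs else a1, b)
        q = from_unconstrained(to_unconstrained(p, spec), spec)
        assert q.alpha_pos == pytest.approx(p.alpha_pos, rel=1e-9)
        assert q.beta == pytest.approx(p.beta, rel=1e-9)


def test_value_series_matches_session_replay():
    params = AgentParams(0.4, 0.2, 4.0)
    spec = ModelSpec(True, True)
    recs = simulate_agent(params, spec, seed=8)
    v = value_series(params, spec, recs)
    assert v.shape == (90,)
    assert v[0] == 0.0
    # reference forward replay
    V = np.zeros(3)
    for t, r in enumerate(recs):
        assert v[t] == pytest.approx(V[r.arm], abs=1e-12)
        V = rw_update(V, r.arm, r.outcome, params, spec)
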