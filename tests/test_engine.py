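"""Stochastic engine versus the analytic three-state model."""

import math

import numpy as np
import pytest
from scipy import stats

import myoswarm as ms
from myoswarm import (
    AgentPhase,
    AgentState,
    ConfigurationError,
    EngineConfig,
    IsoformConfig,
    attachment_histogram,
    duty_ratio_replicates,
    estimate_contact_probability,
    estimate_unloaded_velocity,
    kinetics_at_velocity,
    run_steady_state,
    sample_attachment,
    step_agent,
    unloaded_velocity,
)

SLOW_OFF = IsoformConfig("slow detacher", k_on=900.0, k_off=1.0, delta_plus=5.0)


def _dT(consts, v):
    return consts.dX / v


class TestStepAgent:
    """Single-step reference semantics of the three-state agent."""

    def test_power_stroke_shortens_by_dx(self, chicken, consts):
        out = step_agent(
            AgentState(AgentPhase.POWER, 3.0, 10.0), chicken, consts, _dT(consts, 5000.0), 0.5
        )
        assert (out.state, out.d) == (AgentPhase.POWER, 2.0)

    def test_power_hands_over_to_drag_at_zero(self, chicken, consts):
        out = step_agent(
            AgentState(AgentPhase.POWER, 1.0, 10.0), chicken, consts, _dT(consts, 5000.0), 0.5
        )
        assert (out.state, out.d) == (AgentPhase.DRAG, 0.0)

    def test_detached_stays_detached_without_a_site(self, chicken, consts):
        out = step_agent(
            AgentState(AgentPhase.DETACHED, None, 10.0), chicken, consts, _dT(consts, 5000.0), 0.0
        )
        assert (out.state, out.d) == (AgentPhase.DETACHED, None)

    def test_drag_survival_keeps_sliding(self, consts):
        # k_off*dT = 1e-6 here, so a draw of 0.999 survives and slides on
        out = step_agent(
            AgentState(AgentPhase.DRAG, -2.0, 10.0), SLOW_OFF, consts, _dT(consts, 1000.0), 0.999
        )
        assert (out.state, out.d) == (AgentPhase.DRAG, -3.0)

    def test_binding_sets_full_power_stroke(self, chicken, consts):
        # phase just below the zone edge, draw below p_on: binds at exactly d+
        out = step_agent(
            AgentState(AgentPhase.DETACHED, None, consts.x_z - consts.dX - 0.01),
            chicken,
            consts,
            _dT(consts, 5000.0),
            0.0,
        )
        assert (out.state, out.d) == (AgentPhase.POWER, chicken.delta_plus)

    def test_power_stroke_duration_is_exact(self, chicken, consts):
        agent = AgentState(AgentPhase.POWER, chicken.delta_plus, 10.0)
        steps = 0
        while agent.state == AgentPhase.POWER:
            agent = step_agent(agent, chicken, consts, _dT(consts, 5000.0), 0.999999)
            steps += 1
        assert steps == round(chicken.delta_plus / consts.dX)

    def test_transition_legality(self, chicken, consts):
        # binding only from DETACHED; detachment only from DRAG
        rng = np.random.default_rng(7)
        agent = AgentState(AgentPhase.DETACHED, None, 0.0)
        seen = set()
        for _ in range(20_000):
            nxt = step_agent(agent, chicken, consts, _dT(consts, 3000.0), rng.random())
            seen.add((agent.state, nxt.state))
            if nxt.state != AgentPhase.DETACHED:
                assert nxt.d is not None
                if nxt.state == AgentPhase.POWER:
                    assert nxt.d > 0
                else:
                    assert nxt.d <= 0
            agent = nxt
        assert (AgentPhase.POWER, AgentPhase.DETACHED) not in seen or chicken.delta_plus < consts.dX
        assert (AgentPhase.DRAG, AgentPhase.POWER) not in seen
        assert (AgentPhase.POWER, AgentPhase.DRAG) in seen  # cycle actually ran

    def test_probability_overflow_rejected(self, consts):
        fast = IsoformConfig("too fast", 900.0, 50_000.0, 5.0)
        with pytest.raises(ConfigurationError):
            step_agent(AgentState(), fast, consts, _dT(consts, 100.0), 0.5)


class TestSteadyState:
    def test_force_balances_at_unloaded_velocity(self, chicken, consts):
        v_u = unloaded_velocity(chicken)
        cfg = EngineConfig(v=v_u, N=24, seed=11, max_steps=150_000, min_samples=150_001)
        res = run_steady_state(chicken, consts, cfg)
        # the naive SE underestimates the sampling error of the correlated
        # per-step stream; allow an absolute floor alongside 3*se
        assert abs(res.mean_f) <= max(3 * res.se_f, 0.02)

    def test_histogram_counts_match_samples(self, median, consts):
        res = sample_attachment(median, consts, v=unloaded_velocity(median), N=10,
                                n_samples=500, seed=3)
        assert int(res.attached_histogram.sum()) == 500
        assert res.p_c_hat == pytest.approx(
            1.0 - res.attached_histogram[0] / 500.0, abs=1e-12
        )

    def test_nonconvergence_is_flagged(self, chicken, consts):
        cfg = EngineConfig(v=unloaded_velocity(chicken), N=4, seed=1,
                           max_steps=3000, min_samples=1000)
        res = run_steady_state(chicken, consts, cfg)
        assert res.converged is False

    def test_seed_reproducibility(self, chicken, consts):
        cfg = dict(v=unloaded_velocity(chicken), N=12, max_steps=20_000, min_samples=20_001)
        a = run_steady_state(chicken, consts, EngineConfig(seed=5, **cfg))
        b = run_steady_state(chicken, consts, EngineConfig(seed=5, **cfg))
        c = run_steady_state(chicken, consts, EngineConfig(seed=6, **cfg))
        assert a.mean_f == b.mean_f and a.duty_ratio == b.duty_ratio
        assert np.array_equal(a.attached_histogram, b.attached_histogram)
        assert a.mean_f != c.mean_f


class TestEngineMatchesTheory:
    def test_single_population_duty_ratio(self, chicken, consts):
        v_u = unloaded_velocity(chicken)
        r = kinetics_at_velocity(chicken, consts, v_u).r
        reps = duty_ratio_replicates(
            chicken, consts, v=v_u, reps=8, steps_per_rep=15_000, N=24, seed=2
        )
        se = reps.std(ddof=1) / math.sqrt(len(reps))
        assert abs(reps.mean() - r) <= 3 * se

    def test_drag_dwell_mean(self, chicken, consts):
        cfg = EngineConfig(v=unloaded_velocity(chicken), N=16, seed=9,
                           max_steps=120_000, min_samples=120_001)
        res = run_steady_state(chicken, consts, cfg)
        se = (1.0 / chicken.k_off) / math.sqrt(res.n_dwells)  # exponential: sd ~ mean
        assert abs(res.dwell_mean - 1.0 / chicken.k_off) <= 3 * se

    def test_contact_probability_single_agent(self, median, consts):
        # with N=1 the contact probability is the duty ratio itself
        v_u = unloaded_velocity(median)
        r = kinetics_at_velocity(median, consts, v_u).r
        pc, hist = estimate_contact_probability(
            median, consts, v=v_u, N=1, n_samples=6000, replicates=24, seed=17
        )
        se = math.sqrt(r * (1 - r) / hist.sum())
        assert abs(pc - r) <= 3 * se + 0.01 * r

    def test_attached_counts_track_mean(self, median, consts):
        v_u = unloaded_velocity(median)
        r = kinetics_at_velocity(median, consts, v_u).r
        hist = attachment_histogram(
            median, consts, v=v_u, N=25, n_samples=4000, replicates=16, seed=23
        )
        k = np.arange(hist.size)
        mean = float((k * hist).sum() / hist.sum())
        se = math.sqrt(25 * r / hist.sum())  # Poisson-scale error
        assert abs(mean - 25 * r) <= 4 * se

    def test_unloaded_velocity_bracket(self, chicken, consts):
        est = estimate_unloaded_velocity(chicken, consts, seed=31, mode="fast")
        v_ana = unloaded_velocity(chicken)
        assert est.v_hat - est.increment < v_ana <= est.v_hat + 1e-9
        assert est.mean_d <= 0.0

    def test_unloaded_velocity_strict_mode_scans_from_zero(self, consts):
        slow = IsoformConfig("slow", 900.0, 80.0, 5.0)  # v_u ~ 283 nm/s
        est = estimate_unloaded_velocity(slow, consts, seed=3, mode="strict")
        assert est.mode == "strict"
        assert est.v_hat - est.increment < unloaded_velocity(slow) <= est.v_hat


def test_dissociation_window_probabilities_validated(chicken, consts):
    with pytest.raises(ConfigurationError):
        EngineConfig(v=-5.0, N=10)
    with pytest.raises(ConfigurationError):
        EngineConfig(v=1000.0, N=0)
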