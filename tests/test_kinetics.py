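"""Closed-form three-state model: spot values, identities, and limit behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myoswarm as ms
from myoswarm import (
    DEFAULT_CONSTANTS,
    IsoformConfig,
    MasterCurveCoefficients,
    ModelConstants,
    adjusted_unloaded_velocity,
    calibrate_binding_zone,
    contact_probability,
    derive_mechanics,
    energy_metrics,
    kinetics_at_velocity,
    master_curve_predict,
    required_n_for_contact,
    unloaded_velocity,
)

SQRT2 = math.sqrt(2.0)


@pytest.mark.parametrize(
    "lever, theta, e_atp, dp, kappa",
    [
        (10.0, 30.0, 62.5, 5.0, 2.5),  # sin(30)=1/2, 62.5/25
        (10.0, 90.0, 62.5, 10.0, 0.625),  # sin(90)=1
        (20.0, 30.0, 62.5, 10.0, 0.625),  # 62.5/100
    ],
)
def test_derive_mechanics(lever, theta, e_atp, dp, kappa):
    got_dp, got_kappa = derive_mechanics(lever, theta, e_atp)
    assert got_dp == pytest.approx(dp, rel=1e-12)
    assert got_kappa == pytest.approx(kappa, rel=1e-12)


@pytest.mark.parametrize("bad", [(-1, 30, 62.5), (10, 0, 62.5), (10, 120, 62.5), (10, 30, -5)])
def test_derive_mechanics_rejects_bad_inputs(bad):
    with pytest.raises(ValueError):
        derive_mechanics(*bad)


def test_unloaded_velocity_values(chicken, median):
    assert unloaded_velocity(chicken) == pytest.approx(0.5 * SQRT2 * 5 * 1600, rel=1e-12)
    assert unloaded_velocity(chicken) == pytest.approx(5656.9, abs=0.1)
    assert unloaded_velocity(median) == pytest.approx(17677.7, abs=0.1)


def test_unloaded_velocity_is_linear_in_step_and_detachment(chicken):
    v0 = unloaded_velocity(chicken)
    assert unloaded_velocity(chicken.perturbed(delta_plus=10.0)) == pytest.approx(2 * v0)
    assert unloaded_velocity(chicken.perturbed(k_off=3200.0)) == pytest.approx(2 * v0)
    assert unloaded_velocity(chicken.perturbed(k_on=9000.0)) == pytest.approx(v0)


def test_kinetics_chicken_at_unloaded_velocity(chicken, consts):
    v_u = unloaded_velocity(chicken)
    ks = kinetics_at_velocity(chicken, consts, v_u)
    assert ks.delta_minus == pytest.approx(3.536, abs=1e-3)
    assert ks.delta_on == pytest.approx(8.536, abs=1e-3)
    assert ks.p_on == pytest.approx(0.1672, abs=1e-4)
    assert ks.Delta == pytest.approx(215.3, abs=0.1)
    assert ks.r == pytest.approx(0.0397, abs=1e-4)
    # at v_u power- and drag-strokes balance exactly
    assert ks.mean_d == pytest.approx(0.0, abs=1e-12)
    assert ks.mean_f == pytest.approx(0.0, abs=1e-12)


def test_kinetics_median_at_unloaded_velocity(median, consts):
    ks = kinetics_at_velocity(median, consts, unloaded_velocity(median))
    assert ks.Delta == pytest.approx(295.1, abs=0.2)
    assert ks.r == pytest.approx(0.0579, abs=2e-4)
    assert ks.e_rate == pytest.approx(59.9, abs=0.1)


@pytest.mark.parametrize("name", ["chicken skeletal", "median", "baseline", "low", "high"])
def test_mean_displacement_vanishes_at_unloaded_velocity(name, consts):
    iso = ms.get_isoform(name)
    ks = kinetics_at_velocity(iso, consts, unloaded_velocity(iso))
    assert abs(ks.mean_d) < 1e-9 * iso.delta_plus


def test_kinetics_rejects_nonpositive_velocity(chicken, consts):
    for v in (0.0, -100.0, None):
        with pytest.raises(ValueError):
            kinetics_at_velocity(chicken, consts, v)


def test_duty_ratio_decreases_and_travel_exceeds_spacing(median, consts):
    vs = np.linspace(500.0, 40_000.0, 60)
    states = [kinetics_at_velocity(median, consts, v) for v in vs]
    rs = np.array([s.r for s in states])
    assert np.all(np.diff(rs) < 0)
    assert all(s.Delta >= consts.x_d for s in states)


def _contact_bruteforce(r: float, n: int) -> float:
    # independent-Bernoulli enumeration over all 2^n attachment patterns
    total = 0.0
    for mask in range(1, 2**n):
        k = bin(mask).count("1")
        total += r**k * (1 - r) ** (n - k)
    return total


@pytest.mark.parametrize("r, n", [(0.5, 1), (0.0397, 7), (0.3, 10), (0.039648, 12)])
def test_contact_probability_matches_enumeration(r, n):
    assert contact_probability(r, n) == pytest.approx(_contact_bruteforce(r, n), abs=1e-12)


def test_contact_probability_edges():
    assert contact_probability(0.5, 1) == pytest.approx(0.5)
    assert contact_probability(0.0, 100) == 0.0
    assert contact_probability(1.0, 3) == 1.0
    with pytest.raises(ValueError):
        contact_probability(1.5, 10)
    with pytest.raises(ValueError):
        contact_probability(0.5, -1)


@given(st.floats(min_value=0.1, max_value=20.0))
@settings(max_examples=50, deadline=None)
def test_contact_probability_poisson_limit(nr):
    # as r -> 0 with N*r fixed, 1-(1-r)^N -> 1-exp(-N*r)
    gaps = []
    for n in (100, 10_000, 1_000_000):
        r = nr / n
        gaps.append(abs(contact_probability(r, n) - (1 - math.exp(-nr))))
    assert gaps[-1] < gaps[0] + 1e-12
    assert gaps[-1] < 1e-5


def test_required_n_for_contact_is_minimal(chicken, consts):
    r = kinetics_at_velocity(chicken, consts, unloaded_velocity(chicken)).r
    n = required_n_for_contact(r, 0.90)
    assert contact_probability(r, n) >= 0.90
    assert contact_probability(r, n - 1) < 0.90


@given(
    k_on=st.floats(min_value=300, max_value=5000),
    k_off=st.floats(min_value=500, max_value=5000),
    dp=st.floats(min_value=2.0, max_value=20.0),
    v=st.floats(min_value=200.0, max_value=40_000.0),
    n=st.integers(min_value=1, max_value=500),
)
@settings(max_examples=100, deadline=None)
def test_required_energy_identity(k_on, k_off, dp, v, n):
    # N_att * v / (dp + v/k_off) == e * N_att / r for any parameters
    iso = IsoformConfig("draw", k_on, k_off, dp)
    ks = kinetics_at_velocity(iso, DEFAULT_CONSTANTS, v)
    em = energy_metrics(iso, DEFAULT_CONSTANTS, v, n)
    assert em.E_req == pytest.approx(ks.e_rate * em.N_att / ks.r, rel=1e-9)


def test_required_energy_at_unloaded_velocity(median, consts):
    # at v_u, E_req per attached myosin is k_off*(sqrt(2)-1)
    v_u = unloaded_velocity(median)
    em = energy_metrics(median, consts, v_u, 100)
    assert em.E_req / em.N_att == pytest.approx(median.k_off * (SQRT2 - 1), rel=1e-9)
    assert em.E_req / em.N_att == pytest.approx(1035.5, abs=0.1)


def test_energy_metrics_median_operating_point(median, consts):
    v_u = unloaded_velocity(median)
    em = energy_metrics(median, consts, v_u, 48)
    ks = kinetics_at_velocity(median, consts, v_u)
    assert em.N_att == pytest.approx(48 * ks.r, rel=1e-12)
    assert em.E_sys == pytest.approx(48 * ks.e_rate, rel=1e-12)
    assert em.E_star == pytest.approx(7.99e3, rel=5e-3)


def test_energy_metrics_empty_ensemble(median, consts):
    em = energy_metrics(median, consts, unloaded_velocity(median), 0)
    assert (em.N_att, em.E_sys, em.E_star, em.P_C) == (0.0, 0.0, 0.0, 0.0)


def test_master_curve_prediction():
    coeffs = MasterCurveCoefficients(A=14.5, B=4.5e-4)
    assert master_curve_predict(0.0, coeffs) == pytest.approx(14.5)
    e_star_500 = math.log(500.0 / 14.5) / 4.5e-4
    assert master_curve_predict(e_star_500, coeffs) == pytest.approx(500.0, rel=1e-12)
    xs = np.linspace(0, 2e4, 50)
    ys = [master_curve_predict(x, coeffs) for x in xs]
    assert np.all(np.diff(ys) > 0)
    with pytest.raises(ValueError):
        master_curve_predict(-1.0, coeffs)
    with pytest.raises(ValueError):
        MasterCurveCoefficients(A=-1.0, B=4.5e-4)


def test_adjusted_unloaded_velocity():
    assert adjusted_unloaded_velocity(1.0, 5656.9) == pytest.approx(5656.9)
    assert adjusted_unloaded_velocity(0.0, 5656.9) == 0.0
    assert adjusted_unloaded_velocity(0.91, 5656.9) == pytest.approx(5147.8, abs=0.1)
    with pytest.raises(ValueError):
        adjusted_unloaded_velocity(1.2, 100.0)


def test_binding_zone_calibration_roundtrip(chicken, consts):
    # the default x_z reproduces itself through the calibration inverse
    r = kinetics_at_velocity(chicken, consts, unloaded_velocity(chicken)).r
    pc = contact_probability(r, 60)
    assert calibrate_binding_zone(
        chicken.k_on, chicken.k_off, chicken.delta_plus, target_pc=pc, n=60
    ) == pytest.approx(consts.x_z, rel=1e-9)


def test_model_constants_validation():
    with pytest.raises(ValueError):
        ModelConstants(x_z=40.0)  # zone wider than site spacing
    with pytest.raises(ValueError):
        ModelConstants(dX=0.0)
    assert ModelConstants().with_(x_z=2.0).x_z == 2.0


def test_isoform_construction():
    iso = IsoformConfig.from_lever("test", 900.0, 1600.0, 10.0, theta=30.0)
    assert iso.delta_plus == pytest.approx(5.0, rel=1e-12)
    with pytest.raises(ValueError):
        IsoformConfig("bad", -1.0, 1600.0, 5.0)
    with pytest.raises(TypeError):
        iso.perturbed(nope=3.0)
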