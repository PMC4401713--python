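"""Closed-form relations of the three-state myosin motility model.

This module is the analytic counterpart of the stochastic engine. For a
filament gliding at steady velocity v past a bed of myosins with binding
sites spaced x_d apart:

* drag-stroke length        delta_minus = v / k_off
* full stroke span          delta_on = delta_plus + delta_minus
* binding prob. per passage P_on = 1 - exp(-k_on * x_z / v)
* travel per myosin cycle   Delta = x_d / P_on
* duty ratio                r = delta_on / Delta
* ATPase rate per myosin    e = v / Delta
* mean head displacement    <d> = (dp/2)(dp/d_on) - dm*(dm/d_on)
* mean force per myosin     <f> = kappa * r * <d>,   kappa = e_atp / dp^2

Setting <d> = 0 yields the unloaded velocity v_u = (sqrt(2)/2) * dp * k_off.
Ensemble quantities follow: contact probability P_C = 1 - (1-r)^N, mean
attached count N_att = N*r, system energy rate E_sys = e*N, and the adjusted
system energy E* = E_sys * N_att that unifies processive lifetimes across
isoforms via P(E*) = A * exp(B * E*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .isoforms import IsoformConfig

SQRT2_OVER_2 = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class KineticState:
    """Velocity-dependent derived quantities for one isoform.

    All lengths nm, rates s^-1, forces pN, stiffness pN/nm. ``mean_d`` is the
    time-average head displacement conditional on being attached; ``mean_f``
    is the unconditional time-average force per myosin, kappa * r * mean_d.
    """

    v: float
    delta_minus: float
    delta_on: float
    p_on: float
    Delta: float
    r: float
    e_rate: float
    mean_d: float
    kappa: float
    mean_f: float


@dataclass(frozen=True)
class EnergyMetrics:
    """Ensemble energy bookkeeping at a given velocity and size N.

    Energies are ATP turnovers per second: E_sys = e*N, E_star = E_sys*N_att,
    and E_req = N_att * v / (delta_plus + v/k_off), the rate required to keep
    N_att myosins attached on average (identically e * N_att / r).
    """

    N: int
    N_att: float
    E_sys: float
    E_req: float
    E_star: float
    P_C: float


@dataclass(frozen=True)
class MasterCurveCoefficients:
    """Coefficients of the unified scaling law P(E*) = A * exp(B * E*).

    A is a lifetime intercept in ms; B an energy sensitivity in s (the
    reciprocal of ATP/s).
    """

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0):
            raise ValueError(f"master-curve coefficients must be positive: A={self.A}, B={self.B}")


def derive_mechanics(
    lever_length: float, theta: float, e_atp: float = DEFAULT_CONSTANTS.e_atp
) -> tuple[float, float]:
    """Power-stroke length and myosin stiffness from lever geometry.

    delta_plus = l * sin(theta); kappa = e_atp / delta_plus**2, i.e. the
    stiffness at which a fully displaced head stores exactly one ATP's worth
    of elastic energy (62.5 zJ == 62.5 pN*nm).

    Returns ``(delta_plus [nm], kappa [pN/nm])``.
    """
    if not lever_length > 0:
        raise ValueError(f"lever_length must be strictly positive, got {lever_length!r}")
    if not 0 < theta <= 90:
        raise ValueError(f"theta must lie in (0, 90] degrees, got {theta!r}")
    if not e_atp > 0:
        raise ValueError(f"e_atp must be strictly positive, got {e_atp!r}")
    delta_plus = lever_length * math.sin(math.radians(theta))
    kappa = e_atp / delta_plus**2
    return delta_plus, kappa


def stiffness(iso: IsoformConfig, consts: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """kappa = e_atp / delta_plus^2 in pN/nm for an isoform."""
    return consts.e_atp / iso.delta_plus**2


def unloaded_velocity(iso: IsoformConfig) -> float:
    """Unloaded gliding velocity v_u = (sqrt(2)/2) * delta_plus * k_off, nm/s.

    This is the velocity at which power-stroking and drag-stroking myosins
    balance, i.e. the root of mean_d(v) = 0.
    """
    return SQRT2_OVER_2 * iso.delta_plus * iso.k_off


def kinetics_at_velocity(
    iso: IsoformConfig, consts: ModelConstants = DEFAULT_CONSTANTS, v: float = None
) -> KineticState:
    """Evaluate the steady-state relations at a finite velocity v > 0.

    The v -> 0 limit has P_on -> 1 and Delta -> x_d; the v -> inf limit has
    P_on -> 0. Both are singular in 1/v and deliberately not extrapolated:
    callers needing them should use the limit values explicitly.
    """
    if v is None or not v > 0:
        raise ValueError(
            f"v must be strictly positive, got {v!r}; use the documented limits "
            "(P_on->1, Delta->x_d as v->0; P_on->0 as v->inf) explicitly"
        )
    delta_minus = v / iso.k_off
    delta_on = iso.delta_plus + delta_minus
    p_on = -math.expm1(-iso.k_on * consts.x_z / v)
    Delta = consts.x_d / p_on
    r = delta_on / Delta
    e_rate = v / Delta
    mean_d = (iso.delta_plus / 2.0) * (iso.delta_plus / delta_on) - delta_minus * (
        delta_minus / delta_on
    )
    kappa = stiffness(iso, consts)
    mean_f = kappa * r * mean_d
    return KineticState(
        v=v,
        delta_minus=delta_minus,
        delta_on=delta_on,
        p_on=p_on,
        Delta=Delta,
        r=r,
        e_rate=e_rate,
        mean_d=mean_d,
        kappa=kappa,
        mean_f=mean_f,
    )


def contact_probability(r: float, N: int) -> float:
    """P_C = 1 - (1 - r)^N: probability that at least one of N independent
    myosins, each attached a fraction r of the time, is attached."""
    if not 0 <= r <= 1:
        raise ValueError(f"duty ratio r must lie in [0, 1], got {r!r}")
    if N < 0 or int(N) != N:
        raise ValueError(f"N must be a non-negative integer, got {N!r}")
    return -math.expm1(N * math.log1p(-r)) if r < 1 else (1.0 if N > 0 else 0.0)


def required_n_for_contact(r: float, target_pc: float = 0.90, n_max: int = 100_000) -> int:
    """Smallest integer N with contact probability 1-(1-r)^N >= target_pc."""
    if not 0 < r < 1:
        raise ValueError(f"duty ratio r must lie in (0, 1), got {r!r}")
    if not 0 < target_pc < 1:
        raise ValueError(f"target_pc must lie in (0, 1), got {target_pc!r}")
    n = math.ceil(math.log(1.0 - target_pc) / math.log1p(-r) - 1e-12)
    n = max(n, 1)
    if n > n_max:
        raise ValueError(f"required N={n} exceeds n_max={n_max}")
    # guard against floating-point edge: enforce the defining inequality
    while contact_probability(r, n) < target_pc:
        n += 1
    while n > 1 and contact_probability(r, n - 1) >= target_pc:
        n -= 1
    return n


def energy_metrics(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    v: float = None,
    N: int = 1,
) -> EnergyMetrics:
    """Ensemble energy metrics at velocity v for ensemble size N.

    N_att = N*r; E_sys = e*N; E_star = E_sys*N_att;
    E_req = N_att * v / (delta_plus + v/k_off), which equals e*N_att/r and,
    at v = v_u, N_att * k_off * (sqrt(2) - 1).
    """
    if N < 0 or int(N) != N:
        raise ValueError(f"N must be a non-negative integer, got {N!r}")
    if N == 0:
        return EnergyMetrics(N=0, N_att=0.0, E_sys=0.0, E_req=0.0, E_star=0.0, P_C=0.0)
    ks = kinetics_at_velocity(iso, consts, v)
    n_att = N * ks.r
    e_sys = ks.e_rate * N
    e_req = n_att * v / (iso.delta_plus + v / iso.k_off)
    e_star = e_sys * n_att
    return EnergyMetrics(
        N=int(N),
        N_att=n_att,
        E_sys=e_sys,
        E_req=e_req,
        E_star=e_star,
        P_C=contact_probability(ks.r, int(N)),
    )


def master_curve_predict(e_star: float, coeffs: MasterCurveCoefficients) -> float:
    """Predicted mean processive lifetime A * exp(B * E*), ms."""
    if e_star < 0:
        raise ValueError(f"E* must be non-negative, got {e_star!r}")
    return coeffs.A * math.exp(coeffs.B * e_star)


def adjusted_unloaded_velocity(p_c: float, v_u: float) -> float:
    """Contact-probability-adjusted filament velocity v_u* = P_C * v_u, nm/s."""
    if not 0 <= p_c <= 1:
        raise ValueError(f"P_C must lie in [0, 1], got {p_c!r}")
    return p_c * v_u
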