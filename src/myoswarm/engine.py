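"""Agent-based stochastic engine for constant-velocity motility assays.

The engine drives a rigid filament at fixed velocity v over a 36 nm lattice
of binding sites and steps N autonomous three-state myosin agents (detached /
power-stroke / drag-stroke) in dX = 1 nm increments, dT = dX/v. Agents are
independent (no steric exclusion, no filament compliance): every ensemble
statistic is a sum over independent per-agent renewal processes, which is
what makes the attached-count distribution Poisson-like and the analytic
kinetics of :mod:`myoswarm.kinetics` the engine's expectation.

:func:`step_agent` is the single-step reference semantics; the hot paths run
through the numba kernels in :mod:`myoswarm._kernels`, which implement the
same transition rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from . import _kernels
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .isoforms import IsoformConfig
from .kinetics import kinetics_at_velocity, stiffness, unloaded_velocity


class ConfigurationError(ValueError):
    """Raised for physically inconsistent engine configurations."""


class DiscretizationWarning(UserWarning):
    """Emitted when per-step transition probabilities exceed 0.1.

    The per-step Bernoulli semantics keep mean dwell times exact at any
    k*dT <= 1, but the dwell-time distributions coarsen as k*dT grows.
    """


class AgentPhase(IntEnum):
    DETACHED = _kernels.DETACHED
    POWER = _kernels.POWER
    DRAG = _kernels.DRAG


@dataclass
class AgentState:
    """One myosin agent: mechanochemical state, head displacement, lattice phase.

    ``d`` is the head displacement from zero strain in nm (None while
    detached; positive in the power-stroke, <= 0 in the drag-stroke).
    ``anchor_phase`` locates the agent's zero-strain point modulo the site
    spacing; a binding site is within reach while the phase lies in
    [0, x_z).
    """

    state: AgentPhase = AgentPhase.DETACHED
    d: float | None = None
    anchor_phase: float = 0.0


@dataclass
class EngineConfig:
    """Run configuration for the stochastic engine.

    ``sample_stride`` is the spacing, in steps, between recorded
    attached-count samples; the default (one analytic myosin cycle,
    Delta/dX) gives approximately decorrelated samples. ``dT`` is always
    derived as dX/v, never stored.
    """

    v: float
    N: int
    seed: int = 0
    max_steps: int = 20_000_000
    min_samples: int = 1000
    sample_stride: int | None = None
    burn_in: int | None = None  # steps; default 5 analytic cycles
    stratified_phases: bool = False  # equidistribute anchor phases (variance reduction)

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ConfigurationError(f"v must be strictly positive, got {self.v!r}")
        if self.N < 1:
            raise ConfigurationError(f"N must be >= 1, got {self.N!r}")


@dataclass
class SteadyStateResult:
    """Aggregate statistics of one steady-state run.

    ``mean_f``/``se_f`` are the per-myosin time-average force and its naive
    standard error over the per-step sample stream (pN); ``mean_d`` the
    attached-conditional mean head displacement (nm); ``p_c_hat`` the
    fraction of strided samples with at least one agent attached;
    ``n_att_hat`` the time-average attached count; ``duty_ratio`` the
    attached fraction of agent-steps; ``dwell_mean`` the mean drag-stroke
    dwell in seconds.
    """

    mean_f: float
    se_f: float
    m: int
    mean_d: float
    attached_histogram: np.ndarray
    p_c_hat: float
    n_att_hat: float
    duty_ratio: float
    dwell_mean: float
    n_dwells: int
    bind_events: int
    converged: bool
    config: EngineConfig = field(repr=False, default=None)


def step_probabilities(
    iso: IsoformConfig, consts: ModelConstants, v: float
) -> tuple[float, float, float]:
    """Per-step transition probabilities (p_on, p_off) and the step duration dT.

    Binding uses the exact within-step survival p_on = 1 - exp(-k_on*dT) so
    the per-site-passage binding probability reproduces the analytic
    P_on = 1 - exp(-k_on*x_z/v); detachment uses the linear p_off = k_off*dT
    so the mean drag dwell is exactly 1/k_off.
    """
    if not v > 0:
        raise ConfigurationError(f"v must be strictly positive, got {v!r}")
    dT = consts.dX / v
    p_off = iso.k_off * dT
    if p_off > 1.0:
        raise ConfigurationError(
            f"k_off*dT = {p_off:.3f} > 1 at v={v} nm/s, dX={consts.dX} nm; "
            "reduce dX or raise v"
        )
    if max(iso.k_on * dT, p_off) > 0.1:
        warnings.warn(
            f"per-step transition probability exceeds 0.1 "
            f"(k_on*dT={iso.k_on * dT:.3f}, k_off*dT={p_off:.3f}); "
            "dwell-time distributions are coarsely discretised",
            DiscretizationWarning,
            stacklevel=2,
        )
    p_on = -math.expm1(-iso.k_on * dT)
    return p_on, p_off, dT


def step_agent(
    agent: AgentState,
    iso: IsoformConfig,
    consts: ModelConstants,
    dT: float,
    rng_draw: float,
) -> AgentState:
    """Advance a single agent by one step (reference semantics).

    The filament translates dX during the step. A detached agent binds (with
    head displacement set to exactly delta_plus) if a site is in reach and
    ``rng_draw`` falls below the per-step binding probability. An attached
    agent's displacement falls by dX; the power-stroke hands over to the
    drag-stroke at zero displacement, and a drag-stroking agent detaches if
    ``rng_draw`` falls below k_off*dT, checked after the move.
    """
    if not dT > 0:
        raise ConfigurationError(f"dT must be strictly positive, got {dT!r}")
    v = consts.dX / dT
    p_on, p_off, _ = step_probabilities(iso, consts, v)
    phase = agent.anchor_phase + consts.dX
    if phase >= consts.x_d:
        phase -= consts.x_d
    state, d = agent.state, agent.d
    if state == AgentPhase.DETACHED:
        if phase < consts.x_z and rng_draw < p_on:
            state, d = AgentPhase.POWER, iso.delta_plus
    else:
        d = d - consts.dX
        if state == AgentPhase.POWER:
            if d <= 0.0:
                state = AgentPhase.DRAG
                g = -d / consts.dX
                if g > 0.0 and rng_draw < p_off * g:
                    state, d = AgentPhase.DETACHED, None
        else:
            if rng_draw < p_off:
                state, d = AgentPhase.DETACHED, None
    return AgentState(state=state, d=d, anchor_phase=phase)


def discrete_duty_ratio(
    iso: IsoformConfig, consts: ModelConstants, v: float
) -> float:
    """Exact stationary duty ratio of the discretised engine.

    The continuum duty ratio r = delta_on/Delta is the dX -> 0 limit. At
    finite dX a site passage offers floor(x_z/dX) or floor(x_z/dX)+1
    binding checks depending on the anchor phase, so the phase-averaged
    per-passage binding probability sits slightly below Eq-4's
    1 - exp(-k_on*x_z/v) (a Jensen gap of order (k_on*dT)^2). Exact when
    delta_plus/dX is an integer; otherwise carries an O(dX/delta_minus)
    remainder from the power/drag crossing step.
    """
    p_on, p_off, dT = step_probabilities(iso, consts, v)
    n_lo = math.floor(consts.x_z / consts.dX)
    frac = consts.x_z / consts.dX - n_lo
    q = 1.0 - p_on
    p_pass = (1 - frac) * (1.0 - q**n_lo) + frac * (1.0 - q ** (n_lo + 1))
    cycle_steps = consts.x_d / (consts.dX * p_pass)
    attached_steps = round(iso.delta_plus / consts.dX) + 1.0 / p_off
    return attached_steps / cycle_steps


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic 31-bit child seeds for kernel calls."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1


def _default_stride(iso: IsoformConfig, consts: ModelConstants, v: float) -> int:
    Delta = kinetics_at_velocity(iso, consts, v).Delta
    return max(1, round(Delta / consts.dX))


def _default_burn_in(iso: IsoformConfig, consts: ModelConstants, v: float) -> int:
    Delta = kinetics_at_velocity(iso, consts, v).Delta
    return max(1, round(5.0 * Delta / consts.dX))


def run_steady_state(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    cfg: EngineConfig = None,
) -> SteadyStateResult:
    """Run an ensemble to steady state and aggregate force/attachment statistics.

    A burn-in transient (five analytic cycles by default) is discarded, then
    the ensemble is stepped in blocks until the standard error of the
    per-myosin mean force drops to ``consts.se_threshold`` (after at least
    ``cfg.min_samples`` force samples) or ``cfg.max_steps`` is exhausted, in
    which case the result is flagged ``converged=False``.
    """
    if cfg is None:
        raise ConfigurationError("an EngineConfig is required")
    p_on, p_off, dT = step_probabilities(iso, consts, cfg.v)
    kappa = stiffness(iso, consts)
    stride = cfg.sample_stride or _default_stride(iso, consts, cfg.v)
    burn_in = cfg.burn_in if cfg.burn_in is not None else _default_burn_in(iso, consts, cfg.v)

    rng = np.random.default_rng(cfg.seed)
    state = np.zeros(cfg.N, dtype=np.int8)
    d = np.zeros(cfg.N, dtype=np.float64)
    if cfg.stratified_phases:
        # with dX = 1 nm the binding statistics depend on the fractional part
        # of the anchor phase (it sets 1 vs 2 in-window checks per passage);
        # stratifying the fractional parts removes that quenched-disorder
        # variance from ensemble averages without biasing them
        frac = (np.arange(cfg.N) + rng.random()) / cfg.N
        phase = np.mod(rng.integers(0, int(consts.x_d), cfg.N) + frac, consts.x_d)
        rng.shuffle(phase)
    else:
        phase = rng.uniform(0.0, consts.x_d, cfg.N)
    drag_ctr = np.zeros(cfg.N, dtype=np.int64)
    # blocks are a whole number of strides so strided sampling never skews
    block = stride * max(8, -(-2048 // stride))
    seeds = iter(_spawn_seeds(cfg.seed, cfg.max_steps // block + 8).tolist())

    if burn_in > 0:
        scratch = np.zeros(cfg.N + 1, dtype=np.int64)
        _kernels.steady_kernel(
            state, d, phase, drag_ctr, burn_in, consts.dX, consts.x_d, consts.x_z,
            iso.delta_plus, p_on, p_off, next(seeds), scratch, burn_in + 1,
        )

    hist = np.zeros(cfg.N + 1, dtype=np.int64)
    f_sum = f_sq = d_sum = 0.0
    m = att_steps = dwell_sum = dwell_cnt = binds = 0
    converged = False
    while m < cfg.max_steps:
        n_steps = min(block, cfg.max_steps - m)
        out = _kernels.steady_kernel(
            state, d, phase, drag_ctr, n_steps, consts.dX, consts.x_d, consts.x_z,
            iso.delta_plus, p_on, p_off, next(seeds), hist, stride,
        )
        f_sum += out[0]
        f_sq += out[1]
        m += out[2]
        att_steps += out[3]
        dwell_sum += out[4]
        dwell_cnt += out[5]
        binds += out[6]
        d_sum += out[7]
        if m >= cfg.min_samples:
            mean = f_sum / m
            var = max(f_sq / m - mean * mean, 0.0)
            se = kappa * math.sqrt(var / m)
            if se <= consts.se_threshold:
                converged = True
                break
    mean = f_sum / m
    var = max(f_sq / m - mean * mean, 0.0)
    n_hist = int(hist.sum())
    return SteadyStateResult(
        mean_f=kappa * mean,
        se_f=kappa * math.sqrt(var / m),
        m=m,
        mean_d=d_sum / att_steps if att_steps else 0.0,
        attached_histogram=hist,
        p_c_hat=1.0 - hist[0] / n_hist if n_hist else 0.0,
        n_att_hat=att_steps / m,
        duty_ratio=att_steps / (m * cfg.N),
        dwell_mean=(dwell_sum / dwell_cnt) * dT if dwell_cnt else math.nan,
        n_dwells=dwell_cnt,
        bind_events=binds,
        converged=converged,
        config=cfg,
    )


def sample_attachment(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    v: float,
    N: int,
    n_samples: int = 1000,
    seed: int = 0,
    stride: int | None = None,
) -> SteadyStateResult:
    """Record ``n_samples`` strided attached-count samples after burn-in.

    Convenience wrapper around the steady-state kernel sized so that the
    attached-count histogram holds exactly ``n_samples`` approximately
    decorrelated samples (default stride: one analytic cycle).
    """
    stride = stride or _default_stride(iso, consts, v)
    cfg = EngineConfig(
        v=v,
        N=N,
        seed=seed,
        max_steps=n_samples * stride,
        min_samples=n_samples * stride + 1,  # disable SE-based early stop
        sample_stride=stride,
    )
    return run_steady_state(iso, consts, cfg)


def attachment_histogram(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    v: float,
    N: int,
    n_samples: int = 1000,
    replicates: int = 8,
    seed: int = 0,
    stride: int | None = None,
) -> np.ndarray:
    """Attached-count histogram pooled over independent replicate ensembles.

    With dX = 1 nm and x_z = 1.15 nm an agent's anchor phase decides whether
    a passing site offers one or two binding checks, so per-agent duty
    ratios are phase-heterogeneous; pooling over ``replicates`` fresh-phase
    ensembles averages that quenched disorder out. The histogram's counts
    sum to ``n_samples`` (up to integer division across replicates).
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    replicates = max(1, min(replicates, n_samples))
    seeds = _spawn_seeds(seed, replicates)
    hist = np.zeros(N + 1, dtype=np.int64)
    per = n_samples // replicates
    extra = n_samples - per * replicates
    for i in range(replicates):
        res = sample_attachment(
            iso, consts, v=v, N=N,
            n_samples=per + (1 if i < extra else 0),
            seed=int(seeds[i]), stride=stride,
        )
        hist += res.attached_histogram
    return hist


def estimate_contact_probability(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    v: float,
    N: int,
    n_samples: int = 1000,
    replicates: int = 8,
    seed: int = 0,
    stride: int | None = None,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo contact probability: the fraction of strided samples with
    at least one attached agent, pooled over fresh-phase replicate ensembles.
    Returns (p_c_hat, attached-count histogram)."""
    hist = attachment_histogram(
        iso, consts, v=v, N=N, n_samples=n_samples,
        replicates=replicates, seed=seed, stride=stride,
    )
    total = int(hist.sum())
    return 1.0 - hist[0] / total, hist


@dataclass(frozen=True)
class VelocityEstimate:
    """Result of the iterative unloaded-velocity search.

    ``v_hat`` is the smallest grid velocity at which the simulated mean
    attached displacement fell to <= 0; the true root lies in
    ``(v_hat - increment, v_hat]`` up to sampling noise. ``mode`` records
    whether the grid started from zero ("strict") or warm-started below the
    analytic v_u ("fast").
    """

    v_hat: float
    increment: float
    mode: str
    mean_d: float
    n_evaluated: int


def estimate_unloaded_velocity(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    N: int = 16,
    seed: int = 0,
    mode: str = "fast",
    target_attached_samples: int = 200_000,
    v_ceiling_factor: float = 3.0,
) -> VelocityEstimate:
    """Find the unloaded velocity by scanning v upward until <d> <= 0.

    Walks the grid {dv, 2*dv, ...} (dv = consts.v_increment) and returns the
    first velocity at which the simulated time-average attached displacement
    is non-positive. ``mode="strict"`` starts from the bottom of the grid;
    ``mode="fast"`` warm-starts a few increments below the analytic root.
    Each velocity is simulated long enough to collect roughly
    ``target_attached_samples`` attached agent-steps.
    """
    dv = consts.v_increment
    v_ana = unloaded_velocity(iso)
    if mode == "strict":
        start = 1
    elif mode == "fast":
        start = max(1, int(v_ana / dv) - 5)
    else:
        raise ConfigurationError(f"mode must be 'strict' or 'fast', got {mode!r}")
    ceiling = max(v_ana * v_ceiling_factor, 10 * dv)
    seeds = _spawn_seeds(seed, 4 + int(ceiling / dv))
    k = start
    evaluated = 0
    while k * dv <= ceiling:
        v = k * dv
        if iso.k_off * consts.dX / v > 0.95:
            # too slow to discretise at this dX (k_off*dT ~ 1); the analytic
            # mean displacement is positive this far below v_u anyway
            k += 1
            continue
        r = kinetics_at_velocity(iso, consts, v).r
        n_steps = int(target_attached_samples / max(r * N, 1e-9))
        n_steps = min(max(n_steps, 10_000), 5_000_000)
        cfg = EngineConfig(
            v=v,
            N=N,
            seed=int(seeds[k % len(seeds)]),
            max_steps=n_steps,
            min_samples=n_steps + 1,
        )
        res = run_steady_state(iso, consts, cfg)
        evaluated += 1
        if res.mean_d <= 0.0:
            return VelocityEstimate(
                v_hat=v, increment=dv, mode=mode, mean_d=res.mean_d, n_evaluated=evaluated
            )
        k += 1
    raise ConfigurationError(
        f"unloaded-velocity search failed to bracket a root below {ceiling:.0f} nm/s"
    )


def duty_ratio_replicates(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    v: float,
    reps: int = 8,
    steps_per_rep: int = 100_000,
    N: int = 1,
    seed: int = 0,
    stratified_phases: bool = True,
) -> np.ndarray:
    """Independent replicate estimates of the per-myosin duty ratio.

    Returns an array of ``reps`` attached-time fractions, one per replicate
    run, from which a mean and standard error can be formed. Phases are
    stratified by default so the estimate targets the phase-averaged duty
    ratio rather than one ensemble's quenched phase draw.
    """
    out = np.empty(reps)
    for i in range(reps):
        cfg = EngineConfig(
            v=v,
            N=N,
            seed=seed * 1_000_003 + i,
            max_steps=steps_per_rep,
            min_samples=steps_per_rep + 1,
            stratified_phases=stratified_phases,
        )
        out[i] = run_steady_state(iso, consts, cfg).duty_ratio
    return out
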