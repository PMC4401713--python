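"""Processive run-length simulation, required-energy search, master-curve fit.

A processive event starts with all agents detached, its clock starting at the
first myosin-actin contact. The system dissociates once no myosin has been
attached for a full dissociation window (1 ms by default, the mean time for
an unheld filament to diffuse out of reach); the recorded lifetime runs from
first contact to the last detachment, excluding the terminal window.

Across ensembles and isoforms, mean lifetimes P collapse onto a single
exponential law in the adjusted system energy E* = E_sys * N_att:
P(E*) = A * exp(B * E*), which :func:`sweep_and_fit` recovers by ordinary
least squares on log lifetimes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .engine import ConfigurationError, sample_attachment, step_probabilities
from .isoforms import IsoformConfig
from .kinetics import (
    MasterCurveCoefficients,
    energy_metrics,
    unloaded_velocity,
)


@dataclass(frozen=True)
class RunRecord:
    """One processive run-length event.

    ``lifetime`` and ``first_contact_time`` in ms; ``terminated_by`` is
    "DISSOCIATION" for a completed event or "MAX_TIME" for a censored one.
    """

    lifetime: float
    first_contact_time: float
    n_binding_events: int
    terminated_by: str


@dataclass
class LifetimeStats:
    """Aggregate lifetime statistics over a batch of independent runs.

    ``mean_P``/``se_P`` in ms over completed (non-censored) runs;
    ``exp_rate_fit`` is the maximum-likelihood exponential decay rate 1/mean
    in ms^-1; ``histogram`` holds (counts, bin_edges_ms). Censored
    (MAX_TIME) runs are counted in ``n_censored`` and excluded from the
    moments.
    """

    mean_P: float
    se_P: float
    reps: int
    n_censored: int
    lifetimes: np.ndarray = field(repr=False)
    histogram: tuple = field(repr=False)
    exp_rate_fit: float = math.nan


def _window_steps(consts: ModelConstants, dT: float) -> int:
    return max(1, math.ceil(consts.dissociation_window / 1000.0 / dT - 1e-9))


def simulate_processive_run(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    N: int,
    v: float | None = None,
    seed: int = 0,
    max_time: float = 20.0,
) -> RunRecord:
    """Simulate a single processive event; ``v`` defaults to the isoform's
    analytic unloaded velocity. ``max_time`` (s) bounds near-perpetual runs,
    which come back flagged MAX_TIME."""
    if N < 1:
        raise ConfigurationError(f"N must be >= 1, got {N!r}")
    if v is None:
        v = unloaded_velocity(iso)
    p_on, p_off, dT = step_probabilities(iso, consts, v)
    max_steps = int(max_time / dT)
    life, first, binds, flag = _kernels.processive_kernel(
        N, consts.dX, consts.x_d, consts.x_z, iso.delta_plus,
        p_on, p_off, _window_steps(consts, dT), max_steps, seed,
    )
    if flag == 2:
        raise ConfigurationError(
            f"no binding event within max_time={max_time}s (N={N}, v={v:.0f} nm/s)"
        )
    return RunRecord(
        lifetime=life * dT * 1000.0,
        first_contact_time=first * dT * 1000.0,
        n_binding_events=int(binds),
        terminated_by="DISSOCIATION" if flag == 0 else "MAX_TIME",
    )


def lifetime_batch(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    N: int,
    reps: int = 1000,
    seed: int = 0,
    v: float | None = None,
    max_time: float = 20.0,
    n_bins: int = 20,
    censor_warn: bool = True,
) -> LifetimeStats:
    """Run ``reps`` independent processive events on disjoint seed substreams.

    Censored runs are excluded from the mean with a warning; the exponential
    rate fit is the MLE 1/mean over completed runs.
    """
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps!r}")
    if v is None:
        v = unloaded_velocity(iso)
    p_on, p_off, dT = step_probabilities(iso, consts, v)
    max_steps = int(max_time / dT)
    w = _window_steps(consts, dT)
    seeds = np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint32) >> 1
    lifetimes = []
    n_censored = 0
    for s in seeds:
        life, first, binds, flag = _kernels.processive_kernel(
            N, consts.dX, consts.x_d, consts.x_z, iso.delta_plus,
            p_on, p_off, w, max_steps, int(s),
        )
        if flag == 2:
            raise ConfigurationError(
                f"no binding event within max_time={max_time}s (N={N}, v={v:.0f} nm/s)"
            )
        if flag == 1:
            n_censored += 1
        else:
            lifetimes.append(life * dT * 1000.0)
    if n_censored and censor_warn:
        warnings.warn(
            f"{n_censored}/{reps} runs hit max_time={max_time}s and were excluded "
            "from the batch mean (near-perpetual regime)",
            stacklevel=2,
        )
    lt = np.asarray(lifetimes)
    if lt.size == 0:
        raise ConfigurationError(
            "all runs were censored at max_time; the condition is perpetually "
            "processive at this scale — raise max_time or lower N"
        )
    mean = float(lt.mean())
    se = float(lt.std(ddof=1) / math.sqrt(lt.size)) if lt.size > 1 else math.nan
    return LifetimeStats(
        mean_P=mean,
        se_P=se,
        reps=reps,
        n_censored=n_censored,
        lifetimes=lt,
        histogram=np.histogram(lt, bins=n_bins),
        exp_rate_fit=1.0 / mean,
    )


@dataclass(frozen=True)
class RequiredEnergyResult:
    """Outcome of the required-energy search at a target mean lifetime.

    ``E_sys`` is the analytic system energy rate e*N_req (ATP/s) at the
    isoform's unloaded velocity; ``E_star`` the corresponding adjusted
    energy; ``n_att_analytic`` = N_req * r and ``n_att_measured`` the
    engine's time-average attached count at N_req.
    """

    isoform: str
    N_req: int
    E_sys: float
    E_star: float
    n_att_analytic: float
    n_att_measured: float
    mean_P: float
    se_P: float


def find_required_ensemble(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    target_P: float = 500.0,
    reps: int = 1000,
    seed: int = 0,
    floor: int = 2,
    ceiling: int = 2000,
    coarse: bool = True,
    max_time: float = 20.0,
) -> RequiredEnergyResult:
    """Smallest ensemble size whose mean processive lifetime reaches ``target_P`` (ms).

    Increments N by 1 until the batch mean exceeds the target. With
    ``coarse=True`` a geometric bracket (doubling N from the floor) first
    locates the transition and the unit scan starts from the last ensemble
    size that fell short, which changes nothing when the mean is monotone in
    N; ``coarse=False`` scans every N from the floor.
    """
    if not target_P > 0:
        raise ConfigurationError(f"target_P must be positive, got {target_P!r}")
    v = unloaded_velocity(iso)
    # cap individual search runs well above the target: a censored run then
    # only ever understates the mean, so the acceptance rule below stays exact
    cap = min(max_time, max(10.0 * target_P / 1000.0, 1.0))

    def batch(n: int) -> LifetimeStats | None:
        # None means every run outlasted the cap: unambiguously above target
        try:
            return lifetime_batch(
                iso, consts, N=n, reps=reps, seed=seed + 7919 * n, v=v,
                max_time=cap, censor_warn=False,
            )
        except ConfigurationError:
            return None

    def reaches_target(stats: LifetimeStats | None) -> bool:
        if stats is None:
            return True
        # lower bound on the true mean: censored runs lasted at least `cap`
        lb = (stats.lifetimes.sum() + stats.n_censored * cap * 1000.0) / stats.reps
        return lb >= target_P

    start = floor
    if coarse:
        n = floor
        prev = floor
        while n <= ceiling:
            if reaches_target(batch(n)):
                break
            prev, n = n, n * 2
        start = prev
    n = start
    while n <= ceiling:
        stats = batch(n)
        if reaches_target(stats):
            em = energy_metrics(iso, consts, v, n)
            meas = sample_attachment(
                iso, consts, v=v, N=n, n_samples=2000, seed=seed + 13
            ).n_att_hat
            return RequiredEnergyResult(
                isoform=iso.label,
                N_req=n,
                E_sys=em.E_sys,
                E_star=em.E_star,
                n_att_analytic=em.N_att,
                n_att_measured=meas,
                mean_P=stats.mean_P if stats is not None else math.inf,
                se_P=stats.se_P if stats is not None else math.nan,
            )
        n += 1
    raise ConfigurationError(
        f"mean lifetime never reached {target_P} ms up to N={ceiling}"
    )


def plan_ensemble_sizes(
    iso: IsoformConfig,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    *,
    targets_ms: tuple = (30.0, 100.0, 400.0),
    reps: int = 40,
    seed: int = 0,
    floor: int = 2,
    cap: int = 600,
    max_time: float = 20.0,
) -> list[int]:
    """Pick ensemble sizes whose mean lifetimes land near ``targets_ms``.

    Cheap pilot batches scan N geometrically; ln(mean lifetime) is then
    interpolated against N^2 (the leading dependence of E* on N) to choose
    one N per target. Keeps the master-curve protocol self-contained: no
    externally fitted coefficients enter the choice.
    """
    v = unloaded_velocity(iso)
    ns, means = [], []
    n = max(2, floor)
    top = max(targets_ms)
    pilot_cap = min(max_time, max(8.0 * top / 1000.0, 1.0))
    while n <= cap:
        try:
            stats = lifetime_batch(
                iso, consts, N=n, reps=reps, seed=seed + 104729 * n, v=v,
                max_time=pilot_cap, censor_warn=False,
            )
        except ConfigurationError:
            break  # every pilot run outlasted the cap: far beyond the targets
        ns.append(n)
        means.append(stats.mean_P)
        if stats.mean_P >= 1.5 * top:
            break
        n = max(n + 1, int(round(n * 1.35)))
    if len(ns) < 2 or max(means) < min(targets_ms):
        raise ConfigurationError(
            f"pilot scan failed to span target lifetimes {targets_ms} by N={cap}"
        )
    n_sq = np.array(ns, dtype=float) ** 2
    log_p = np.log(means)
    order = np.argsort(log_p)
    chosen: list[int] = []
    for t in sorted(targets_ms):
        n_t = math.sqrt(float(np.interp(math.log(t), log_p[order], n_sq[order])))
        n_pick = max(2, int(round(n_t)))
        while n_pick in chosen:
            n_pick += 1
        chosen.append(n_pick)
    return chosen


@dataclass
class MasterCurveFit:
    """OLS fit of ln(mean_P) = ln A + B * E* over a sweep of conditions.

    ``points`` holds one row per (isoform, N) with columns isoform, N,
    E_star, mean_P, se_P, log_residual; ``r_squared`` is the goodness of fit
    on the log scale; ``residuals`` maps isoform label to its residual array
    (the collapse diagnostic: between-isoform spread comparable to
    within-batch noise means one master curve).
    """

    coeffs: MasterCurveCoefficients
    points: pd.DataFrame
    r_squared: float
    residuals: dict[str, np.ndarray]


def fit_master_curve(points: pd.DataFrame) -> MasterCurveFit:
    """Fit P = A*exp(B*E*) by unweighted least squares on log lifetimes.

    ``points`` needs columns ``isoform``, ``N``, ``E_star``, ``mean_P`` (ms);
    refitting a stored table reproduces the coefficients exactly.
    """
    if len(points) < 4:
        raise ConfigurationError(
            f"refusing to fit a master curve to {len(points)} < 4 points"
        )
    x = points["E_star"].to_numpy(dtype=float)
    y = np.log(points["mean_P"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    pred = intercept + slope * x
    resid = y - pred
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    pts = points.copy()
    pts["log_residual"] = resid
    residuals = {
        label: grp["log_residual"].to_numpy() for label, grp in pts.groupby("isoform")
    }
    return MasterCurveFit(
        coeffs=MasterCurveCoefficients(A=float(np.exp(intercept)), B=float(slope)),
        points=pts,
        r_squared=r2,
        residuals=residuals,
    )


def sweep_and_fit(
    isoforms: list[IsoformConfig],
    consts: ModelConstants = DEFAULT_CONSTANTS,
    n_grids: dict[str, list[int]] | None = None,
    *,
    reps: int = 200,
    seed: int = 0,
    targets_ms: tuple = (30.0, 100.0, 400.0),
    max_time: float = 20.0,
) -> MasterCurveFit:
    """Simulate lifetime batches over (isoform, N) conditions and fit the master curve.

    Each isoform runs at its own analytic unloaded velocity. ``n_grids`` maps
    isoform label to its ensemble sizes; missing entries are planned by
    :func:`plan_ensemble_sizes` so mean lifetimes span roughly
    ``targets_ms``. E* for each point uses the analytic kinetics at the
    run's velocity with the nominal N.
    """
    if len(isoforms) < 2:
        raise ConfigurationError("need at least 2 isoforms for a master-curve sweep")
    n_grids = dict(n_grids or {})
    ss = np.random.SeedSequence(seed)
    iso_seeds = ss.generate_state(2 * len(isoforms), dtype=np.uint32) >> 1
    rows = []
    for j, iso in enumerate(isoforms):
        v = unloaded_velocity(iso)
        grid = n_grids.get(iso.label)
        if grid is None:
            grid = plan_ensemble_sizes(
                iso, consts, targets_ms=targets_ms, seed=int(iso_seeds[2 * j]),
                max_time=max_time,
            )
        if len(grid) < 3:
            raise ConfigurationError(
                f"isoform {iso.label!r} needs >= 3 ensemble sizes, got {grid}"
            )
        for k, n in enumerate(grid):
            stats = lifetime_batch(
                iso, consts, N=n, reps=reps,
                seed=int(iso_seeds[2 * j + 1]) + 31 * k, v=v, max_time=max_time,
            )
            em = energy_metrics(iso, consts, v, n)
            rows.append(
                {
                    "isoform": iso.label,
                    "N": n,
                    "E_star": em.E_star,
                    "mean_P": stats.mean_P,
                    "se_P": stats.se_P,
                }
            )
    return fit_master_curve(pd.DataFrame(rows))


def median_family(include_multi: bool = False) -> list[IsoformConfig]:
    """The median isoform and its six single-parameter extrapolations.

    Parameters are varied one at a time to 2-3x above or below the datum
    values, spanning known fast-kinetics and long-lever myosins. With
    ``include_multi`` the "low" and "high" isoforms (all three parameters
    changed at once) are appended.
    """
    from .isoforms import get_isoform

    median = get_isoform("median")
    family = [
        median,
        median.perturbed(k_on=1000.0),
        median.perturbed(k_on=3000.0),
        median.perturbed(k_off=1500.0),
        median.perturbed(k_off=3500.0),
        median.perturbed(delta_plus=5.0),
        median.perturbed(delta_plus=15.0),
    ]
    if include_multi:
        family += [get_isoform("low"), get_isoform("high")]
    return family
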