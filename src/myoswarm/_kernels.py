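"""Numba-compiled inner loops of the agent-based engine.

All kernels share the same per-step agent update (one filament translation of
dX over dT = dX/v):

1. each agent's lattice phase advances by dX modulo x_d; a binding site is in
   reach while the phase lies in [0, x_z);
2. DETACHED agents in reach bind with probability p_on per step, entering the
   power-stroke with head displacement d = delta_plus;
3. attached agents' d decreases by dX; the power-stroke becomes a drag-stroke
   when d crosses zero; drag-stroking agents detach with probability p_off
   per step, checked after the move.

Force sampling uses trapezoid (power) / right-endpoint (drag) quadrature of
each step's sweep, which makes the stationary estimate of the mean attached
displacement exactly unbiased for the analytic
<d> = (dp^2/2 - dm^2)/d_on whenever delta_plus/dX is an integer. The partial
step at the power/drag crossing carries a hazard pro-rated by the fraction of
the sweep spent in drag, so non-integer delta_plus/dX incurs only an
O(dX/delta_minus) residual.

States: 0 = detached, 1 = power-stroke, 2 = drag-stroke.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DETACHED = 0
POWER = 1
DRAG = 2


@njit(cache=False)
def steady_kernel(
    state,  # int8[N], modified in place
    d,  # float64[N], modified in place
    phase,  # float64[N], modified in place
    drag_ctr,  # int64[N], modified in place
    n_steps,
    dx,
    x_d,
    x_z,
    delta_plus,
    p_on,
    p_off,
    seed,
    hist,  # int64[N+1] attached-count histogram, modified in place
    stride,  # record attached count every `stride` steps
):
    """Advance an ensemble n_steps; accumulate force and attachment statistics.

    Returns (f_sum, f_sq_sum, n_force_samples, attached_agent_steps,
    dwell_steps_sum, dwell_count, bind_events, d_sum). Force samples are the
    per-step per-myosin instantaneous force divided by kappa (i.e. mean
    displacement contribution); callers multiply by kappa.
    """
    np.random.seed(seed)
    n = state.shape[0]
    f_sum = 0.0
    f_sq = 0.0
    att_steps = 0
    dwell_sum = 0
    dwell_cnt = 0
    bind_events = 0
    d_sum = 0.0
    for t in range(n_steps):
        contrib = 0.0
        n_att = 0
        for i in range(n):
            ph = phase[i] + dx
            if ph >= x_d:
                ph -= x_d
            phase[i] = ph
            s = state[i]
            if s == DETACHED:
                if ph < x_z and np.random.random() < p_on:
                    state[i] = POWER
                    d[i] = delta_plus
                    bind_events += 1
                    n_att += 1
            else:
                di = d[i] - dx
                d[i] = di
                if s == POWER:
                    contrib += di + 0.5 * dx  # trapezoid of this step's sweep
                    if di > 0.0:
                        n_att += 1
                    else:
                        state[i] = DRAG
                        drag_ctr[i] = 0
                        g = -di / dx  # drag fraction of the crossing sweep
                        if g > 0.0 and np.random.random() < p_off * g:
                            state[i] = DETACHED
                            dwell_cnt += 1
                        else:
                            n_att += 1
                else:
                    contrib += di  # right endpoint: debiases the geometric dwell
                    drag_ctr[i] += 1
                    if np.random.random() < p_off:
                        state[i] = DETACHED
                        dwell_sum += drag_ctr[i]
                        dwell_cnt += 1
                    else:
                        n_att += 1
        att_steps += n_att
        d_sum += contrib
        fpm = contrib / n
        f_sum += fpm
        f_sq += fpm * fpm
        if t % stride == stride - 1:
            hist[n_att] += 1
    return f_sum, f_sq, n_steps, att_steps, dwell_sum, dwell_cnt, bind_events, d_sum


@njit(cache=False)
def processive_kernel(
    n_agents,
    dx,
    x_d,
    x_z,
    delta_plus,
    p_on,
    p_off,
    window_steps,
    max_steps,
    seed,
):
    """Run one processive event from an all-detached start.

    The lifetime clock starts at the first binding event; a dissociation
    timer accumulates over contiguous zero-attachment steps and fires once it
    reaches window_steps. Lifetime excludes the terminal window (measured to
    the step of last detachment).

    Returns (lifetime_steps, first_contact_step, bind_events, flag) with
    flag 0 = dissociation, 1 = max-time reached while engaged,
    2 = no binding event at all within max_steps.
    """
    np.random.seed(seed)
    state = np.zeros(n_agents, dtype=np.int8)
    d = np.zeros(n_agents, dtype=np.float64)
    phase = np.random.random(n_agents) * x_d
    first = np.int64(-1)
    gap = np.int64(0)
    gap_start = np.int64(0)
    bind_events = np.int64(0)
    for t in range(max_steps):
        n_att = 0
        for i in range(n_agents):
            ph = phase[i] + dx
            if ph >= x_d:
                ph -= x_d
            phase[i] = ph
            s = state[i]
            if s == DETACHED:
                if ph < x_z and np.random.random() < p_on:
                    state[i] = POWER
                    d[i] = delta_plus
                    bind_events += 1
                    n_att += 1
            else:
                di = d[i] - dx
                d[i] = di
                if s == POWER:
                    if di > 0.0:
                        n_att += 1
                    else:
                        state[i] = DRAG
                        g = -di / dx
                        if g > 0.0 and np.random.random() < p_off * g:
                            state[i] = DETACHED
                        else:
                            n_att += 1
                else:
                    if np.random.random() < p_off:
                        state[i] = DETACHED
                    else:
                        n_att += 1
        if n_att > 0:
            if first < 0:
                first = t
            gap = 0
        elif first >= 0:
            if gap == 0:
                gap_start = t
            gap += 1
            if gap >= window_steps:
                return gap_start - first, first, bind_events, 0
    if first < 0:
        return np.int64(0), first, bind_events, 2
    return np.int64(max_steps) - first, first, bind_events, 1
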