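"""Numba-compiled hot loops shared by the simulator, penalty and objective.

Every kernel works on the canonical 13-vector layout
``[x1(0), x2(0), x3(0), d11_on, d21_on, d22_on, d31_on, d32_on, d33_on,
d11_off, d12_off, d22_off, d33_off]``.  The pure-Python ``model.step``
implements the same one-day maps and serves as the reference the kernels are
tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: number of inequality terms in the penalty (see constraints.CONSTRAINT_LABELS)
N_Q_TERMS = 38

#: days at which continuous-suppression feasibility is checked
CAS_CHECK_EARLY = 360
CAS_CHECK_LATE = 1800

#: cap on any compartment inside the fitting kernels; keeps energies finite
#: for runaway candidates (1.2^3600 overflows a double) without affecting
#: any trajectory a feasible parameter vector can produce
STATE_CAP = 1e30


@njit(cache=True)
def _cap(v: float) -> float:
    if v > STATE_CAP:
        return STATE_CAP
    return v


@njit(cache=True)
def penalty_h(e: float) -> float:
    """Penalty kernel: 0 for a satisfied margin, 10000*(1 - e) for e < 0."""
    if e >= 0.0:
        return 0.0
    return 10000.0 * (1.0 - e)


@njit(cache=True)
def simulate_flags(p, flags):
    """Iterate the daily maps under a per-day on/off flag array.

    Returns states of shape (len(flags)+1, 3); row t is the state at day t.
    """
    T = flags.shape[0]
    out = np.empty((T + 1, 3))
    x1, x2, x3 = p[0], p[1], p[2]
    for t in range(T):
        out[t, 0] = x1
        out[t, 1] = x2
        out[t, 2] = x3
        if flags[t] == 1:
            y1 = p[3] * x1
            y2 = p[4] * x1 + p[5] * x2
            y3 = p[6] * x1 + p[7] * x2 + p[8] * x3
        else:
            y1 = p[9] * x1 + p[10] * x2
            y2 = p[11] * x2
            y3 = p[12] * x3
        x1, x2, x3 = y1, y2, y3
    out[T, 0] = x1
    out[T, 1] = x2
    out[T, 2] = x3
    return out


@njit(cache=True)
def cas_checkpoints(p):
    """Total PSA at the two continuous-suppression feasibility days.

    Runs the on-treatment map from the initial state for CAS_CHECK_LATE days
    and returns (PSA(360), PSA(1800)).
    """
    x1, x2, x3 = p[0], p[1], p[2]
    psa_early = x1 + x2 + x3
    for t in range(CAS_CHECK_LATE):
        y1 = _cap(p[3] * x1)
        y2 = _cap(p[4] * x1 + p[5] * x2)
        y3 = _cap(p[6] * x1 + p[7] * x2 + p[8] * x3)
        x1, x2, x3 = y1, y2, y3
        if t + 1 == CAS_CHECK_EARLY:
            psa_early = x1 + x2 + x3
    return psa_early, x1 + x2 + x3


@njit(cache=True)
def q_margins(p):
    """Margins e of the 38 inequality terms, in the fixed label order.

    A margin >= 0 means the term is satisfied; the penalty is
    sum(penalty_h(e)).  The last two terms require simulating continuous
    suppression to day 1800, which makes the penalty trajectory-dependent.
    """
    m = np.empty(N_Q_TERMS)
    k = 0
    # non-negativity of the 10 transition coefficients
    for i in range(3, 13):
        m[k] = p[i]
        k += 1
    # non-negativity of the 3 initial conditions
    for i in range(3):
        m[k] = p[i]
        k += 1
    # diagonal bounds 0.8 <= d <= 1.2 (six diagonals, two terms each)
    for i in (3, 5, 8, 9, 11, 12):
        m[k] = p[i] - 0.8
        k += 1
        m[k] = 1.2 - p[i]
        k += 1
    # off-diagonal caps <= 0.1
    for i in (4, 6, 7, 10):
        m[k] = 0.1 - p[i]
        k += 1
    # column sums within [0.8, 1.2]
    s1 = p[3] + p[4] + p[6]
    s2 = p[5] + p[7]
    s3 = p[10] + p[11]
    for s in (s1, s2, s3):
        m[k] = s - 0.8
        k += 1
        m[k] = 1.2 - s
        k += 1
    # irreversible compartment must not shrink on treatment
    m[k] = p[8] - 1.0
    k += 1
    # continuous-suppression feasibility: remission by day 360, relapse by 1800
    early, late = cas_checkpoints(p)
    m[k] = 2.0 - early
    k += 1
    m[k] = late - 10.0
    return m


@njit(cache=True)
def penalty_q_value(p):
    m = q_margins(p)
    q = 0.0
    for i in range(N_Q_TERMS):
        q += penalty_h(m[i])
    return q


@njit(cache=True)
def objective_parts(p, obs_t, obs_v, flags, weight, use_prior, pmean, pprec):
    """(sse_term, prior_term, q_value) of the penalized negative log posterior.

    weight = 1/(2 sigma^2).  obs_t must be strictly increasing and
    obs_t[-1] <= len(flags).  pprec is the prior precision (inverse
    covariance); ignored when use_prior is False.
    """
    K = obs_t.shape[0]
    T = flags.shape[0]
    sse = 0.0
    k = 0
    x1, x2, x3 = p[0], p[1], p[2]
    for t in range(T + 1):
        if k < K and obs_t[k] == t:
            r = obs_v[k] - (x1 + x2 + x3)
            sse += r * r
            k += 1
        if t == T:
            break
        if flags[t] == 1:
            y1 = _cap(p[3] * x1)
            y2 = _cap(p[4] * x1 + p[5] * x2)
            y3 = _cap(p[6] * x1 + p[7] * x2 + p[8] * x3)
        else:
            y1 = _cap(p[9] * x1 + p[10] * x2)
            y2 = _cap(p[11] * x2)
            y3 = _cap(p[12] * x3)
        x1, x2, x3 = y1, y2, y3
    sse *= weight

    prior_term = 0.0
    if use_prior:
        n = pmean.shape[0]
        for i in range(n):
            di = p[i] - pmean[i]
            for j in range(n):
                prior_term += di * pprec[i, j] * (p[j] - pmean[j])
        prior_term *= 0.5

    return sse, prior_term, penalty_q_value(p)


@njit(cache=True)
def objective_batch(P, obs_t, obs_v, flags, weight, use_prior, pmean, pprec):
    """Total objective for a whole population P of shape (S, 13)."""
    S = P.shape[0]
    out = np.empty(S)
    for s in range(S):
        a, b, c = objective_parts(P[s], obs_t, obs_v, flags, weight,
                                  use_prior, pmean, pprec)
        out[s] = a + b + c
    return out


@njit(cache=True)
def simulate_ias_kernel(p, min_on_days, psa_low, psa_high, horizon):
    """Threshold-switched intermittent schedule generated on the fly.

    Treatment starts on at day 0; switches off on the first day with at least
    min_on_days elapsed on-days in the current on-stint and PSA <= psa_low;
    switches back on on the first day with PSA >= psa_high.  Decisions use the
    noiseless model PSA at the start of the day; the chosen flag governs the
    step to the next day.
    """
    states = np.empty((horizon + 1, 3))
    flags = np.empty(horizon, dtype=np.uint8)
    x1, x2, x3 = p[0], p[1], p[2]
    on = True
    on_days = 0
    for t in range(horizon):
        states[t, 0] = x1
        states[t, 1] = x2
        states[t, 2] = x3
        psa = x1 + x2 + x3
        if on:
            if on_days >= min_on_days and psa <= psa_low:
                on = False
        else:
            if psa >= psa_high:
                on = True
                on_days = 0
        if on:
            flags[t] = 1
            on_days += 1
            y1 = p[3] * x1
            y2 = p[4] * x1 + p[5] * x2
            y3 = p[6] * x1 + p[7] * x2 + p[8] * x3
        else:
            flags[t] = 0
            y1 = p[9] * x1 + p[10] * x2
            y2 = p[11] * x2
            y3 = p[12] * x3
        x1, x2, x3 = y1, y2, y3
    states[horizon, 0] = x1
    states[horizon, 1] = x2
    states[horizon, 2] = x3
    return states, flags
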