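"""Synthetic patients and cohorts with the structure the analysis assumes.

Parameters are rejection-sampled from the biologically feasible region (the
penalty Q must be exactly zero, which includes the simulated continuous
-suppression feasibility checks), PSA series are generated by simulating the
threshold-switched trial protocol, sampling every few weeks plus at every
treatment switch, and adding i.i.d. Gaussian observation noise clipped at
zero.  This emulates the record structure of intermittent-suppression trial
data so the whole pipeline — prior-free cohort fits, prior construction,
MAP fits of truncated series, classification, cross-tabulation — runs
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._kernels import penalty_q_value, simulate_flags
from .classify import classify
from .constraints import constraint_margins
from .fitting import ObservationSeries
from .model import (CombinedParameters, IASProtocol, TreatmentSchedule,
                    simulate_ias)

DEFAULT_NOISE_SD = 0.64        # mean per-measurement residual scale, ng/mL
DEFAULT_SAMPLING_DAYS = 28     # typical PSA monitoring cadence
DEFAULT_FOLLOWUP_CAP = 30.0    # ng/mL; record ends at castration resistance


@dataclass(frozen=True)
class SyntheticPatient:
    params: CombinedParameters
    observations: ObservationSeries
    true_type: str


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_params(seed=None, max_attempts: int = 200_000
                  ) -> CombinedParameters:
    """Draw one feasible combined-parameter vector by rejection sampling.

    Proposal: diagonals uniform in [0.8, 1.2] conditioned so each
    constrained column sum lands in [0.8, 1.2] (d33_on in [1.0, 1.01] —
    larger on-treatment growth of the irreversible pool is essentially never
    compatible with the continuous-suppression feasibility window);
    conversion rates d21_on and d12_off uniform in [0, 0.1]; the fluxes into
    the irreversible pool d31_on, d32_on uniform in [0, 0.01]; total initial
    burden uniform in [5, 30] ng/mL, of which at most 20% starts reversibly
    resistant and at most 2% irreversibly resistant.  A draw is accepted only
    if the penalty Q is exactly zero, which checks every constraint
    including the simulated remission/relapse window.
    """
    rng = _rng(seed)
    worst: dict = {}
    for _ in range(int(max_attempts)):
        d21 = rng.uniform(0.0, 0.1)
        d31 = rng.uniform(0.0, 0.01)
        d32 = rng.uniform(0.0, 0.01)
        d12 = rng.uniform(0.0, 0.1)
        d11_on = rng.uniform(0.8, 1.2 - d21 - d31)
        d22_on = rng.uniform(0.8, 1.2 - d32)
        d33_on = rng.uniform(1.0, 1.01)
        d11_off = rng.uniform(0.8, 1.2)
        d22_off = rng.uniform(0.8, 1.2 - d12)
        d33_off = rng.uniform(0.8, 1.2)
        total = rng.uniform(5.0, 30.0)
        f2 = rng.uniform(0.0, 0.2)
        f3 = rng.uniform(0.0, 0.02)
        x0 = total * np.array([1.0 - f2 - f3, f2, f3])
        p = np.concatenate([x0, [d11_on, d21, d22_on, d31, d32, d33_on],
                            [d11_off, d12, d22_off, d33_off]])
        if penalty_q_value(p) == 0.0:
            return CombinedParameters.from_array(p)
        for label, e in constraint_margins(p):
            if e < 0:
                worst[label] = worst.get(label, 0) + 1
    dominant = max(worst, key=worst.get) if worst else "unknown"
    raise RuntimeError(
        f"no feasible parameter vector found in {max_attempts} attempts; "
        f"constraint dominating rejections: {dominant}")


def _clip_schedule(schedule: TreatmentSchedule, end: int
                   ) -> TreatmentSchedule:
    segs = []
    for s, e, m in schedule.segments:
        if s >= end:
            break
        segs.append((s, min(e, end), m))
    return TreatmentSchedule(tuple(segs))


def _observation_days(schedule: TreatmentSchedule, horizon: int,
                      sampling_interval: int) -> np.ndarray:
    days = set(range(0, horizon + 1, int(sampling_interval)))
    days.update(s for s, _, _ in schedule.segments if s <= horizon)
    days = np.array(sorted(d for d in days if d < schedule.end),
                    dtype=np.int64)
    return days


def generate_patient(params: CombinedParameters,
                     protocol: IASProtocol = IASProtocol(),
                     noise_sd: float = DEFAULT_NOISE_SD,
                     sampling_interval: int = DEFAULT_SAMPLING_DAYS,
                     seed=None,
                     followup_psa_cap: Optional[float] = DEFAULT_FOLLOWUP_CAP
                     ) -> ObservationSeries:
    """Simulate the trial protocol and sample noisy PSA measurements.

    PSA is read every ``sampling_interval`` days and additionally at every
    treatment-switch day; noise is Gaussian with s.d. ``noise_sd`` and the
    result is clipped at zero (PSA cannot be negative).  Follow-up ends at
    the first sampled day whose noiseless PSA reaches ``followup_psa_cap``
    (castration resistance established; real records stop there, they do
    not chart a decade of unchecked growth); pass None to observe the whole
    protocol horizon regardless.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed)
    traj, schedule = simulate_ias(params, protocol)
    days = _observation_days(schedule, protocol.horizon, sampling_interval)
    true = traj.psa[days]
    if followup_psa_cap is not None:
        over = np.flatnonzero(true >= followup_psa_cap)
        if over.size:
            days = days[:over[0] + 1]
            true = true[:over[0] + 1]
            schedule = _clip_schedule(schedule, int(days[-1]) + 1)
    noisy = true + rng.normal(0.0, noise_sd, size=days.size) \
        if noise_sd > 0 else true.copy()
    np.clip(noisy, 0.0, None, out=noisy)
    return ObservationSeries(times=days, values=noisy, schedule=schedule)


def generate_cohort(n: int, protocol: IASProtocol = IASProtocol(),
                    noise_sd: float = DEFAULT_NOISE_SD,
                    seed=None,
                    sampling_interval: int = DEFAULT_SAMPLING_DAYS,
                    followup_psa_cap: Optional[float] = DEFAULT_FOLLOWUP_CAP
                    ) -> List[SyntheticPatient]:
    """n independent synthetic patients with their true Type labels."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = _rng(seed)
    out = []
    for _ in range(int(n)):
        params = sample_params(rng)
        obs = generate_patient(params, protocol, noise_sd,
                               sampling_interval, rng, followup_psa_cap)
        label = classify(params, protocol).type_label
        out.append(SyntheticPatient(params, obs, label))
    return out


def generate_artificial_pre_off(params: CombinedParameters,
                                off_weeks: int = 16,
                                protocol: IASProtocol = IASProtocol(),
                                noise_sd: float = DEFAULT_NOISE_SD,
                                sampling_interval: int = DEFAULT_SAMPLING_DAYS,
                                seed=None,
                                followup_psa_cap: Optional[float] =
                                DEFAULT_FOLLOWUP_CAP) -> ObservationSeries:
    """Series with an untreated lead-in before the first on-period.

    The schedule is off-treatment for 7*off_weeks days, then on-treatment
    until the protocol's stopping rule fires (at least min_on_days elapsed
    and PSA at or below psa_low) or the horizon is reached.  Used to test
    whether pre-treatment observations help parameter estimation.
    """
    if off_weeks <= 0:
        raise ValueError("off_weeks must be positive")
    rng = _rng(seed)
    p = params.to_array()
    off_days = 7 * int(off_weeks)

    # evolve through the off lead-in, then apply the on-stopping rule
    flags = [0] * off_days
    x = simulate_flags(p, np.array(flags, dtype=np.uint8))[-1]
    on_days = 0
    while off_days + on_days < protocol.horizon:
        psa = float(x.sum())
        if on_days >= protocol.min_on_days and psa <= protocol.psa_low:
            break
        x = simulate_flags(p, np.array([1], dtype=np.uint8))[-1]
        flags.append(1)
        on_days += 1
    schedule = TreatmentSchedule.from_flags(flags)

    traj_states = simulate_flags(p, schedule.flags(schedule.end))
    days = _observation_days(schedule, schedule.end, sampling_interval)
    true = traj_states.sum(axis=1)[days]
    if followup_psa_cap is not None:
        # record ends at castration resistance, but only once therapy is on
        over = np.flatnonzero((true >= followup_psa_cap) & (days >= off_days))
        if over.size:
            days = days[:over[0] + 1]
            true = true[:over[0] + 1]
            schedule = _clip_schedule(schedule, int(days[-1]) + 1)
    noisy = true + rng.normal(0.0, noise_sd, size=days.size) \
        if noise_sd > 0 else true.copy()
    np.clip(noisy, 0.0, None, out=noisy)
    return ObservationSeries(times=days, values=noisy, schedule=schedule)
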