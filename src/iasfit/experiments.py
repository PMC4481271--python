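"""End-to-end simulation studies over synthetic cohorts.

These are the package's standing experiments: penalty-semantics agreement,
noiseless parameter recovery, prior shrinkage on truncated noisy records,
and calibration of the Mardia normality tests.  Both the test suite and the
reproduction script run them; every function takes an explicit seed and
returns plain dictionaries of computed quantities.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional

import numpy as np

from .classify import classify
from .constraints import penalty_Q
from .fitting import FitConfig, PsaTimeCourseModel, truncate
from .model import CombinedParameters, IASProtocol, TumorState, step
from .prior import build_prior, mardia_tests
from .synth import generate_patient, sample_params


def check_constraints_directly(params: CombinedParameters) -> bool:
    """Feasibility check written directly from the constraint definitions.

    Deliberately independent of the penalty implementation: margins are
    spelled out one by one and the continuous-suppression checkpoints come
    from iterating the pure-Python one-day map.
    """
    x0 = params.x0
    don = params.d_on      # d11, d21, d22, d31, d32, d33
    doff = params.d_off    # d11, d12, d22, d33
    if np.any(x0 < 0) or np.any(don < 0) or np.any(doff < 0):
        return False
    diags = [don[0], don[2], don[5], doff[0], doff[2], doff[3]]
    if any(d < 0.8 or d > 1.2 for d in diags):
        return False
    if don[1] > 0.1 or don[3] > 0.1 or don[4] > 0.1 or doff[1] > 0.1:
        return False
    for s in (don[0] + don[1] + don[3], don[2] + don[4], doff[1] + doff[2]):
        if s < 0.8 or s > 1.2:
            return False
    if don[5] < 1.0:
        return False
    x = TumorState(*x0)
    psa360 = None
    for t in range(1800):
        x = step(x, params, 1)
        if t + 1 == 360:
            psa360 = x.psa
    return psa360 <= 2.0 and x.psa >= 10.0


def penalty_semantics_study(n: int = 1000, seed: int = 0) -> Dict[str, float]:
    """Q = 0 iff all constraints hold, any violation costs more than 10000.

    Vectors come in three strata: known-feasible draws (the rejection
    sampler), near-feasible proposals without the rejection step (most sit
    just outside), and a wide box that violates freely.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    min_violated_q = np.inf
    n_feasible = 0
    for i in range(n):
        if i % 4 == 0:
            params = sample_params(rng)
            x0, d_on, d_off = params.x0, params.d_on, params.d_off
        elif i % 4 in (1, 2):
            x0 = rng.uniform(0, 30, 3)
            d_on = np.array([rng.uniform(0.8, 1.2), rng.uniform(0, 0.1),
                             rng.uniform(0.8, 1.2), rng.uniform(0, 0.01),
                             rng.uniform(0, 0.01), rng.uniform(1.0, 1.01)])
            d_off = np.array([rng.uniform(0.8, 1.2), rng.uniform(0, 0.1),
                              rng.uniform(0.8, 1.2), rng.uniform(0.8, 1.2)])
            params = CombinedParameters(x0, d_on, d_off)
        else:
            x0 = rng.uniform(-5, 40, 3)
            d_on = rng.uniform(-0.2, 1.4, 6)
            d_off = rng.uniform(-0.2, 1.4, 4)
            params = CombinedParameters(x0, d_on, d_off)
        rep = penalty_Q(params)
        ok = check_constraints_directly(params)
        if ok == (rep.q_value == 0.0):
            agree += 1
        if rep.q_value > 0:
            min_violated_q = min(min_violated_q, rep.q_value)
        else:
            n_feasible += 1
    return {
        "agreement_rate": agree / n,
        "min_violated_q": float(min_violated_q),
        "n_feasible": n_feasible,
        "n": n,
    }


def recovery_study(n_patients: int = 12, seed: int = 0,
                   config: Optional[FitConfig] = None) -> Dict[str, float]:
    """Prior-free fits of full noiseless synthetic records.

    Reports the worst and mean PSA RMSE at observation days and the
    fraction of patients whose fitted parameters reproduce the true Type.
    """
    rng = np.random.default_rng(seed)
    rmses, hits = [], 0
    for i in range(n_patients):
        params = sample_params(rng)
        obs = generate_patient(params, noise_sd=0.0, seed=rng)
        true_type = classify(params).type_label
        cfg = config or FitConfig(use_prior=False)
        res = PsaTimeCourseModel(obs, config=cfg).fit(
            seed=(seed + 7919 * (i + 1)) % (2 ** 31))
        rmses.append(res.rmse)
        hits += classify(res.params).type_label == true_type
    return {
        "max_rmse": float(np.max(rmses)),
        "mean_rmse": float(np.mean(rmses)),
        "type_accuracy": hits / n_patients,
        "n": n_patients,
    }


def _truncatable_patient(rng, noise_sd: float,
                         protocol: IASProtocol):
    """Draw patients until one has the on/off/on start that a one-and-a
    -half-cycle truncation needs (records ending in relapse before the
    second on-period cannot be truncated, as in the real study where only
    patients with enough cycles were usable)."""
    while True:
        params = sample_params(rng)
        obs = generate_patient(params, protocol, noise_sd, seed=rng)
        segs = obs.schedule.segments
        if (len(segs) >= 3 and segs[0][2] == 1 and segs[1][2] == 0
                and segs[2][2] == 1):
            return params, obs


def shrinkage_study(n_prior: int = 60, n_test: int = 10,
                    noise_sd: float = 0.64, seed: int = 0,
                    config: Optional[FitConfig] = None) -> Dict[str, float]:
    """MAP vs prior-free fits of one-and-a-half-cycle noisy records.

    The prior is the Gaussian over ``n_prior`` cohort parameter vectors.
    For ``n_test`` fresh patients, both fits run on the truncated record;
    reported are the mean Mahalanobis distance of each estimate to the
    prior mean (the prior should shrink estimates toward the cohort) and
    each method's agreement with the true Type labels.
    """
    rng = np.random.default_rng(seed)
    protocol = IASProtocol()
    prior = build_prior([sample_params(rng) for _ in range(n_prior)])
    prec = prior.precision

    def mahal(p: np.ndarray) -> float:
        d = p - prior.mean
        return float(np.sqrt(d @ prec @ d))

    d_map, d_free = [], []
    hit_map = hit_free = 0
    for i in range(n_test):
        params, obs = _truncatable_patient(rng, noise_sd, protocol)
        true_type = classify(params).type_label
        short = truncate(obs, "one_and_half")
        fit_seed = (seed + 104729 * (i + 1)) % (2 ** 31)

        base = config or FitConfig()
        res_map = PsaTimeCourseModel(
            short, prior=prior,
            config=replace(base, use_prior=True)).fit(seed=fit_seed)
        res_free = PsaTimeCourseModel(
            short,
            config=replace(base, use_prior=False)).fit(seed=fit_seed)

        d_map.append(mahal(res_map.params.to_array()))
        d_free.append(mahal(res_free.params.to_array()))
        hit_map += classify(res_map.params).type_label == true_type
        hit_free += classify(res_free.params).type_label == true_type
    return {
        "mean_mahalanobis_map": float(np.mean(d_map)),
        "mean_mahalanobis_free": float(np.mean(d_free)),
        "agreement_map": hit_map / n_test,
        "agreement_free": hit_free / n_test,
        "n": n_test,
    }


def mardia_calibration_study(n_reps: int = 200, n_draws: int = 200,
                             dim: int = 13, seed: int = 0,
                             alpha: float = 0.05) -> Dict[str, float]:
    """Rejection rates of Mardia's tests on true Gaussian samples."""
    rng = np.random.default_rng(seed)
    rej_skew = rej_kurt = 0
    for _ in range(n_reps):
        X = rng.standard_normal((n_draws, dim))
        res = mardia_tests(X)
        rej_skew += res.skewness_p < alpha
        rej_kurt += res.kurtosis_p < alpha
    return {
        "skewness_rejection_rate": rej_skew / n_reps,
        "kurtosis_rejection_rate": rej_kurt / n_reps,
        "n": n_reps,
    }
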