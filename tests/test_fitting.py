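"""Objective terms, truncation, and the differential-evolution fit path."""

from dataclasses import replace

import numpy as np
import pytest

import iasfit as F
from iasfit.fitting import (DEFAULT_SIGMA, ObservationSeries,
                            PsaTimeCourseModel, default_bounds, objective,
                            sse_term, truncate)
from iasfit.model import TreatmentSchedule
from iasfit.prior import build_prior, prior_quadform


def series_from(params, horizon=200, every=20,
                schedule=None) -> ObservationSeries:
    schedule = schedule or TreatmentSchedule.all_on(horizon)
    traj = F.simulate(params, schedule, horizon)
    t = np.arange(0, horizon, every)
    return ObservationSeries(times=t, values=traj.psa[t], schedule=schedule)


class TestObservationSeries:
    def test_validation(self):
        sched = TreatmentSchedule.all_on(10)
        with pytest.raises(ValueError, match="increasing"):
            ObservationSeries([0, 0], [1, 1], sched)
        with pytest.raises(ValueError, match="non-negative"):
            ObservationSeries([0, 5], [1, -1], sched)
        with pytest.raises(ValueError, match="beyond"):
            ObservationSeries([0, 10], [1, 1], sched)


class TestSseTerm:
    def test_zero_for_perfect_predictions(self, feasible_params):
        obs = series_from(feasible_params)
        assert sse_term(feasible_params, obs) == pytest.approx(0.0, abs=1e-12)

    def test_single_residual_weighting(self, feasible_params):
        """Residual 2 at sigma = 1/sqrt(2) contributes exactly 4."""
        sched = TreatmentSchedule.all_on(10)
        traj = F.simulate(feasible_params, sched, 10)
        obs = ObservationSeries([5], [traj.psa[5] + 2.0], sched)
        assert sse_term(feasible_params, obs, DEFAULT_SIGMA) == \
            pytest.approx(4.0)

    def test_doubling_sigma_quarters_the_term(self, feasible_params):
        sched = TreatmentSchedule.all_on(10)
        traj = F.simulate(feasible_params, sched, 10)
        obs = ObservationSeries([5], [traj.psa[5] + 1.5], sched)
        a = sse_term(feasible_params, obs, 0.5)
        b = sse_term(feasible_params, obs, 1.0)
        assert a == pytest.approx(4 * b)


class TestObjective:
    def test_vanishes_at_truth_with_prior_at_truth(self, feasible_params):
        obs = series_from(feasible_params)
        cohort = [feasible_params.to_array() + 0 for _ in range(3)]
        prior = build_prior(cohort, ridge=1e-6)
        assert objective(feasible_params, obs, prior) == \
            pytest.approx(0.0, abs=1e-9)

    def test_identity_prior_offset(self, feasible_params):
        obs = series_from(feasible_params)
        mean = feasible_params.to_array() + 0.0
        prior = F.PriorModel(mean=mean + 0.1, covariance=np.eye(13),
                             ridge=0.0, n_cohort=5)
        # perfect fit, feasible: objective reduces to the prior quadform
        expected = prior_quadform(feasible_params, prior)
        assert objective(feasible_params, obs, prior) == \
            pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.5 * 13 * 0.1 ** 2)

    def test_infeasible_vector_costs_at_least_10000(self, feasible_params):
        obs = series_from(feasible_params)
        p = feasible_params.to_array().copy()
        p[8] = 0.95
        assert objective(p, obs) >= 10000.0

    def test_decomposition_identity(self, feasible_params):
        """objective = sse + prior quadform + penalty at random points."""
        obs = series_from(feasible_params)
        rng = np.random.default_rng(0)
        cohort = [feasible_params.to_array() * rng.uniform(0.9, 1.1, 13)
                  for _ in range(20)]
        prior = build_prior(cohort)
        for _ in range(10):
            p = feasible_params.to_array() * rng.uniform(0.8, 1.2, 13)
            total = objective(p, obs, prior)
            parts = (sse_term(p, obs) + prior_quadform(p, prior)
                     + F.penalty_Q(p).q_value)
            assert total == pytest.approx(parts, rel=1e-9)


class TestTruncate:
    def _obs(self, pattern):
        segs, start = [], 0
        for m, length in pattern:
            segs.append((start, start + length, m))
            start += length
        sched = TreatmentSchedule(tuple(segs))
        t = np.arange(0, start, 10)
        return ObservationSeries(t, np.ones_like(t, dtype=float), sched)

    def test_full_is_identity(self):
        obs = self._obs([(1, 100), (0, 50), (1, 80), (0, 40)])
        out = truncate(obs, "full")
        assert out is obs

    def test_one_and_half_keeps_first_three_segments(self):
        obs = self._obs([(1, 100), (0, 50), (1, 80), (0, 40)])
        out = truncate(obs, "one_and_half")
        assert out.schedule.segments == ((0, 100, 1), (100, 150, 0),
                                         (150, 230, 1))
        assert out.times[-1] < 230
        assert np.all(out.times == obs.times[obs.times < 230])

    def test_half_keeps_first_on_segment(self):
        obs = self._obs([(1, 100), (0, 50), (1, 80)])
        out = truncate(obs, "half")
        assert out.schedule.segments == ((0, 100, 1),)
        assert out.times.max() < 100

    def test_half_on_off_first_series_errors(self):
        obs = self._obs([(0, 60), (1, 100)])
        with pytest.raises(ValueError, match="on-treatment"):
            truncate(obs, "half")

    def test_missing_segment_reported(self):
        obs = self._obs([(1, 100)])
        with pytest.raises(ValueError, match="segment"):
            truncate(obs, "one_and_half")

    def test_unknown_mode(self):
        obs = self._obs([(1, 100)])
        with pytest.raises(ValueError, match="mode"):
            truncate(obs, "quarter")


class TestFit:
    def test_requires_observations(self, feasible_params):
        sched = TreatmentSchedule.all_on(10)
        obs = ObservationSeries(np.array([], dtype=int), np.array([]), sched)
        with pytest.raises(ValueError, match="observation"):
            PsaTimeCourseModel(obs)

    def test_bounds_excluding_feasible_region_rejected(self, feasible_params):
        obs = series_from(feasible_params)
        bad = list(default_bounds(obs))
        bad[8] = (0.7, 0.95)  # d33_on >= 1 impossible
        with pytest.raises(ValueError, match="d33_on"):
            PsaTimeCourseModel(obs, config=F.FitConfig(bounds=tuple(bad)))

    def test_seeded_determinism(self, feasible_params, tiny_fit_config):
        obs = series_from(feasible_params)
        r1 = PsaTimeCourseModel(obs, config=tiny_fit_config).fit()
        r2 = PsaTimeCourseModel(obs, config=tiny_fit_config).fit()
        assert np.array_equal(r1.params.to_array(), r2.params.to_array())
        assert r1.cost == r2.cost

    def test_cost_decomposition_and_summary(self, feasible_params,
                                            tiny_fit_config):
        obs = series_from(feasible_params)
        res = PsaTimeCourseModel(obs, config=tiny_fit_config).fit()
        assert res.cost == pytest.approx(
            res.sse_term + res.prior_term + res.q_value, rel=1e-12)
        assert res.prior_term == 0.0
        assert res.evaluations > 0
        text = res.summary()
        assert "prior-free" in text and "d33_on" in text

    def test_fit_never_worse_than_prior_mean(self, feasible_params,
                                             tiny_fit_config):
        """With the prior mean injected, the optimum dominates it."""
        obs = series_from(feasible_params)
        rng = np.random.default_rng(1)
        cohort = [feasible_params.to_array() * rng.uniform(0.98, 1.02, 13)
                  for _ in range(20)]
        prior = build_prior(cohort)
        cfg = replace(tiny_fit_config, use_prior=True)
        res = PsaTimeCourseModel(obs, prior=prior, config=cfg).fit()
        at_mean = objective(prior.mean, obs, prior, cfg)
        assert res.cost <= at_mean + 1e-9

    def test_tight_prior_pins_estimate_to_its_mean(self, feasible_params,
                                                   tiny_fit_config):
        """As the prior covariance shrinks the MAP estimate goes to p-bar."""
        obs = series_from(feasible_params)
        mean = feasible_params.to_array()
        prior = F.PriorModel(mean=mean, covariance=1e-10 * np.eye(13),
                             ridge=0.0, n_cohort=10)
        cfg = replace(tiny_fit_config, use_prior=True)
        res = PsaTimeCourseModel(obs, prior=prior, config=cfg).fit()
        assert np.allclose(res.params.to_array(), mean, atol=1e-4)

    def test_noiseless_recovery_single_patient(self, feasible_params):
        """A moderate budget recovers a noiseless record almost exactly."""
        obs = F.generate_patient(feasible_params, noise_sd=0.0, seed=4)
        cfg = F.FitConfig(use_prior=False, de_maxiter=600, n_restarts=2,
                          seed=11)
        res = PsaTimeCourseModel(obs, config=cfg).fit()
        assert res.feasible
        assert res.rmse <= 0.1
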