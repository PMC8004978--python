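"""Quadratic weight-trajectory posteriors and responder classification."""

import numpy as np
import pytest

from chronofood.synthetic_data import generate_weight_series
from chronofood.weight_trajectory import (
    TrajectoryPosterior,
    WeightSeries,
    fit_quadratic_weight,
    percent_weight_change,
    weight_change_posterior,
)


def series_from(a, b, c, sigma=0.0, t=(0.0, 0.0, 2.0, 4.0, 6.0), seed=0, pid="P0"):
    return generate_weight_series(a, b, c, sigma, visit_times=t, seed=seed, participant_id=pid)


class TestFit:
    def test_noiseless_series_recovered(self):
        tp = fit_quadratic_weight(series_from(80.0, -0.5, 0.0), seed=1)
        assert np.median(tp.flat("a")) == pytest.approx(80.0, abs=0.05)
        assert np.median(tp.flat("b")) == pytest.approx(-0.5, abs=0.05)
        assert np.median(tp.flat("c")) == pytest.approx(0.0, abs=0.05)

    def test_noiseless_quadratic_recovered(self):
        tp = fit_quadratic_weight(series_from(75.0, -0.8, 0.05), seed=2)
        assert np.median(tp.flat("b")) == pytest.approx(-0.8, abs=0.05)
        assert np.median(tp.flat("c")) == pytest.approx(0.05, abs=0.05)

    def test_constant_series_null_slopes(self):
        tp = fit_quadratic_weight(series_from(80.0, 0.0, 0.0, sigma=0.0), seed=3)
        assert np.median(tp.flat("b")) == pytest.approx(0.0, abs=0.02)
        assert np.median(tp.flat("c")) == pytest.approx(0.0, abs=0.02)

    def test_requires_three_observations(self):
        with pytest.raises(ValueError):
            fit_quadratic_weight(
                WeightSeries("P0", t=np.array([0.0, 6.0]), weights=np.array([80.0, 78.0]))
            )

    def test_duplicate_baseline_tightens_intercept(self):
        """Using both t=0 weights must narrow the posterior of the starting
        weight compared to a single baseline, on matched seeds."""
        full = series_from(80.0, -0.3, 0.0, sigma=0.5, seed=4)
        reduced = WeightSeries("P0", t=full.t[1:], weights=full.weights[1:])
        sd_full = fit_quadratic_weight(full, seed=5).flat("a").std()
        sd_reduced = fit_quadratic_weight(reduced, seed=5).flat("a").std()
        assert sd_full < sd_reduced

    def test_percentiles_monotone(self):
        tp = fit_quadratic_weight(series_from(80.0, -0.2, 0.01, sigma=0.5, seed=6), seed=6)
        summ = weight_change_posterior(tp)
        vals = [summ.percentiles[p] for p in sorted(summ.percentiles)]
        assert all(x <= y for x, y in zip(vals, vals[1:]))


class TestChangePosterior:
    @staticmethod
    def _constant_posterior(a, b, c):
        shape = (4, 100)
        return TrajectoryPosterior(
            participant_id="P0",
            a=np.full(shape, a),
            b=np.full(shape, b),
            c=np.full(shape, c),
            sigma=np.full(shape, 0.1),
            rhat=np.ones(3),
        )

    def test_point_mass_arithmetic(self):
        """b=-0.5, c=0, a=80 over 6 months: change is exactly -3.75%."""
        tp = self._constant_posterior(80.0, -0.5, 0.0)
        summ = weight_change_posterior(tp)
        assert summ.percentiles[50] == pytest.approx(-3.75)
        assert summ.significant and summ.direction == -1

    def test_symmetric_draws_not_significant(self):
        rng = np.random.default_rng(7)
        shape = (4, 1000)
        tp = TrajectoryPosterior(
            "P0",
            a=np.full(shape, 80.0),
            b=rng.normal(0.0, 0.2, shape),
            c=np.zeros(shape),
            sigma=np.full(shape, 0.5),
            rhat=np.ones(3),
        )
        summ = weight_change_posterior(tp)
        assert not summ.significant and summ.direction == 0

    def test_kg_scale_option(self):
        tp = self._constant_posterior(80.0, -0.5, 0.0)
        summ = weight_change_posterior(tp, percent=False)
        assert summ.percentiles[50] == pytest.approx(-3.0)


class TestCalibration:
    def test_self_consistent_simulation_recovers_nominal_coverage(self):
        """When every parameter (a, b, c and sigma_eps) is drawn from the
        model's own priors, 90% central intervals for the 6-month change must
        cover the truth at the nominal rate — the strict simulation-based
        calibration property of an exactly sampled posterior."""
        rng = np.random.default_rng(2)
        ss = np.random.SeedSequence(2).spawn(400)
        covered = n = 0
        times = np.array([0.0, 0.0, 2.0, 4.0, 6.0])
        for s in ss:
            a = rng.normal(80.0, 10.0)
            b, c = rng.normal(0.0, 10.0, 2)
            sigma = abs(rng.normal(0.0, 10.0))
            w = a + b * times + c * times**2 + sigma * rng.standard_normal(5)
            if a < 40 or np.any(w <= 0):
                continue
            truth = 100.0 * (b * 6 + c * 36) / a
            series = WeightSeries("P0", t=times, weights=w)
            tp = fit_quadratic_weight(
                series, seed=int(s.generate_state(1)[0] % 2**31), prior_center_a=80.0
            )
            summ = weight_change_posterior(tp)
            covered += summ.percentiles[5] <= truth <= summ.percentiles[95]
            n += 1
        assert n > 150
        assert 0.85 <= covered / n <= 0.95

    def test_low_noise_series_never_undercover(self):
        """With the measurement noise fixed well below the prior scale
        (0.5 kg vs half-normal(10)), the five-point design leaves only two
        residual degrees of freedom, so the inferred noise scale — and hence
        the change interval — is conservative: coverage sits at or above the
        nominal 90%, never below."""
        rng = np.random.default_rng(8)
        ss = np.random.SeedSequence(8).spawn(120)
        covered = 0
        for s in ss:
            a = max(45.0, rng.normal(80.0, 10.0))
            b = rng.normal(-0.1, 0.25)
            c = rng.normal(0.0, 0.02)
            truth = 100.0 * (b * 6 + c * 36) / a
            series = generate_weight_series(a, b, c, 0.5, seed=s)
            tp = fit_quadratic_weight(series, seed=int(s.generate_state(1)[0] % 2**31))
            summ = weight_change_posterior(tp)
            covered += summ.percentiles[5] <= truth <= summ.percentiles[95]
        assert covered / 120 >= 0.85

    def test_responder_counting_recovers_truth(self):
        """A 25-participant arm with 9 planted losers and 2 gainers."""
        ss = np.random.SeedSequence(9).spawn(25)
        slopes = [-1.0] * 9 + [0.9] * 2 + [0.0] * 14
        lost = gained = 0
        for slope, s in zip(slopes, ss):
            series = generate_weight_series(80.0, slope, 0.0, 0.5, seed=s)
            tp = fit_quadratic_weight(series, seed=int(s.generate_state(1)[0] % 2**31))
            summ = weight_change_posterior(tp)
            lost += summ.significant and summ.direction < 0
            gained += summ.significant and summ.direction > 0
        assert abs(lost - 9) <= 2
        assert abs(gained - 2) <= 2


class TestPercentChange:
    def test_known_values(self):
        assert percent_weight_change(80.0, 78.72) == pytest.approx(-1.6)
        assert percent_weight_change(80.0, 80.0) == 0.0

    def test_antisymmetry_of_absolute_change(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            pre, post = rng.uniform(50, 120, 2)
            up = percent_weight_change(pre, post)
            down = percent_weight_change(pre, 2 * pre - post)
            assert up == pytest.approx(-down)

    def test_non_positive_pre_rejected(self):
        with pytest.raises(ValueError):
            percent_weight_change(0.0, 70.0)
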