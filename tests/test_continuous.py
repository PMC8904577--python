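"""Bivariate-normal trait conversion: truncated moments, quantile tables, intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, truncnorm

from pgsabs import (
    ContinuousTraitModel,
    individual_trait,
    trait_by_quantile,
    trait_moments_interval,
    truncated_std_normal_moments,
)
from pgsabs.errors import DegenerateIntervalError, DomainError


class TestTruncatedMoments:
    def test_no_truncation(self):
        m, v = truncated_std_normal_moments(-np.inf, np.inf)
        assert m == pytest.approx(0.0, abs=1e-14)
        assert v == pytest.approx(1.0, abs=1e-14)

    def test_lower_tail_frozen_value(self):
        # E[X | X < -1.6449] = -phi(1.6449)/Phi(-1.6449) = -2.0627
        m, v = truncated_std_normal_moments(-np.inf, -1.6449)
        assert m == pytest.approx(-2.0627, abs=2e-4)
        assert 0 < v < 1

    @given(st.floats(0.1, 4.0))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_interval_has_zero_mean(self, c):
        m, v = truncated_std_normal_moments(-c, c)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert 0 < v < 1

    @pytest.mark.parametrize(
        "a, b",
        [(-np.inf, -1.0), (-0.5, 0.75), (1.0, np.inf), (2.0, 2.1), (-np.inf, np.inf)],
    )
    def test_matches_scipy_truncnorm(self, a, b):
        """Closed form agrees with scipy's independent truncnorm implementation."""
        m, v = truncated_std_normal_moments(a, b)
        m_ref, v_ref = truncnorm.stats(a, b, moments="mv")
        assert m == pytest.approx(float(m_ref), abs=1e-9)
        assert v == pytest.approx(float(v_ref), abs=1e-9)

    def test_matches_rejection_sampling(self, rng):
        a, b = -np.inf, -1.6449
        x = rng.standard_normal(10_000_000)
        x = x[x < b]
        m, v = truncated_std_normal_moments(a, b)
        assert x.mean() == pytest.approx(m, abs=3 * x.std() / np.sqrt(len(x)))
        assert x.var() == pytest.approx(v, rel=0.01)

    def test_degenerate_intervals_raise(self):
        with pytest.raises(DomainError):
            truncated_std_normal_moments(1.0, 1.0)
        with pytest.raises(DegenerateIntervalError):
            truncated_std_normal_moments(40.0, 41.0)

    def test_mean_lies_inside_interval(self):
        for a, b in [(-2, -1), (0.3, 0.4), (3, np.inf)]:
            m, _ = truncated_std_normal_moments(a, b)
            assert a < m < b if np.isfinite(b) else m > a


class TestTraitMoments:
    def test_whole_line_returns_population_moments(self, iq_model):
        mean, sd = trait_moments_interval(iq_model, -np.inf, np.inf)
        assert mean == pytest.approx(100.0, abs=1e-10)
        assert sd == pytest.approx(15.0, abs=1e-10)

    def test_uninformative_score_returns_population_moments(self):
        m = ContinuousTraitModel(trait_mean=50.0, trait_sd=8.0, r2=0.0)
        for a, b in [(-1, 1), (2, np.inf)]:
            mean, sd = trait_moments_interval(m, a, b)
            assert (mean, sd) == (pytest.approx(50.0), pytest.approx(8.0))

    def test_iq_worked_example_cell_mean(self, iq_model):
        """The 2.5th-percentile cell of a 1000-cell partition has mean IQ ~90.7."""
        a, b = norm.ppf(0.024), norm.ppf(0.025)
        mean, sd = trait_moments_interval(iq_model, a, b)
        assert round(mean, 1) == 90.7
        assert sd == pytest.approx(15 * math.sqrt(0.9), abs=0.01)

    def test_conditional_sd_floor(self, iq_model):
        floor = 15 * math.sqrt(1 - 0.10)
        for a, b in [(-np.inf, -2), (-0.1, 0.1), (1, 3)]:
            _, sd = trait_moments_interval(iq_model, a, b)
            assert floor - 1e-12 <= sd <= 15.0


class TestTraitByQuantile:
    def test_null_r2_table_is_flat(self):
        m = ContinuousTraitModel(trait_mean=100.0, trait_sd=15.0, r2=0.0)
        t = trait_by_quantile(m, 20)
        assert np.allclose(t.trait_mean, 100.0)
        assert np.allclose(t.trait_sd, 15.0)

    @pytest.mark.parametrize(
        "mu, sigma, r2, n",
        [(100, 15, 0.10, 20), (0, 1, 0.5, 10), (170, 8, 0.25, 100), (100, 15, 0.10, 1000)],
    )
    def test_laws_of_total_expectation_and_variance(self, mu, sigma, r2, n):
        """Per-quantile moments reassemble the population mean and variance."""
        t = trait_by_quantile(ContinuousTraitModel(trait_mean=mu, trait_sd=sigma, r2=r2), n)
        assert t.trait_mean.mean() == pytest.approx(mu, abs=1e-6)
        total_var = np.mean(t.trait_sd**2) + np.mean((t.trait_mean - mu) ** 2)
        assert total_var == pytest.approx(sigma**2, rel=1e-4)

    def test_means_strictly_increasing_when_informative(self, iq_model):
        t = trait_by_quantile(iq_model, 20)
        assert np.all(np.diff(t.trait_mean) > 0)

    def test_matches_bivariate_monte_carlo(self, iq_model):
        rng = np.random.default_rng(23)
        n = 10_000_000
        z = rng.standard_normal(n)
        y = 100 + 15 * (math.sqrt(0.10) * z + math.sqrt(0.90) * rng.standard_normal(n))
        t = trait_by_quantile(iq_model, 20)
        bins = np.searchsorted(t.partition.boundaries[1:-1], z, side="left")
        for i in range(0, 20, 4):
            sel = bins == i
            m_obs, sd_obs = y[sel].mean(), y[sel].std(ddof=1)
            se = t.trait_sd[i] / np.sqrt(sel.sum())
            assert m_obs == pytest.approx(t.trait_mean[i], abs=3 * se)
            assert sd_obs == pytest.approx(t.trait_sd[i], rel=0.005)

    def test_discretization_tracks_point_conditional(self, iq_model):
        """At 1000 cells, per-cell means sit within 0.1% of sigma of mu+rho*sigma*z_mid."""
        t = trait_by_quantile(iq_model, 1000)
        mids = norm.ppf((np.arange(1000) + 0.5) / 1000)
        point = 100 + math.sqrt(0.10) * 15 * mids
        diff = np.abs(t.trait_mean - point)
        # interior cells are essentially exact; the outermost cells inside
        # |z|<=3 widen enough that the truncated mean drifts to ~0.2% of sigma
        assert np.max(diff[np.abs(mids) <= 2.5]) < 0.001 * 15
        assert np.max(diff[np.abs(mids) <= 3.0]) < 0.002 * 15

    def test_stratified_models_share_the_code_path(self):
        """Stratum-specific (mu, sigma, r2) is pure re-parameterization."""
        male = trait_by_quantile(ContinuousTraitModel(175.0, 7.0, r2=0.4), 20)
        female = trait_by_quantile(ContinuousTraitModel(162.0, 6.5, r2=0.4), 20)
        # same standardized partition, moments shifted/scaled per stratum
        assert np.allclose(male.partition.boundaries, female.partition.boundaries)
        z_m = (male.trait_mean - 175.0) / 7.0
        z_f = (female.trait_mean - 162.0) / 6.5
        assert np.allclose(z_m, z_f, atol=1e-12)


class TestIndividualTrait:
    def test_iq_worked_example(self, iq_model):
        """z=-1.96: 2.5th percentile, mean IQ 90.7, 95% PI (62.8, 118.6)."""
        res = individual_trait(iq_model, -1.96)
        assert round(res.percentile, 1) == 2.5
        assert round(res.predicted_mean, 1) == 90.7
        lo, hi = res.prediction_interval
        assert (round(lo, 1), round(hi, 1)) == (62.8, 118.6)

    def test_interval_symmetric_with_stated_width(self, iq_model):
        res = individual_trait(iq_model, 1.3, level=0.8)
        lo, hi = res.prediction_interval
        assert (lo + hi) / 2 == pytest.approx(res.predicted_mean, abs=1e-10)
        assert hi - lo == pytest.approx(2 * norm.ppf(0.9) * res.predicted_sd, abs=1e-10)

    def test_null_r2_gives_population_interval(self):
        m = ContinuousTraitModel(trait_mean=100.0, trait_sd=15.0, r2=0.0)
        res = individual_trait(m, 2.7)
        assert res.predicted_mean == pytest.approx(100.0)
        assert res.prediction_interval[1] == pytest.approx(100 + norm.ppf(0.975) * 15, abs=1e-9)

    def test_cell_conditional_close_to_point_conditional(self):
        m = ContinuousTraitModel(trait_mean=0.0, trait_sd=1.0, r2=0.25)
        cell = individual_trait(m, 2.0, conditional="cell")
        point = individual_trait(m, 2.0, conditional="point")
        assert point.predicted_mean == pytest.approx(0.5 * 2.0, abs=1e-12)
        assert point.predicted_sd == pytest.approx(math.sqrt(0.75), abs=1e-12)
        assert cell.predicted_mean == pytest.approx(point.predicted_mean, abs=0.01)
        assert cell.predicted_sd == pytest.approx(point.predicted_sd, abs=0.01)

    def test_negative_orientation_flips_the_gradient(self):
        m = ContinuousTraitModel(trait_mean=100.0, trait_sd=15.0, r2=0.10,
                                 rho=-math.sqrt(0.10))
        res = individual_trait(m, -1.96)
        assert res.predicted_mean > 100.0

    @pytest.mark.parametrize("bad", [dict(z=np.inf), dict(z=0.0, level=1.0),
                                     dict(z=0.0, conditional="banana")])
    def test_invalid_arguments_rejected(self, iq_model, bad):
        with pytest.raises(DomainError):
            individual_trait(iq_model, **bad)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(DomainError):
            ContinuousTraitModel(trait_mean=0.0, trait_sd=-1.0, r2=0.1)
        with pytest.raises(DomainError):
            ContinuousTraitModel(trait_mean=0.0, trait_sd=1.0, r2=1.5)
        with pytest.raises(DomainError):
            ContinuousTraitModel(trait_mean=0.0, trait_sd=1.0, r2=0.1, rho=0.9)
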