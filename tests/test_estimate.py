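import numpy as np
import pytest

from labri.errors import DegenerateDataError, EstimationError
from labri.estimate import (
    EstimatorSettings,
    build_histogram,
    bootstrap_ci,
    estimate_ri,
    fit_central_model,
    fit_truncated_normal,
)
from labri.prep import quantile

Z = 1.959964


def lognormal(n, seed, mu=0.2, sigma=0.45):
    return np.exp(mu + sigma * np.random.default_rng(seed).standard_normal(n))


def contaminated(n, seed, healthy=0.85):
    """healthy lognormal(0.2, 0.45) plus equal low/high lognormal tails."""
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    z = rng.standard_normal(n)
    tail = (1 - healthy) / 2
    return np.where(
        u < healthy,
        np.exp(0.2 + 0.45 * z),
        np.where(u < healthy + tail, np.exp(-2.3 + 0.5 * z), np.exp(2.6 + 0.5 * z)),
    )


class TestEstimatorSettings:
    def test_defaults_match_published_configuration(self):
        s = EstimatorSettings()
        assert s.central_coverage == 0.95
        assert s.ci_level == 0.90
        assert s.bootstrap_reps == 250

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"central_coverage": 1.0},
            {"ci_level": 0.0},
            {"bootstrap_reps": 0},
            {"lambda_grid": ()},
            {"hist_min_bins": 300},
        ],
    )
    def test_invalid_settings(self, kwargs):
        with pytest.raises(ValueError):
            EstimatorSettings(**kwargs)


class TestBuildHistogram:
    def test_freedman_diaconis_width(self):
        # independent oracle: numpy percentiles + the published width rule
        arr = lognormal(5000, 1)
        edges, counts = build_histogram(arr)
        iqr = float(np.percentile(arr, 75) - np.percentile(arr, 25))
        h = 2 * iqr * arr.size ** (-1 / 3)
        expected = int(np.clip(np.ceil((arr.max() - arr.min()) / h), 30, 200))
        assert len(counts) == expected
        assert edges[0] == arr.min() and edges[-1] == arr.max()

    def test_counts_conserved(self):
        arr = lognormal(2048, 2)
        _, counts = build_histogram(arr)
        assert counts.sum() == arr.size

    def test_bin_count_clamped(self):
        # few distinct narrow values -> would want < 30 bins; clamp kicks in
        arr = np.random.default_rng(0).uniform(0, 1, 100)
        edges, counts = build_histogram(arr)
        assert 30 <= len(counts) <= 200

    def test_constant_vector(self):
        with pytest.raises(DegenerateDataError):
            build_histogram(np.ones(100))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            build_histogram(np.arange(10.0))


class TestFitTruncatedNormal:
    def test_unbounded_window_closed_form(self):
        mu, sigma = fit_truncated_normal(np.array([0.0, 2.0]), (-np.inf, np.inf))
        assert (mu, sigma) == pytest.approx((1.0, 1.0))

    def test_monte_carlo_recovery(self):
        # N(10,1) truncated to (9, 11); generating-parameter oracle
        y = 10 + np.random.default_rng(1).standard_normal(50_000)
        mu, sigma = fit_truncated_normal(y, (9.0, 11.0))
        assert mu == pytest.approx(10.0, abs=0.02)
        assert sigma == pytest.approx(1.0, abs=0.03)

    def test_window_excludes_data(self):
        y = 10 + np.random.default_rng(1).standard_normal(1000)
        with pytest.raises(ValueError):
            fit_truncated_normal(y, (100.0, 101.0))

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            fit_truncated_normal(np.arange(100.0), (5.0, 5.0))


class TestFitCentralModel:
    def test_lognormal_selects_log_transform(self):
        m = fit_central_model(lognormal(50_000, 3))
        assert m.lambda_hat == 0.0

    def test_shifted_normal_location_recovery(self):
        x = 14 + 2 * np.random.default_rng(2).standard_normal(50_000)
        m = fit_central_model(x)
        assert m.lambda_hat == 1.0
        assert m.mu_hat == pytest.approx(13.0, abs=0.05)  # transformed scale: x - 1

    def test_contamination_nonpath_fraction(self):
        m = fit_central_model(contaminated(50_000, 4))
        assert 0.75 <= m.nonpath_fraction_hat <= 0.95

    def test_small_subgroup_warns(self):
        with pytest.warns(UserWarning, match="below"):
            fit_central_model(lognormal(300, 5))

    def test_tiny_subgroup_fails(self):
        with pytest.raises(EstimationError):
            fit_central_model(lognormal(20, 5))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_central_model(np.linspace(-1, 1, 1000))


class TestEstimateRI:
    def test_pure_normal_limits(self):
        x = 10 + np.random.default_rng(1).standard_normal(50_000)
        ri = estimate_ri(x)
        assert ri.ll == pytest.approx(10 - Z, abs=0.1)
        assert ri.ul == pytest.approx(10 + Z, abs=0.1)

    def test_pure_lognormal_limits(self):
        ri = estimate_ri(lognormal(50_000, 6))
        assert ri.ll == pytest.approx(np.exp(0.2 - Z * 0.45), rel=0.03)
        assert ri.ul == pytest.approx(np.exp(0.2 + Z * 0.45), rel=0.03)

    def test_matches_direct_percentiles_when_uncontaminated(self):
        x = lognormal(50_000, 7)
        ri = estimate_ri(x)
        assert ri.ll == pytest.approx(np.percentile(x, 2.5), rel=0.03)
        assert ri.ul == pytest.approx(np.percentile(x, 97.5), rel=0.03)

    def test_contaminated_recovery_within_five_percent(self):
        # median over 10 seeds at n=20,000 with 15% contamination
        ll_t, ul_t = np.exp(0.2 - Z * 0.45), np.exp(0.2 + Z * 0.45)
        errs_ll, errs_ul = [], []
        for seed in range(1, 11):
            ri = estimate_ri(contaminated(20_000, seed))
            errs_ll.append(abs(ri.ll - ll_t) / ll_t)
            errs_ul.append(abs(ri.ul - ul_t) / ul_t)
        assert np.median(errs_ll) < 0.05
        assert np.median(errs_ul) < 0.05

    def test_constant_input(self):
        with pytest.raises((DegenerateDataError, EstimationError)):
            estimate_ri(np.full(1000, 3.5))

    def test_scale_equivariance_log_transform(self):
        s = EstimatorSettings(lambda_grid=(0.0,))
        x = lognormal(20_000, 8)
        base = estimate_ri(x, s)
        scaled = estimate_ri(3.0 * x, s)
        assert scaled.ll == pytest.approx(3.0 * base.ll, rel=1e-6)
        assert scaled.ul == pytest.approx(3.0 * base.ul, rel=1e-6)

    def test_wider_coverage_widens_limits(self):
        x = lognormal(20_000, 9)
        narrow = estimate_ri(x, EstimatorSettings(lambda_grid=(0.0,), central_coverage=0.90))
        wide = estimate_ri(x, EstimatorSettings(lambda_grid=(0.0,), central_coverage=0.99))
        assert wide.ll < narrow.ll < narrow.ul < wide.ul


class TestBootstrapCI:
    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            EstimatorSettings(bootstrap_reps=0)

    def test_deterministic_under_seed(self):
        x = lognormal(2000, 10)
        s = EstimatorSettings(bootstrap_reps=25, seed=99)
        a = bootstrap_ci(x, s)
        b = bootstrap_ci(x, s)
        assert a.ll_ci == b.ll_ci and a.ul_ci == b.ul_ci
        np.testing.assert_array_equal(a.bootstrap_ul, b.bootstrap_ul)

    def test_cis_contain_point_estimates(self):
        x = lognormal(5000, 11)
        ri = bootstrap_ci(x, EstimatorSettings(bootstrap_reps=250, seed=1))
        assert ri.ll_ci[0] <= ri.ll <= ri.ll_ci[1]
        assert ri.ul_ci[0] <= ri.ul <= ri.ul_ci[1]

    def test_ci_quantiles_match_recorded_replicates(self):
        x = lognormal(2000, 12)
        s = EstimatorSettings(bootstrap_reps=40, seed=5)
        ri = bootstrap_ci(x, s)
        assert ri.ul_ci[0] == pytest.approx(quantile(ri.bootstrap_ul, 0.05))
        assert ri.ul_ci[1] == pytest.approx(quantile(ri.bootstrap_ul, 0.95))
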