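import numpy as np
import pandas as pd
import pytest
from scipy import stats

from whaletrack import calibrate as cal
from whaletrack.geoframe import LocalFrame, local_to_geodetic

REF = cal.reference_gps_error_model()


class TestResidualFilter:
    def test_strict_threshold(self):
        df = pd.DataFrame({"residual": [10.0, 31.0, 30.0]})
        out = cal.filter_by_residual(df)
        assert out["residual"].tolist() == [10.0, 30.0]

    def test_identity_when_all_pass(self):
        df = pd.DataFrame({"residual": np.linspace(0, 30, 20)})
        assert len(cal.filter_by_residual(df)) == 20

    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(0)
        res = rng.uniform(0, 60, size=1000)
        df = pd.DataFrame({"residual": res})
        expected = sum(1 for r in res if r <= 30)
        assert len(cal.filter_by_residual(df)) == expected


class TestSatelliteBin:
    @pytest.mark.parametrize("nsat,q", [(4, 1), (5, 2), (6, 3), (7, 4), (8, 5),
                                        (9, 6), (12, 6)])
    def test_mapping(self, nsat, q):
        assert cal.satellite_bin(nsat) == q

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            cal.satellite_bin(3)


class TestPositionalErrors:
    def _records(self, lat, lon, nsat, logger="A"):
        return pd.DataFrame({"lat": lat, "lon": lon, "nsat": nsat,
                             "residual": 0.0, "logger_id": logger})

    def test_median_residuals(self):
        frame = LocalFrame(70.0, 19.0)
        lat, lon = local_to_geodetic(np.array([0.0, 10.0, 40.0]), np.zeros(3), frame)
        out = cal.positional_errors(self._records(lat, lon, 6), frame)
        assert np.allclose(np.sort(out["ex"]), [-10.0, 0.0, 30.0], atol=1e-6)

    def test_symmetric_cloud_centres_at_zero(self):
        frame = LocalFrame(70.0, 19.0)
        x = np.concatenate([np.arange(1, 51), -np.arange(1, 51)])
        lat, lon = local_to_geodetic(x, -x, frame)
        out = cal.positional_errors(self._records(lat, lon, 7), frame)
        assert np.median(out["ex"]) == pytest.approx(0.0, abs=1e-6)
        assert np.median(out["ey"]) == pytest.approx(0.0, abs=1e-6)

    def test_recovers_injected_noise(self):
        # simulation oracle: t noise around a fixed point comes back as the
        # error sample (up to the median re-centering)
        rng = np.random.default_rng(1)
        frame = LocalFrame(70.0, 19.0)
        noise = stats.t.rvs(df=3, scale=15.0, size=10_000, random_state=rng)
        lat, lon = local_to_geodetic(noise, np.zeros_like(noise), frame)
        out = cal.positional_errors(self._records(lat, lon, 8), frame)
        shift = np.median(noise)
        assert np.allclose(np.sort(out["ex"]), np.sort(noise - shift), atol=1e-5)

    def test_single_record_logger_dropped(self):
        frame = LocalFrame(70.0, 19.0)
        df = pd.DataFrame({"lat": [70.0, 70.0, 70.0], "lon": [19.0, 19.0, 19.0],
                           "nsat": 6, "residual": 0.0,
                           "logger_id": ["A", "A", "B"]})
        with pytest.warns(UserWarning, match="single-observation"):
            out = cal.positional_errors(df, frame)
        assert set(out["logger_id"]) == {"A"}


class TestScaledTFit:
    def test_recovery_at_calibration_truth(self):
        # 4-satellite x-dimension parameters as simulation truth
        rng = np.random.default_rng(2)
        x = stats.t.rvs(df=0.93, loc=0.57, scale=24.51, size=10_000, random_state=rng)
        fit = cal.fit_scaled_t(x, seed=0)
        assert abs(fit.sigma - 24.51) < 3 * max(fit.se_sigma, 0.68)
        assert abs(fit.nu - 0.93) < 3 * max(fit.se_nu, 0.90)

    def test_symmetric_sample_centred(self):
        rng = np.random.default_rng(3)
        half = stats.t.rvs(df=4, scale=5.0, size=500, random_state=rng)
        fit = cal.fit_scaled_t(np.concatenate([half, -half]), seed=0)
        assert abs(fit.mu) < 0.05

    def test_normal_sample_large_nu_and_grid_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5000)
        fit = cal.fit_scaled_t(x, seed=0)
        assert fit.sigma == pytest.approx(1.0, abs=0.05)
        assert fit.nu > 20
        # the MLE log-likelihood beats every point of a (sigma, nu) grid
        grid_best = -np.inf
        for s in np.linspace(0.8, 1.2, 50):
            for nu in np.geomspace(0.5, 100, 50):
                ll = stats.t.logpdf(x, df=nu, loc=fit.mu, scale=s).sum()
                grid_best = max(grid_best, ll)
        assert fit.loglik >= grid_best - 1e-6

    def test_matches_scipy_fit(self):
        rng = np.random.default_rng(5)
        x = stats.t.rvs(df=3.0, loc=1.0, scale=10.0, size=4000, random_state=rng)
        fit = cal.fit_scaled_t(x, seed=0)
        df_s, loc_s, scale_s = stats.t.fit(x)
        assert fit.nu == pytest.approx(df_s, rel=0.02)
        assert fit.sigma == pytest.approx(scale_s, rel=0.01)
        assert fit.mu == pytest.approx(loc_s, abs=0.1)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        x = stats.t.rvs(df=2.5, scale=7.0, size=2000, random_state=rng)
        f1 = cal.fit_scaled_t(x, seed=1)
        f2 = cal.fit_scaled_t(10.0 * x, seed=1)
        assert f2.sigma == pytest.approx(10.0 * f1.sigma, rel=1e-4)
        assert f2.nu == pytest.approx(f1.nu, rel=1e-4)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cal.fit_scaled_t(np.ones(10))


class TestCalibrationRecoveryProperty:
    def test_x_dimension_recovery_within_three_se(self, gps_model):
        """Simulating each satellite bin at its test sample size, the MLEs
        land within +/-3 SE of truth in >=95 % of seeded replicates."""
        n_rep = 50
        hits = 0
        total = 0
        for qi in range(6):
            sig, nu = gps_model.sigma["x"][qi], gps_model.nu["x"][qi]
            se_s = gps_model.se["sigma_x"][qi]
            se_n = gps_model.se["nu_x"][qi]
            n = int(cal.REFERENCE_GPS_BIN_COUNTS[qi])
            for rep in range(n_rep):
                rng = np.random.default_rng(1000 * qi + rep)
                x = stats.t.rvs(df=nu, scale=sig, size=n, random_state=rng)
                fit = cal.fit_scaled_t(x, n_restarts=1, seed=rep)
                total += 1
                se_s_eff = max(se_s, fit.se_sigma)
                se_n_eff = max(se_n, fit.se_nu)
                if (abs(fit.sigma - sig) < 3 * se_s_eff
                        and abs(fit.nu - nu) < 3 * se_n_eff):
                    hits += 1
        assert hits / total >= 0.95

    def test_monotone_accuracy_across_bins(self, gps_model):
        """Refitting per-bin simulations reproduces the qualitative pattern:
        scale decreasing and tail weight decreasing with more satellites."""
        rng = np.random.default_rng(7)
        sigmas, nus = [], []
        for qi in range(6):
            x = stats.t.rvs(df=gps_model.nu["x"][qi], scale=gps_model.sigma["x"][qi],
                            size=4000, random_state=rng)
            fit = cal.fit_scaled_t(x, seed=0)
            sigmas.append(fit.sigma)
            nus.append(fit.nu)
        assert np.all(np.diff(sigmas) < 0)
        assert np.all(np.diff(nus) > 0)


class TestWrappedCauchy:
    def test_recovery_at_calibration_truth(self):
        rng = np.random.default_rng(8)
        ang = np.degrees(stats.wrapcauchy.rvs(0.897, size=5000, random_state=rng))
        mu, rho = cal.fit_wrapped_cauchy(ang)
        assert rho == pytest.approx(0.897, abs=0.01)
        assert abs(mu) < 1.0

    def test_uniform_angles_give_zero_concentration(self):
        rng = np.random.default_rng(9)
        mu, rho = cal.fit_wrapped_cauchy(rng.uniform(-180, 180, size=2000))
        assert rho < 0.05

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(10)
        ang = np.degrees(stats.wrapcauchy.rvs(0.7, size=1000, random_state=rng))
        mu1, rho1 = cal.fit_wrapped_cauchy(ang)
        mu2, rho2 = cal.fit_wrapped_cauchy(ang + 37.0)
        from whaletrack.geoframe import wrap_angle
        assert wrap_angle(mu2 - mu1) == pytest.approx(37.0, abs=1e-3)
        assert rho2 == pytest.approx(rho1, abs=1e-6)

    def test_density_matches_scipy(self):
        theta = np.linspace(-3, 3, 25)
        ours = cal.wrapped_cauchy_logpdf(theta, 0.3, 0.6)
        ref = stats.wrapcauchy.logpdf(np.mod(theta - 0.3, 2 * np.pi), 0.6)
        assert np.allclose(ours, ref, atol=1e-10)


class TestRangePercentError:
    def test_exact_estimates(self):
        truth = np.linspace(50, 500, 40)
        fit = cal.fit_range_percent_error(truth, truth)
        assert (fit.mu, fit.sigma, fit.slope) == (0.0, 0.0, 0.0)

    def test_constant_doubling(self):
        truth = np.linspace(50, 500, 40)
        fit = cal.fit_range_percent_error(2 * truth, truth)
        assert fit.mu == pytest.approx(100.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-9)

    def test_recovery_at_calibration_truth(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(50, 1000, size=5000)
        e = rng.normal(-2.95, 30.2, size=5000)
        fit = cal.fit_range_percent_error(truth * (1 + e / 100.0), truth)
        assert abs(fit.mu - (-2.95)) < 3 * 30.2 / np.sqrt(5000)
        assert abs(fit.sigma - 30.2) < 3 * 30.2 / np.sqrt(2 * 5000)
        assert fit.slope_p > 0.001  # no genuine range dependence injected

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            cal.fit_range_percent_error([10.0, 10.0], [5.0, 0.0])


class TestKsGof:
    def test_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=200)
        dist = stats.norm(0, 1)
        d, p = cal.ks_gof(x, dist)
        xs = np.sort(x)
        n = xs.size
        cdf = dist.cdf(xs)
        d_oracle = max(np.max(np.arange(1, n + 1) / n - cdf),
                       np.max(cdf - np.arange(0, n) / n))
        assert d == pytest.approx(d_oracle, abs=1e-12)

    def test_well_specified_samples_usually_pass(self):
        passes = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            x = stats.t.rvs(df=4, scale=10, size=300, random_state=rng)
            _, p = cal.ks_gof(x, stats.t(df=4, scale=10))
            passes += p > 0.05
        assert passes >= 90

    def test_gross_misfit_detected(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(-1, 1, size=500)
        _, p = cal.ks_gof(x, stats.t(df=3, scale=5))
        assert p < 0.001

    def test_bootstrap_p_more_conservative(self):
        rng = np.random.default_rng(14)
        x = stats.t.rvs(df=4, scale=10, size=300, random_state=rng)
        fit = cal.fit_scaled_t(x, seed=0)
        d, p_plain, p_boot = cal.ks_gof(
            x, fit.dist(), bootstrap=50,
            refit=lambda s: cal.fit_scaled_t(s, n_restarts=1, seed=0).dist(), seed=0)
        assert 0.0 <= p_boot <= 1.0
        # fitting the parameters shrinks D's null distribution, so the
        # bootstrap p-value is smaller than the (anticonservative) plain one
        assert p_boot <= p_plain
        assert p_boot > 0.05  # but the true-family null is still not rejected
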