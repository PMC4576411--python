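import math

import numpy as np
import pytest
from scipy import stats

from whaletrack import calibrate as cal
from whaletrack import deadreckon as dr
from whaletrack import simulate as sim
from whaletrack import ssm


def _gps_fixes(t, xy, q):
    n = len(t)
    return ssm.FixSeries.from_parts(gps_t=t, gps_xy=xy, gps_q=np.full(n, q, int))


class TestAlignFixTimes:
    def _series(self, gps_t, vis_t=()):
        n_v = len(vis_t)
        return ssm.FixSeries.from_parts(
            gps_t=gps_t, gps_xy=np.zeros((len(gps_t), 2)), gps_q=[3] * len(gps_t),
            vis_t=vis_t, vis_r=[100.0] * n_v, vis_phi=[0.0] * n_v,
            vis_method=[1] * n_v, vis_boat_xy=np.zeros((n_v, 2)))

    def test_gps_pair_merged_to_first(self):
        out = ssm.align_fix_times(self._series([100.0, 103.0]))
        assert np.allclose(out.t, [100.0, 100.0])

    def test_visual_takes_gps_timestamp(self):
        out = ssm.align_fix_times(self._series([100.0], vis_t=[104.0]))
        assert np.allclose(out.t, [100.0, 100.0])

    def test_distant_fixes_unchanged(self):
        out = ssm.align_fix_times(self._series([100.0, 106.0], vis_t=[250.0]))
        assert np.allclose(np.sort(out.t), [100.0, 106.0, 250.0])


def _two_fix_model(gps_model, vis_model, second_kind="gps", q=6):
    """Minimal model: origin GPS fix at t=0, one more fix at t=60."""
    v = dr.DrVelocity(t=np.arange(61.0), v=np.tile([0.5, 0.2], (61, 1)))
    if second_kind == "gps":
        x_implied = np.array([0.5, 0.2]) * 60.0
        fixes = _gps_fixes([0.0, 60.0], np.vstack([[0, 0], x_implied]), q)
    else:
        fixes = ssm.FixSeries.from_parts(
            gps_t=[0.0], gps_xy=[[0.0, 0.0]], gps_q=[q],
            vis_t=[60.0], vis_r=[100.0], vis_phi=[0.0], vis_method=[1],
            vis_boat_xy=[[30.0, 12.0 - 100.0]])
    d, delta = dr.segment_displacements(v, np.unique(fixes.t))
    return ssm.TrackModel(fixes, d, delta, gps_model, vis_model), v


class TestPriorAndLikelihood:
    def test_sigma_outside_support(self, gps_model, vis_model):
        model, _ = _two_fix_model(gps_model, vis_model)
        latent = ssm.LatentTrack(np.zeros(2), np.zeros((1, 2)))
        assert model.log_prior(ssm.ProcessParams(0.2, 0.05), latent) == -np.inf
        assert model.log_prior(ssm.ProcessParams(0.05, 0.05),
                               ssm.LatentTrack(np.zeros(2), np.full((1, 2), 1.5))) == -np.inf

    def test_uniform_prior_arithmetic(self, gps_model, vis_model):
        model, _ = _two_fix_model(gps_model, vis_model, q=6)
        latent = ssm.LatentTrack(np.array([3.0, -2.0]), np.zeros((1, 2)))
        lp = model.log_prior(ssm.ProcessParams(0.05, 0.05), latent)
        x1_terms = (stats.t.logpdf(3.0, df=8.17, scale=7.77)
                    + stats.t.logpdf(-2.0, df=7.72, scale=9.35))
        expected = -2 * math.log(0.1) - 2 * math.log(2.0) + x1_terms
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_gps_fix_at_implied_position_closed_form(self, gps_model, vis_model):
        # a GPS fix exactly at the implied position contributes the central
        # scaled-t ordinate in each dimension
        model, _ = _two_fix_model(gps_model, vis_model, second_kind="gps", q=6)
        latent = ssm.LatentTrack(np.zeros(2), np.zeros((1, 2)))
        ll = model.log_likelihood(latent, ssm.ProcessParams(0.05, 0.05))
        from scipy.special import gammaln
        expected = 0.0
        for sig, nu in [(7.77, 8.17), (9.35, 7.72)]:
            expected += (gammaln((nu + 1) / 2) - gammaln(nu / 2)
                         - 0.5 * math.log(nu * math.pi) - math.log(sig))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_visual_fix_closed_form(self, gps_model, vis_model):
        # whale due north of the boat at the observed range and bearing:
        # zero residuals, so the density is the Normal ordinate at 0 with
        # SD = R sigma_m / 100 plus the wrapped-Cauchy mode ordinate
        model, _ = _two_fix_model(gps_model, vis_model, second_kind="visual")
        latent = ssm.LatentTrack(np.zeros(2), np.zeros((1, 2)))
        ll = model.log_likelihood(latent, ssm.ProcessParams(0.05, 0.05))
        sd = 100.0 * 30.2 / 100.0
        rho = 0.897
        expected = (-math.log(sd * math.sqrt(2 * math.pi))
                    + math.log((1 - rho**2) / (2 * math.pi * (1 + rho**2 - 2 * rho))))
        assert ll == pytest.approx(expected, abs=1e-10)


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 20_000))
        assert abs(ssm.rhat(chains) - 1.0) < 1e-3

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert ssm.rhat(chains) > 1.1

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = np.cumsum(rng.normal(size=(4, 1000)), axis=1) * 0.01
        ours = ssm.rhat(chains)
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestEquation1Determinism:
    def test_implied_positions_match_recursion(self):
        rng = np.random.default_rng(3)
        J = 40
        d = rng.normal(size=(J - 1, 2)) * 50
        delta = rng.uniform(30, 300, J - 1)
        latent = ssm.LatentTrack(rng.normal(size=2), rng.normal(size=(J - 1, 2)) * 0.01)
        x = latent.implied_x(d, delta)
        xr = np.zeros((J, 2))
        xr[0] = latent.x1
        for j in range(J - 1):
            xr[j + 1] = xr[j] + d[j] + latent.v_cor[j] * delta[j]
        assert np.allclose(x, xr, atol=1e-12)
        back = ssm.LatentTrack.from_positions(x, d, delta)
        assert np.allclose(back.v_cor, latent.v_cor, atol=1e-12)


class TestFitMcmc:
    def test_degenerate_noise_concentrates_on_fixes(self, vis_model):
        # near-noiseless GPS and a drift-free track: posterior positions pin
        # to the fixes
        tight = cal.GpsErrorModel(
            mu={"x": np.zeros(6), "y": np.zeros(6)},
            sigma={"x": np.full(6, 0.01), "y": np.full(6, 0.01)},
            nu={"x": np.full(6, 50.0), "y": np.full(6, 50.0)})
        v = dr.DrVelocity(t=np.arange(601.0), v=np.tile([1.0, 0.5], (601, 1)))
        ft = np.arange(0.0, 601.0, 120.0)
        track = dr.uncorrected_track((0.0, 0.0), v)
        fixes = _gps_fixes(ft, track[ft.astype(int)], 6)
        d, delta = dr.segment_displacements(v, ft)
        cfg = ssm.McmcConfig(iterations=3000, burn_in=1000, thin=2, seed=0)
        post = ssm.fit_mcmc(fixes, d, delta, tight, config=cfg)
        xj = _implied_draws(post)
        sd = xj.reshape(-1, *xj.shape[2:]).std(axis=0)
        assert np.max(sd) < 1.0

    def test_posterior_respects_prior_support(self, small_fit):
        _, _, _, post = small_fit
        s = post.flat("sigma")
        assert np.all((s > 0) & (s < 0.1))
        v1 = post.flat("v_cor")[:, 0, :]
        assert np.all(np.abs(v1) < 1.0)

    def test_reproducible_given_seed(self, gps_model):
        v = dr.DrVelocity(t=np.arange(301.0), v=np.tile([1.0, 0.0], (301, 1)))
        ft = np.arange(0.0, 301.0, 60.0)
        rng = np.random.default_rng(0)
        xy = dr.uncorrected_track((0.0, 0.0), v)[ft.astype(int)] + rng.normal(size=(6, 2))
        fixes = _gps_fixes(ft, xy, 5)
        d, delta = dr.segment_displacements(v, ft)
        cfg = ssm.McmcConfig(iterations=600, burn_in=200, thin=2, seed=7)
        p1 = ssm.fit_mcmc(fixes, d, delta, gps_model, config=cfg)
        p2 = ssm.fit_mcmc(fixes, d, delta, gps_model, config=cfg)
        assert np.array_equal(p1.sigma, p2.sigma)
        assert np.array_equal(p1.v_cor, p2.v_cor)


def _implied_draws(post):
    """Latent positions per draw, (chains, draws, J, 2)."""
    step = post.d[None, None] + post.v_cor * post.delta[None, None, :, None]
    x = np.concatenate([np.zeros_like(step[..., :1, :]), np.cumsum(step, axis=2)], axis=2)
    return x + post.x1[:, :, None, :]


def _rts_smoother(d, delta, obs, x1_var, sigma, v1_var):
    """Independent RTS smoother oracle for one dimension.

    obs: list per latent index of (value, variance) Gaussian position
    observations.  Returns smoothed means of the positions.
    """
    J = len(delta) + 1
    m = np.zeros(2)
    p = np.diag([x1_var, v1_var])
    mf, pf, mp, pp = [], [], [], []
    for j in range(J):
        for z, r in obs[j]:
            s = p[0, 0] + r
            k = p[:, 0] / s
            m = m + k * (z - m[0])
            p = p - np.outer(k, p[0, :])
        mf.append(m.copy())
        pf.append(p.copy())
        if j < J - 1:
            dt = delta[j]
            f = np.array([[1.0, dt], [0.0, 1.0]])
            m = f @ m + np.array([d[j], 0.0])
            p = f @ p @ f.T + np.diag([0.0, sigma**2 * dt])
            mp.append(m.copy())
            pp.append(p.copy())
    ms = [None] * J
    ms[-1] = mf[-1]
    ps = pf[-1]
    for j in range(J - 2, -1, -1):
        dt = delta[j]
        f = np.array([[1.0, dt], [0.0, 1.0]])
        g = pf[j] @ f.T @ np.linalg.inv(pp[j])
        ms[j] = mf[j] + g @ (ms[j + 1] - mp[j])
        ps = pf[j] + g @ (ps - pp[j]) @ g.T
    return np.array([m[0] for m in ms])


class TestKalmanEquivalence:
    def test_gaussian_variant_matches_rts_smoother(self, gps_model):
        """With Normal observation errors and fixed process SDs, MCMC
        posterior means of the latent positions agree with an exact Kalman
        smoother (primary correctness check of the sampler)."""
        az = pytest.importorskip("arviz")
        cfg = sim.SimConfig(duration=3600, visual_interval=1e12, gps_fix_prob=1.0)
        ds = sim.simulate_dataset(cfg, seed=5)
        fixes = ssm.align_fix_times(ds.fixes)
        v = ds.truth.dr_velocity()
        times = np.unique(fixes.t)
        d, delta = dr.segment_displacements(v, times)
        sigma = (0.014, 0.012)
        mc = ssm.McmcConfig(iterations=6000, burn_in=2000, thin=2, seed=3)
        post = ssm.fit_mcmc(fixes, d, delta, gps_model, config=mc,
                            gaussian_obs=True, fix_sigma=sigma)
        xj = _implied_draws(post)  # (chains, draws, J, 2)

        model = ssm.TrackModel(fixes, d, delta, gps_model, gaussian_obs=True)
        _, obs_j = fixes.latent_structure()
        for k, dim in enumerate("xy"):
            obs = [[] for _ in range(times.size)]
            for i in range(len(fixes)):
                if i == model.origin_obs:
                    continue
                var = gps_model.sigma[dim][fixes.q[i] - 1] ** 2
                obs[obs_j[i]].append((fixes.xy[i, k], var))
            x1_var = gps_model.sigma[dim][fixes.q[model.origin_obs] - 1] ** 2
            truth = _rts_smoother(d[:, k], delta, obs, x1_var, sigma[k], v1_var=100.0)
            mean = xj[..., k].reshape(-1, times.size).mean(axis=0)
            for j in range(times.size):
                draws = xj[:, :, j, k]
                ess = float(az.ess(draws))
                mcse = draws.std() / math.sqrt(max(ess, 1.0))
                assert abs(mean[j] - truth[j]) < 2.0 * mcse + 0.15, (
                    f"dim {dim} j={j}: {mean[j]:.3f} vs {truth[j]:.3f} "
                    f"(mcse {mcse:.3f})")


class TestRealisations:
    def _dummy_posterior(self, v, times, x1, v_cor_draws):
        d, delta = dr.segment_displacements(v, times)
        draws = v_cor_draws.shape[1]
        cfg = ssm.McmcConfig(iterations=200, burn_in=100, thin=1, seed=0)
        return ssm.SsmPosterior(
            x1=np.broadcast_to(x1, (1, draws, 2)).copy(),
            v_cor=v_cor_draws, sigma=np.full((1, draws, 2), 0.01),
            rhat={}, config=cfg, times=times, d=d, delta=delta)

    def test_zero_correction_shifts_uncorrected_track(self):
        rng = np.random.default_rng(6)
        v = dr.DrVelocity(t=np.arange(240.0), v=rng.normal(size=(240, 2)))
        times = np.array([0.0, 120.0, 239.0])
        x1 = np.array([7.0, -5.0])
        post = self._dummy_posterior(v, times, x1, np.zeros((1, 10, 2, 2)))
        real = ssm.posterior_track_realisations(post, v, fraction=1.0)
        expected = dr.uncorrected_track(x1, v)
        for r in real:
            assert np.allclose(r, expected, atol=1e-9)

    def test_fix_time_positions_match_recursion(self):
        rng = np.random.default_rng(7)
        v = dr.DrVelocity(t=np.arange(500.0), v=rng.normal(size=(500, 2)))
        times = np.array([0.0, 90.0, 260.0, 499.0])
        vc = rng.normal(size=(1, 8, 3, 2)) * 0.1
        post = self._dummy_posterior(v, times, np.array([1.0, 2.0]), vc)
        real = ssm.posterior_track_realisations(post, v, fraction=1.0)
        idx = times.astype(int)
        for s in range(8):
            latent = ssm.LatentTrack(post.x1[0, s], post.v_cor[0, s])
            xj = latent.implied_x(post.d, post.delta)
            assert np.allclose(real[s][idx], xj, atol=1e-9)

    def test_full_length_bookkeeping_gives_3200(self):
        # 2 chains x 280,000 iterations with 200,000 burn-in and thinning by
        # 5 store 16,000 draws per chain; retaining 10 % gives 3,200 tracks
        cfg = ssm.PAPER_MCMC_CONFIG
        assert cfg.stored_per_chain == 16_000
        v = dr.DrVelocity(t=np.arange(61.0), v=np.zeros((61, 2)))
        times = np.array([0.0, 60.0])
        d, delta = dr.segment_displacements(v, times)
        post = ssm.SsmPosterior(
            x1=np.zeros((2, cfg.stored_per_chain, 2)),
            v_cor=np.zeros((2, cfg.stored_per_chain, 1, 2)),
            sigma=np.full((2, cfg.stored_per_chain, 2), 0.01),
            rhat={}, config=cfg, times=times, d=d, delta=delta)
        real = ssm.posterior_track_realisations(post, v, fraction=0.10)
        assert real.shape[0] == 3200

    def test_fraction_validated(self, small_fit):
        _, _, v, post = small_fit
        with pytest.raises(ValueError):
            ssm.posterior_track_realisations(post, v, fraction=1.5)


class TestUncertaintyOrdering:
    def test_visual_only_wider_than_gps(self, gps_model, vis_model):
        """Positional uncertainty is larger for visual-only fixes than for
        frequent GPS fixes."""
        widths = {}
        for kind in ("gps", "visual"):
            cfg = sim.SimConfig(
                duration=3600,
                visual_interval=120.0 if kind == "visual" else 1e12,
                gps_fix_prob=0.95 if kind == "gps" else 0.0)
            ds = sim.simulate_dataset(cfg, seed=9)
            fixes = ssm.align_fix_times(ds.fixes)
            v = ds.truth.dr_velocity()
            times = np.unique(fixes.t)
            d, delta = dr.segment_displacements(v, times)
            mc = ssm.McmcConfig(iterations=4000, burn_in=1500, thin=2, seed=1)
            post = ssm.fit_mcmc(fixes, d, delta, gps_model, vis_model, config=mc)
            xj = _implied_draws(post).reshape(-1, times.size, 2)
            lo, hi = np.percentile(xj, [2.5, 97.5], axis=0)
            widths[kind] = float(np.mean(hi - lo))
        assert widths["visual"] > widths["gps"]
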