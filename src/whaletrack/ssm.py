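"""Bayesian state-space track reconstruction.

The model operates at the irregular time scale of the position fixes.  Given
the initial unobserved position x_1, latent positions follow the
deterministic recursion

    x_{j+1} = x_j + d_j + v_j * delta_j,

where d_j is the dead-reckoned displacement over segment j and v_j the
velocity-correction term — a slowly varying bias absorbing current drift,
sensor error and dead-reckoning assumption violations — modelled as a
non-directional first-order Gaussian random walk with per-dimension variance
rate sigma^2 (units m/s per sqrt-second: Var(v_{j+1} - v_j) = sigma^2 *
delta_j with delta_j in seconds).  The x/y components are independent.

Observations at fix times are Fastloc-GPS positions with per-dimension
scaled-t errors (parameters fixed at their calibrated values per satellite
bin) and/or visual fixes modelled through the observer-to-whale range
(Normal, SD proportional to range) and absolute bearing (wrapped Cauchy).

Priors: sigma_x, sigma_y ~ Unif(0, 0.1); v_1 components ~ Unif(-1, 1); x_1
centred at the origin with the error family of the first observation.

Fitting is by adaptive random-walk Metropolis-within-Gibbs.  Internally the
sampler updates the latent positions x_j (a linear, constant-Jacobian
reparameterisation of (x_1, v_1..v_{J-1}) with strictly local dependence)
in three conditionally independent colour groups per sweep, plus a joint
(log sigma_x, log sigma_y) block; proposal scales adapt during burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .calibrate import GpsErrorModel, VisualErrorModel
from .deadreckon import DrVelocity

__all__ = [
    "FixSeries",
    "ProcessParams",
    "LatentTrack",
    "McmcConfig",
    "PAPER_MCMC_CONFIG",
    "SsmPosterior",
    "TrackModel",
    "align_fix_times",
    "fit_mcmc",
    "rhat",
    "posterior_track_realisations",
    "posterior_mean_track",
]

_LOG_2PI = math.log(2.0 * math.pi)
_SIGMA_MAX = 0.1
_VCOR1_MAX = 1.0
_RHAT_LIMIT = 1.05


# ---------------------------------------------------------------------------
# fixes


@dataclass
class FixSeries:
    """Ordered position fixes in the local frame.

    Parallel arrays over observations: ``t`` (s), ``kind`` ("gps"/"visual"),
    GPS local coordinates ``xy`` with satellite bin ``q``; visual range ``r``
    (m) with method ``method`` (1 by eye, 2 laser range finder), absolute
    bearing ``phi`` (deg) and boat position ``boat_xy``.  Fields that do not
    apply to an observation hold NaN / 0.  After time alignment several
    observations may share a timestamp, meaning multiple observations of one
    surfacing.
    """

    t: np.ndarray
    kind: np.ndarray
    xy: np.ndarray
    q: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    method: np.ndarray
    boat_xy: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.q = np.asarray(self.q, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.method = np.asarray(self.method, dtype=int)
        self.boat_xy = np.asarray(self.boat_xy, dtype=float).reshape(-1, 2)
        if np.any(np.diff(self.t) < 0):
            raise ValueError("fixes must be time-sorted")
        bad = ~np.isin(self.kind, ("gps", "visual"))
        if bad.any():
            raise ValueError(f"unknown fix kinds: {set(self.kind[bad])}")

    def __len__(self):
        return self.t.size

    @classmethod
    def from_parts(cls, gps_t=(), gps_xy=(), gps_q=(), vis_t=(), vis_r=(),
                   vis_phi=(), vis_method=(), vis_boat_xy=()) -> "FixSeries":
        """Assemble a time-sorted series from separate GPS and visual parts."""
        gps_t = np.asarray(gps_t, dtype=float)
        vis_t = np.asarray(vis_t, dtype=float)
        n_g, n_v = gps_t.size, vis_t.size
        t = np.concatenate([gps_t, vis_t])
        kind = np.array(["gps"] * n_g + ["visual"] * n_v, dtype=object)
        xy = np.full((n_g + n_v, 2), np.nan)
        if n_g:
            xy[:n_g] = np.asarray(gps_xy, dtype=float).reshape(n_g, 2)
        q = np.concatenate([np.asarray(gps_q, dtype=int).reshape(n_g), np.zeros(n_v, int)])
        r = np.concatenate([np.full(n_g, np.nan), np.asarray(vis_r, dtype=float).reshape(n_v)])
        phi = np.concatenate([np.full(n_g, np.nan), np.asarray(vis_phi, dtype=float).reshape(n_v)])
        method = np.concatenate(
            [np.zeros(n_g, int), np.asarray(vis_method, dtype=int).reshape(n_v)]
        )
        boat = np.full((n_g + n_v, 2), np.nan)
        if n_v:
            boat[n_g:] = np.asarray(vis_boat_xy, dtype=float).reshape(n_v, 2)
        order = np.argsort(t, kind="stable")
        return cls(t[order], kind[order], xy[order], q[order], r[order],
                   phi[order], method[order], boat[order])

    def subset(self, mask) -> "FixSeries":
        mask = np.asarray(mask)
        return FixSeries(self.t[mask], self.kind[mask], self.xy[mask], self.q[mask],
                         self.r[mask], self.phi[mask], self.method[mask],
                         self.boat_xy[mask])

    def latent_structure(self):
        """Unique fix times and the latent index of each observation."""
        times, inverse = np.unique(self.t, return_inverse=True)
        return times, inverse


def align_fix_times(fixes: FixSeries, window: float = 5.0) -> FixSeries:
    """Merge near-simultaneous fixes onto shared timestamps.

    GPS fixes within ``window`` seconds of the previous GPS fix take its
    (earlier) timestamp; visual fixes within +/- ``window`` of a GPS fix take
    that GPS timestamp.  Shared timestamps mean multiple observations of the
    same surfacing.
    """
    t = fixes.t.copy()
    gps_idx = np.flatnonzero(fixes.kind == "gps")
    group_t = None
    for i in gps_idx:
        if group_t is not None and t[i] - group_t <= window:
            t[i] = group_t
        else:
            group_t = t[i]
    gps_times = t[gps_idx]
    for i in np.flatnonzero(fixes.kind == "visual"):
        if gps_times.size == 0:
            break
        k = np.argmin(np.abs(gps_times - t[i]))
        if abs(gps_times[k] - t[i]) <= window:
            t[i] = gps_times[k]
    order = np.argsort(t, kind="stable")
    return FixSeries(t[order], fixes.kind[order], fixes.xy[order], fixes.q[order],
                     fixes.r[order], fixes.phi[order], fixes.method[order],
                     fixes.boat_xy[order])


# ---------------------------------------------------------------------------
# parameters and latent state


@dataclass
class ProcessParams:
    """Process-noise SD rates (m/s) for the x and y dimensions."""

    sigma_x: float
    sigma_y: float

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y])


@dataclass
class LatentTrack:
    """Initial position and velocity-correction path of one posterior state."""

    x1: np.ndarray
    v_cor: np.ndarray  # (J-1, 2)

    def implied_x(self, d: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """Latent positions from the deterministic recursion
        x_{j+1} = x_j + d_j + v_j delta_j."""
        x = np.empty((self.v_cor.shape[0] + 1, 2))
        x[0] = self.x1
        np.cumsum(d + self.v_cor * delta[:, None], axis=0, out=x[1:])
        x[1:] += self.x1
        return x

    @classmethod
    def from_positions(cls, x: np.ndarray, d: np.ndarray, delta: np.ndarray):
        v = (np.diff(x, axis=0) - d) / delta[:, None]
        return cls(x1=x[0].copy(), v_cor=v)


@dataclass
class McmcConfig:
    chains: int = 2
    iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int | None = None
    #: run a joint FFBS path proposal every this many iterations (local
    #: Metropolis sweeps run every iteration)
    ffbs_every: int = 10

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be shorter than the run")

    @property
    def stored_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: the full-length configuration used for the whale fits
PAPER_MCMC_CONFIG = McmcConfig(chains=2, iterations=280_000, burn_in=200_000, thin=5)


@dataclass
class SsmPosterior:
    """Posterior samples (chains x draws) plus diagnostics and bookkeeping."""

    x1: np.ndarray        # (chains, draws, 2)
    v_cor: np.ndarray     # (chains, draws, J-1, 2)
    sigma: np.ndarray     # (chains, draws, 2)
    rhat: dict
    config: McmcConfig
    times: np.ndarray     # latent (unique fix) times
    d: np.ndarray
    delta: np.ndarray
    accept: dict = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        return max(float(np.max(v)) for v in self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat <= _RHAT_LIMIT

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


# ---------------------------------------------------------------------------
# model


class TrackModel:
    """Joint density of the track-reconstruction model for one deployment.

    Parameters
    ----------
    fixes : FixSeries
        Time-aligned position fixes; the first observation defines the origin
        and supplies the x_1 prior, and is therefore not part of the
        likelihood.
    d, delta : arrays
        Dead-reckoned displacements (J-1, 2) and durations (J-1,) of the
        segments between unique fix times.
    gps_model, vis_model
        Calibrated observation-error parameters, used as fixed values.
    gaussian_obs : bool
        Replace each scaled-t GPS error with a Normal of matching scale
        parameter (used for linear-Gaussian cross-checks).
    """

    def __init__(self, fixes: FixSeries, d, delta, gps_model: GpsErrorModel,
                 vis_model: VisualErrorModel | None = None, gaussian_obs: bool = False):
        self.fixes = fixes
        self.d = np.asarray(d, dtype=float).reshape(-1, 2)
        self.delta = np.asarray(delta, dtype=float)
        self.gps_model = gps_model
        self.vis_model = vis_model
        self.gaussian_obs = gaussian_obs

        self.times, obs_j = fixes.latent_structure()
        self.J = self.times.size
        if self.J < 2:
            raise ValueError("need at least two distinct fix times")
        if self.d.shape[0] != self.J - 1:
            raise ValueError("displacements must cover the J-1 inter-fix segments")

        # the first observation (GPS preferred on ties) anchors the origin
        first = np.flatnonzero(obs_j == 0)
        gps_first = first[fixes.kind[first] == "gps"]
        self.origin_obs = int(gps_first[0]) if gps_first.size else int(first[0])
        self._prepare_obs(obs_j)
        self._prepare_x1_prior()

    # -- precomputed observation arrays

    def _prepare_obs(self, obs_j):
        fx = self.fixes
        keep = np.ones(len(fx), dtype=bool)
        keep[self.origin_obs] = False
        g = keep & (fx.kind == "gps")
        v = keep & (fx.kind == "visual")
        if np.any((fx.kind == "gps") & ((fx.q < 1) | (fx.q > 6))):
            raise ValueError("GPS fix with satellite bin outside 1..6")
        self._gps_j = obs_j[g]
        self._gps_xy = fx.xy[g]
        qg = fx.q[g]
        sig = np.column_stack([self.gps_model.sigma["x"][qg - 1],
                               self.gps_model.sigma["y"][qg - 1]])
        nu = np.column_stack([self.gps_model.nu["x"][qg - 1],
                              self.gps_model.nu["y"][qg - 1]])
        self._gps_sigma = sig
        if self.gaussian_obs:
            self._gps_nu = np.full_like(nu, np.inf)
            self._gps_const = -np.log(sig) - 0.5 * _LOG_2PI
        else:
            self._gps_nu = nu
            self._gps_const = (
                special.gammaln((nu + 1.0) / 2.0)
                - special.gammaln(nu / 2.0)
                - 0.5 * np.log(nu * np.pi)
                - np.log(sig)
            )
        if v.any():
            if self.vis_model is None:
                raise ValueError("visual fixes present but no visual error model")
            if np.any(~np.isin(fx.method[v], (1, 2))):
                raise ValueError("visual fix with unknown range method")
            self._vis_j = obs_j[v]
            self._vis_R = fx.r[v]
            sdpct = np.array([self.vis_model.sigma_r[int(m)] for m in fx.method[v]])
            self._vis_sdfrac = sdpct / 100.0
            self._vis_phi = np.radians(fx.phi[v])
            self._vis_boat = fx.boat_xy[v]
            # Gaussian surrogate of each visual fix (used only as an MCMC
            # proposal, Metropolis-corrected against the exact density):
            # position pseudo-observation at boat + R*(sin,cos)Phi with
            # radial SD R*sigma_m/100 and tangential SD from the
            # wrapped-Cauchy curvature at its mode, (1-rho)/sqrt(2 rho).
            self._vis_ur = np.column_stack([np.sin(self._vis_phi), np.cos(self._vis_phi)])
            self._vis_ut = np.column_stack([np.cos(self._vis_phi), -np.sin(self._vis_phi)])
            self._vis_z = self._vis_boat + self._vis_R[:, None] * self._vis_ur
            rho = self.vis_model.rho
            # small-angle limit of the wrapped Cauchy is a Cauchy with scale
            # (1-rho)/sqrt(rho); a Cauchy is a precision-mixture of Normals
            # with Gamma(1/2, 1/2) weights, which gives the surrogate its
            # tangential scales
            gam = (1.0 - rho) / math.sqrt(rho) if rho > 0 else math.pi
            self._vis_sr = self._vis_R * self._vis_sdfrac
            self._vis_st0 = self._vis_R * gam
        else:
            self._vis_j = np.zeros(0, dtype=int)

    def _prepare_x1_prior(self):
        fx = self.fixes
        i = self.origin_obs
        if fx.kind[i] == "gps":
            q = int(fx.q[i])
            _, sx, nx = self.gps_model.params("x", q)
            _, sy, ny = self.gps_model.params("y", q)
            if self.gaussian_obs:
                nx = ny = np.inf
            self._x1_scale = np.array([sx, sy])
            self._x1_nu = np.array([nx, ny])
        else:
            sd = float(fx.r[i]) * self.vis_model.sigma_r[int(fx.method[i])] / 100.0
            self._x1_scale = np.array([sd, sd])
            self._x1_nu = np.array([np.inf, np.inf])

    # -- density pieces

    def x1_log_prior(self, x1) -> float:
        z = np.asarray(x1, dtype=float) / self._x1_scale
        fin = np.isfinite(self._x1_nu)
        nu = np.where(fin, self._x1_nu, 1.0)
        out = np.where(
            fin,
            special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0)
            - 0.5 * np.log(nu * np.pi)
            - (nu + 1.0) / 2.0 * np.log1p(z * z / nu),
            -0.5 * (z * z + _LOG_2PI),
        )
        return float(np.sum(out - np.log(self._x1_scale)))

    def log_prior(self, params: ProcessParams, latent: LatentTrack) -> float:
        """Table-2 priors: uniforms on sigma and v_1, observation-error family
        on x_1 (centred at the origin)."""
        sig = params.sigma
        if np.any(sig <= 0) or np.any(sig >= _SIGMA_MAX):
            return -np.inf
        if np.any(np.abs(latent.v_cor[0]) >= _VCOR1_MAX):
            return -np.inf
        lp = -2.0 * math.log(_SIGMA_MAX) - 2.0 * math.log(2.0 * _VCOR1_MAX)
        return lp + self.x1_log_prior(latent.x1)

    def _rw_logdens(self, v_cor, sigma):
        """Per-increment Gaussian random-walk log-densities (J-2,)."""
        if v_cor.shape[0] < 2:
            return np.zeros(0)
        w = np.diff(v_cor, axis=0)
        var = sigma[None, :] ** 2 * self.delta[:-1, None]
        return np.sum(-0.5 * (_LOG_2PI + np.log(var)) - w * w / (2.0 * var), axis=1)

    def _obs_logdens_by_latent(self, x) -> np.ndarray:
        """Observation log-density accumulated per latent index (J,)."""
        out = np.zeros(self.J)
        if self._gps_j.size:
            z = (self._gps_xy - x[self._gps_j]) / self._gps_sigma
            fin = np.isfinite(self._gps_nu)
            nu = np.where(fin, self._gps_nu, 1.0)
            term = np.where(
                fin,
                self._gps_const - (nu + 1.0) / 2.0 * np.log1p(z * z / nu),
                self._gps_const - 0.5 * z * z,
            )
            np.add.at(out, self._gps_j, term.sum(axis=1))
        if self._vis_j.size:
            dxy = x[self._vis_j] - self._vis_boat
            r = np.hypot(dxy[:, 0], dxy[:, 1])
            r = np.maximum(r, 1e-9)
            phi = np.arctan2(dxy[:, 0], dxy[:, 1])
            sd = r * self._vis_sdfrac
            range_ld = -np.log(sd) - 0.5 * _LOG_2PI - (self._vis_R - r) ** 2 / (2.0 * sd * sd)
            rho = self.vis_model.rho
            bear_ld = (
                math.log(1.0 - rho * rho)
                - _LOG_2PI
                - np.log(1.0 + rho * rho - 2.0 * rho * np.cos(self._vis_phi - phi))
            )
            np.add.at(out, self._vis_j, range_ld + bear_ld)
        return out

    def log_likelihood(self, latent: LatentTrack, params: ProcessParams) -> float:
        """Random-walk increments of v_cor plus all observation terms."""
        x = latent.implied_x(self.d, self.delta)
        return float(
            np.sum(self._rw_logdens(latent.v_cor, params.sigma))
            + np.sum(self._obs_logdens_by_latent(x))
        )

    def log_posterior(self, latent: LatentTrack, params: ProcessParams) -> float:
        lp = self.log_prior(params, latent)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(latent, params)

    # -- fast local decomposition used by the sampler (x-space)

    def _v_from_x(self, x):
        return (np.diff(x, axis=0) - self.d) / self.delta[:, None]

    def _local_lp(self, x, sigma) -> np.ndarray:
        """Per-site local log-posterior contributions (length J).

        local[j] collects every density term that depends on x_j: the
        observation terms at j, the RW increments within two segments of j,
        the v_1 support indicator (sites 0 and 1) and the x_1 prior (site 0).
        Sites three or more apart never share a term, which makes the three
        colour groups (j mod 3) conditionally independent.
        """
        v = self._v_from_x(x)
        rw = self._rw_logdens(v, sigma)
        padded = np.zeros(self.J + 2)
        padded[2:2 + rw.size] = rw
        local = padded[:-2] + padded[1:-1] + padded[2:]
        local += self._obs_logdens_by_latent(x)
        if np.any(np.abs(v[0]) >= _VCOR1_MAX):
            local[0] = local[1] = -np.inf
        local[0] += self.x1_log_prior(x[0])
        return local

    def _sigma_lp(self, x, log_sigma) -> float:
        """Log-posterior terms involving sigma (log-scale, incl. Jacobian)."""
        sigma = np.exp(log_sigma)
        if np.any(sigma >= _SIGMA_MAX):
            return -np.inf
        v = self._v_from_x(x)
        return float(np.sum(self._rw_logdens(v, sigma)) + np.sum(log_sigma))

    def _x_from_v(self, x1, v) -> np.ndarray:
        x = np.empty((self.J, 2))
        x[0] = x1
        np.cumsum(self.d + v * self.delta[:, None], axis=0, out=x[1:])
        x[1:] += x1
        return x

    def _rescaled_state(self, x, log_sigma, new_log_sigma):
        """Rescale the v_cor innovation path from sigma to sigma'.

        In the non-centred parameterisation (standardised innovations held
        fixed) a change of sigma rescales the increments of v_cor; x_1 and
        v_1 are unchanged and the innovation density cancels from the MH
        ratio, so only the observation terms and the sigma prior remain.
        """
        v = self._v_from_x(x)
        if v.shape[0] >= 2:
            w = np.diff(v, axis=0) * np.exp(new_log_sigma - log_sigma)[None, :]
            v_new = np.vstack([v[:1], v[:1] + np.cumsum(w, axis=0)])
        else:
            v_new = v
        return self._x_from_v(x[0], v_new)

    # -- conditionally linear-Gaussian machinery
    #
    # Given per-observation scale-mixture variables u (a scaled t with nu
    # degrees of freedom is a Normal whose precision is Gamma(nu/2, nu/2)
    # mixed), the model with Gaussian surrogates for the visual fixes is
    # linear-Gaussian in the state (x_j, v_j), so whole latent paths can be
    # drawn exactly by forward filtering / backward sampling.  The draw is
    # used as an independence proposal and corrected for the exact visual
    # and v_1-prior densities.

    _TAU_V1 = math.sqrt(1.0 / 3.0)  # proposal SD matching Unif(-1,1)

    def draw_mixture_scales(self, x, rng):
        """Gibbs draw of the scale-mixture precisions given the path.

        Returns (u_gps, u_x1, w_vis): Gamma((nu+1)/2, (nu+z^2)/2) precisions
        for the scaled-t GPS errors and the x_1 prior, and Gamma(1, (1 +
        z_t^2)/2) precisions for the tangential Cauchy surrogate of each
        visual bearing.
        """
        if self.gaussian_obs:
            u_gps = np.ones_like(self._gps_sigma)
            u_x1 = np.ones(2)
        else:
            z2 = ((self._gps_xy - x[self._gps_j]) / self._gps_sigma) ** 2
            nu = self._gps_nu
            u_gps = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + z2))
            nu1 = self._x1_nu
            z2 = (x[0] / self._x1_scale) ** 2
            fin = np.isfinite(nu1)
            u_x1 = np.where(
                fin,
                rng.gamma((np.where(fin, nu1, 2.0) + 1.0) / 2.0,
                          2.0 / (np.where(fin, nu1, 2.0) + z2)),
                1.0,
            )
        if self._vis_j.size:
            z2 = np.column_stack([
                (self._vis_radial(x) / self._vis_sr) ** 2,
                (self._vis_tangential(x) / self._vis_st0) ** 2,
            ])
            w_vis = rng.gamma(1.0, 2.0 / (1.0 + z2))
        else:
            w_vis = np.zeros((0, 2))
        return u_gps, u_x1, w_vis

    def _vis_tangential(self, x):
        resid = x[self._vis_j] - self._vis_z
        return np.einsum("ij,ij->i", resid, self._vis_ut)

    def _vis_radial(self, x):
        resid = x[self._vis_j] - self._vis_z
        return np.einsum("ij,ij->i", resid, self._vis_ur)

    def _gaussianised_obs(self, u_gps, u_x1, w_vis):
        """Per-latent lists of Gaussian (z, cov) position observations."""
        obs = [[] for _ in range(self.J)]
        var = self._gps_sigma**2 / u_gps
        for k in range(self._gps_j.size):
            obs[self._gps_j[k]].append((self._gps_xy[k], np.diag(var[k])))
        for k in range(self._vis_j.size):
            ur, ut = self._vis_ur[k], self._vis_ut[k]
            cov = (self._vis_sr[k] ** 2 / w_vis[k, 0] * np.outer(ur, ur)
                   + self._vis_st0[k] ** 2 / w_vis[k, 1] * np.outer(ut, ut))
            obs[self._vis_j[k]].append((self._vis_z[k], cov))
        return obs, self._x1_scale**2 / u_x1

    def ffbs_draw(self, sigma, u_gps, u_x1, w_vis, rng):
        """Exact joint path draw from the Gaussian-surrogate model.

        Returns latent positions x (J, 2).  State is (x, y, vx, vy); the
        position transition is deterministic given v, handled in the backward
        pass by sampling v_j from its conditional and back-substituting.
        """
        J = self.J
        obs, x1_var = self._gaussianised_obs(u_gps, u_x1, w_vis)
        qv = sigma**2  # per-second variance rates

        m = np.zeros(4)
        p = np.diag([x1_var[0], x1_var[1], self._TAU_V1**2, self._TAU_V1**2])
        ms = np.empty((J, 4))
        ps = np.empty((J, 4, 4))
        for j in range(J):
            for z, r in obs[j]:
                s = p[:2, :2] + r
                k = np.linalg.solve(s.T, p[:, :2].T).T  # P H' S^-1
                m = m + k @ (z - m[:2])
                p = p - k @ p[:2, :]
                p = 0.5 * (p + p.T)
            ms[j] = m
            ps[j] = p
            if j < J - 1:
                dt = self.delta[j]
                f = np.eye(4)
                f[0, 2] = f[1, 3] = dt
                m = f @ m
                m[:2] += self.d[j]
                p = f @ p @ f.T
                p[2, 2] += qv[0] * dt
                p[3, 3] += qv[1] * dt

        x = np.empty((J, 2))
        alpha = rng.multivariate_normal(ms[-1], ps[-1], method="svd")
        x[-1] = alpha[:2]
        v_next = alpha[2:]
        for j in range(J - 2, -1, -1):
            dt = self.delta[j]
            # alpha_j = G v_j + g on the deterministic-position constraint
            g2 = x[j + 1] - self.d[j]
            pinv = np.linalg.inv(ps[j])
            gmat = np.zeros((4, 2))
            gmat[0, 0] = gmat[1, 1] = -dt
            gmat[2, 0] = gmat[3, 1] = 1.0
            goff = np.concatenate([g2, np.zeros(2)])
            prec = gmat.T @ pinv @ gmat + np.diag(1.0 / (qv * dt))
            rhs = gmat.T @ pinv @ (ms[j] - goff) + v_next / (qv * dt)
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + cov.T)
            vj = rng.multivariate_normal(cov @ rhs, cov, method="svd")
            x[j] = x[j + 1] - self.d[j] - vj * dt
            v_next = vj
        return x

    def path_correction(self, x, w_vis) -> float:
        """Exact-minus-surrogate log density of a state for the FFBS step.

        Auxiliary-variable Metropolis correction: the FFBS proposal targets
        the surrogate model given the mixture scales, so the acceptance ratio
        needs (exact likelihood) - (surrogate likelihood | scales) + (log
        density of drawing those scales from this state), evaluated at old
        and new states.  The GPS scaled-t terms cancel identically (their
        mixture is exact) and are omitted; what remains is the visual block
        and the uniform-vs-Gaussian v_1 prior.
        """
        out = 0.0
        if self._vis_j.size:
            dxy = x[self._vis_j] - self._vis_boat
            r = np.maximum(np.hypot(dxy[:, 0], dxy[:, 1]), 1e-9)
            phi = np.arctan2(dxy[:, 0], dxy[:, 1])
            sd = r * self._vis_sdfrac
            exact = (-np.log(sd) - 0.5 * _LOG_2PI
                     - (self._vis_R - r) ** 2 / (2.0 * sd * sd))
            rho = self.vis_model.rho
            exact += (math.log(1.0 - rho * rho) - _LOG_2PI
                      - np.log(1.0 + rho * rho - 2.0 * rho * np.cos(self._vis_phi - phi)))
            z = np.column_stack([self._vis_radial(x) / self._vis_sr,
                                 self._vis_tangential(x) / self._vis_st0])
            surr = np.sum(
                -np.log(np.column_stack([self._vis_sr, self._vis_st0]))
                + 0.5 * np.log(w_vis) - 0.5 * _LOG_2PI - 0.5 * w_vis * z * z,
                axis=1,
            )
            rate = (1.0 + z * z) / 2.0  # Gamma(1, rate) scale draws
            scale_lp = np.sum(np.log(rate) - rate * w_vis, axis=1)
            out += float(np.sum(exact - surr + scale_lp))
        v1 = (x[1] - x[0] - self.d[0]) / self.delta[0]
        if np.any(np.abs(v1) >= _VCOR1_MAX):
            return -np.inf
        # uniform v_1 prior is constant on its support; subtract the
        # Gaussian proposal prior
        out += float(np.sum(0.5 * (v1 / self._TAU_V1) ** 2
                            + 0.5 * _LOG_2PI + math.log(self._TAU_V1)))
        return out

    # -- initial states

    def observed_positions(self) -> np.ndarray:
        """Best available observed position per latent time (NaN-free).

        GPS coordinates where present; visual fixes converted through boat
        position, range and bearing; remaining gaps linearly interpolated.
        """
        fx = self.fixes
        _, obs_j = fx.latent_structure()
        pos = np.full((self.J, 2), np.nan)
        for i in np.argsort(fx.kind)[::-1]:  # visual first, gps overwrite
            j = obs_j[i]
            if fx.kind[i] == "gps":
                pos[j] = fx.xy[i]
            else:
                b = np.radians(fx.phi[i])
                pos[j] = fx.boat_xy[i] + fx.r[i] * np.array([np.sin(b), np.cos(b)])
        ok = np.isfinite(pos[:, 0])
        for k in range(2):
            pos[~ok, k] = np.interp(self.times[~ok], self.times[ok], pos[ok, k])
        return pos

    def initial_states(self):
        """Two over-dispersed initial states: the fix-following (forced-point)
        track with sigma = 0.01, and the zero-correction dead-reckoning track
        with sigma = 0.05."""
        obs_pos = self.observed_positions()
        dr_pos = np.vstack([[0.0, 0.0], np.cumsum(self.d, axis=0)])
        states = []
        for x0, sig in ((obs_pos, 0.01), (dr_pos, 0.05)):
            x = x0.copy()
            v1 = (x[1] - x[0] - self.d[0]) / self.delta[0]
            clipped = np.clip(v1, -0.9 * _VCOR1_MAX, 0.9 * _VCOR1_MAX)
            x[1] = x[0] + self.d[0] + clipped * self.delta[0]
            states.append((x, np.array([sig, sig])))
        return states


# ---------------------------------------------------------------------------
# sampler


def _run_chain(model: TrackModel, x0, sigma0, config: McmcConfig, rng,
               fix_sigma: bool = False):
    J = model.J
    x = x0.copy()
    log_sigma = np.log(np.asarray(sigma0, dtype=float))
    colors = [np.arange(c, J, 3) for c in range(3)]

    scale_x = np.full(J, 5.0)
    scale_s = 0.2
    scale_nc = 0.2
    scale_t = 5.0
    target, t_sig = 0.35, 0.30

    n_store = config.stored_per_chain
    out_x1 = np.empty((n_store, 2))
    out_v = np.empty((n_store, J - 1, 2))
    out_s = np.empty((n_store, 2))
    acc_x = np.zeros(J)
    acc_s = 0
    n_kept = 0
    local = model._local_lp(x, np.exp(log_sigma))
    if not np.isfinite(local.sum()):
        raise RuntimeError("non-finite log-posterior at the initial state")

    acc_ffbs = np.zeros(2)  # accepted, proposed
    for it in range(config.iterations):
        adapting = it < config.burn_in
        gamma = 2.0 / max(20.0, it + 1.0) ** 0.6 if adapting else 0.0

        if config.ffbs_every and it % config.ffbs_every == 0:
            u_gps, u_x1, w_vis = model.draw_mixture_scales(x, rng)
            x_prop = model.ffbs_draw(np.exp(log_sigma), u_gps, u_x1, w_vis, rng)
            dlp = model.path_correction(x_prop, w_vis) - model.path_correction(x, w_vis)
            acc_ffbs[1] += 1
            if np.log(rng.uniform()) < dlp:
                x = x_prop
                acc_ffbs[0] += 1

        for sites in colors:
            prop = x.copy()
            prop[sites] += rng.normal(size=(sites.size, 2)) * scale_x[sites, None]
            cur_local = model._local_lp(x, np.exp(log_sigma))
            new_local = model._local_lp(prop, np.exp(log_sigma))
            with np.errstate(invalid="ignore"):
                dlp = new_local[sites] - cur_local[sites]
            accept = np.log(rng.uniform(size=sites.size)) < dlp
            x[sites[accept]] = prop[sites[accept]]
            if adapting:
                scale_x[sites] *= np.exp(gamma * (accept.astype(float) - target))
            else:
                acc_x[sites] += accept

        if not fix_sigma:
            prop_ls = log_sigma + rng.normal(size=2) * scale_s
            dlp = model._sigma_lp(x, prop_ls) - model._sigma_lp(x, log_sigma)
            acc = np.log(rng.uniform()) < dlp
            if acc:
                log_sigma = prop_ls
            if adapting:
                scale_s *= math.exp(gamma * (float(acc) - t_sig))
            else:
                acc_s += acc

            # non-centred sigma move: rescale the innovation path with sigma
            prop_ls = log_sigma + rng.normal(size=2) * scale_nc
            if np.all(prop_ls < math.log(_SIGMA_MAX)):
                x_new = model._rescaled_state(x, log_sigma, prop_ls)
                dlp = (np.sum(model._obs_logdens_by_latent(x_new))
                       - np.sum(model._obs_logdens_by_latent(x))
                       + float(np.sum(prop_ls - log_sigma)))
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    log_sigma, x = prop_ls, x_new
            else:
                acc = False
            if adapting:
                scale_nc *= math.exp(gamma * (float(acc) - t_sig))

        # whole-track translation (global placement)
        shift = rng.normal(size=2) * scale_t
        dlp = (np.sum(model._obs_logdens_by_latent(x + shift))
               - np.sum(model._obs_logdens_by_latent(x))
               + model.x1_log_prior(x[0] + shift) - model.x1_log_prior(x[0]))
        acc = np.log(rng.uniform()) < dlp
        if acc:
            x = x + shift
        if adapting:
            scale_t *= math.exp(gamma * (float(acc) - t_sig))

        if not adapting and (it - config.burn_in) % config.thin == 0 and n_kept < n_store:
            out_x1[n_kept] = x[0]
            out_v[n_kept] = model._v_from_x(x)
            out_s[n_kept] = np.exp(log_sigma)
            n_kept += 1

    post_iters = max(1, config.iterations - config.burn_in)
    return (out_x1[:n_kept], out_v[:n_kept], out_s[:n_kept],
            {"x": acc_x / post_iters, "sigma": acc_s / post_iters,
             "ffbs": acc_ffbs[0] / max(acc_ffbs[1], 1)})


def fit_mcmc(fixes: FixSeries, d, delta, gps_model: GpsErrorModel,
             vis_model: VisualErrorModel | None = None,
             config: McmcConfig | None = None,
             gaussian_obs: bool = False,
             fix_sigma: tuple | None = None) -> SsmPosterior:
    """Fit the state-space model by MCMC.

    Runs ``config.chains`` chains from different initial values (fix-following
    vs. pure dead-reckoning), computes split R-hat per parameter and warns if
    any exceeds 1.05.  ``fix_sigma`` holds the process SDs at known values
    instead of sampling them (used in linear-Gaussian cross-checks).
    """
    import warnings

    config = config or McmcConfig()
    model = TrackModel(fixes, d, delta, gps_model, vis_model, gaussian_obs=gaussian_obs)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    inits = model.initial_states()
    xs, vs, ss, accs = [], [], [], []
    for c in range(config.chains):
        x0, sig0 = inits[c % len(inits)]
        if fix_sigma is not None:
            sig0 = np.asarray(fix_sigma, dtype=float)
        rng = np.random.default_rng(seeds[c])
        cx1, cv, cs, acc = _run_chain(model, x0, sig0, config, rng,
                                      fix_sigma=fix_sigma is not None)
        xs.append(cx1)
        vs.append(cv)
        ss.append(cs)
        accs.append(acc)

    x1 = np.stack(xs)
    v_cor = np.stack(vs)
    sigma = np.stack(ss)
    rh = {
        "x1": rhat(x1),
        "v_cor": rhat(v_cor),
        "sigma": rhat(sigma),
    }
    post = SsmPosterior(x1=x1, v_cor=v_cor, sigma=sigma, rhat=rh, config=config,
                        times=model.times, d=model.d, delta=model.delta,
                        accept={"chain_%d" % i: a for i, a in enumerate(accs)})
    if not post.converged:
        warnings.warn(
            f"max split R-hat {post.max_rhat:.3f} exceeds {_RHAT_LIMIT}; "
            "treat the posterior with caution", stacklevel=2)
    return post


def rhat(chains: np.ndarray) -> np.ndarray:
    """Split R-hat (Brooks-Gelman-Rubin) per parameter.

    ``chains`` has shape (chains, draws, ...); each chain is split in half,
    and the classic potential-scale-reduction factor is computed from the
    within- and between-half variances.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim < 2 or arr.shape[0] < 2 or arr.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    n = arr.shape[1] // 2
    halves = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / w)
    return np.where(w > 0, out, 1.0)


# ---------------------------------------------------------------------------
# post-processing


def posterior_track_realisations(posterior: SsmPosterior, v: DrVelocity,
                                 fraction: float = 0.10) -> np.ndarray:
    """High-resolution posterior sample tracks.

    For each retained posterior draw (an evenly spaced ``fraction`` of the
    stored draws per chain) the 1-Hz track is the dead-reckoning integral of
    the uncorrected velocity plus the drawn initial position and the
    accumulated velocity correction of the segment containing each sample.
    At the fix times each realisation reproduces that draw's implied latent
    positions exactly.  Returns an array (realisations, samples, 2).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    chains, draws = posterior.x1.shape[:2]
    keep = max(1, int(round(draws * fraction)))
    sel = np.linspace(0, draws - 1, keep).astype(int)

    cum = np.vstack([[0.0, 0.0], np.cumsum(v.v * v.delta, axis=0)[:-1]])
    times = posterior.times
    i1 = int(np.clip(round((times[0] - v.t[0]) / v.delta), 0, v.t.size - 1))
    seg = np.clip(np.searchsorted(times, v.t, side="right") - 1, 0, times.size - 2)
    tau = (v.t - times[seg])[:, None]
    base = cum - cum[i1]

    out = np.empty((chains * keep, v.t.size, 2))
    k = 0
    for c in range(chains):
        for s in sel:
            vc = posterior.v_cor[c, s]
            prefix = np.vstack([[0.0, 0.0], np.cumsum(vc * posterior.delta[:, None], axis=0)])
            out[k] = posterior.x1[c, s] + base + prefix[seg] + vc[seg] * tau
            k += 1
    return out


def posterior_mean_track(posterior: SsmPosterior, v: DrVelocity,
                         fraction: float = 0.10) -> np.ndarray:
    """Pointwise mean of the posterior track realisations (the "most
    probable" 1-Hz track)."""
    return posterior_track_realisations(posterior, v, fraction).mean(axis=0)
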