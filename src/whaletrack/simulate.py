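"""Synthetic whale biologging datasets.

The generator emits data with the exact statistical structure the
track-reconstruction model assumes: a 1-Hz dive-cycling movement trace in the
water frame; a velocity-correction drift that is a Gaussian random walk with
variance sigma^2 * elapsed-time, held constant within a dive cycle and
stepped at surfacings (the scale at which the model observes it); Fastloc-GPS
fixes at surfacings with satellite-count-dependent scaled-t errors; visual
range/bearing fixes from a pursuing boat with Normal percent-range and
wrapped-Cauchy bearing errors; and a flow-noise level series log-linearly
tied to speed-through-water so the sensor pipeline can re-estimate speed.

Defaults mirror the field conditions: fix rates of a few tenths per minute,
a >=30 s minimum GPS interval, satellite counts drawn with the stationary-test
bin proportions (11/13/16/18/17/24 % for 4/5/6/7/8/>8), process SDs around
0.01 m/s, and a boat standing off a few hundred metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import (GpsErrorModel, VisualErrorModel,
                        reference_gps_error_model, reference_visual_error_model)
from .deadreckon import DrVelocity
from .geoframe import LocalFrame, local_to_geodetic, wrap_angle
from .sensors import SensorSeries
from .ssm import FixSeries

__all__ = [
    "SimConfig",
    "TruthTrack",
    "SyntheticDataset",
    "simulate_truth",
    "simulate_sensors",
    "simulate_fixes",
    "simulate_dataset",
    "simulate_gps_calibration",
    "simulate_visual_calibration",
]

#: satellite-count proportions observed in the stationary tests (bins 4..>8),
#: with the >8 mass spread uniformly over 9..12
NSAT_VALUES = np.arange(4, 13)
NSAT_PROBS = np.array([0.11, 0.13, 0.16, 0.18, 0.17] + [0.25 / 4] * 4)
NSAT_PROBS = NSAT_PROBS / NSAT_PROBS.sum()


@dataclass
class SimConfig:
    """Scenario parameters for one synthetic deployment."""

    duration: float = 7200.0       # s; >= 600
    # dive cycle (s) and orientation
    surface_duration: float = 30.0
    descent_duration: float = 30.0
    bottom_duration: float = 30.0
    ascent_duration: float = 30.0
    dive_pitch: float = 60.0       # deg, magnitude during ascent/descent
    heading_sd: float = 4.0        # deg per sqrt-s heading random walk
    # velocity-correction process SDs (m/s); defaults are whale 11's
    # posterior means
    sigma_x: float = 0.014
    sigma_y: float = 0.012
    # flow-noise speed physics: log s = beta0 + beta1 L + eps
    beta0: float = -3.0
    beta1: float = 0.05
    sigma_L: float = 0.1
    level_mean: float = 60.0
    level_sd: float = 6.0
    level_corr_time: float = 60.0  # s, AR(1) correlation time of L
    # position fixes
    gps_fix_prob: float = 0.9
    gps_min_interval: float = 30.0
    nsat_values: np.ndarray = field(default_factory=lambda: NSAT_VALUES.copy())
    nsat_probs: np.ndarray = field(default_factory=lambda: NSAT_PROBS.copy())
    visual_interval: float = 120.0
    vis_lrf_prob: float = 0.3      # laser-range-finder share of visual fixes
    boat_standoff: float = 200.0   # m
    noise_scale: float = 1.0       # 0 disables all observation noise

    def __post_init__(self):
        if self.duration < 600:
            raise ValueError("duration must be at least 600 s")
        if self.beta1 == 0:
            raise ValueError("beta1 = 0 leaves speed unidentifiable from noise level")

    @property
    def cycle(self) -> float:
        return (self.surface_duration + self.descent_duration
                + self.bottom_duration + self.ascent_duration)


@dataclass
class TruthTrack:
    """Ground truth of one synthetic deployment (1-Hz grid)."""

    t: np.ndarray
    depth: np.ndarray
    pitch: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    level: np.ndarray
    v_water: np.ndarray       # (n, 2) water-frame velocity, east/north
    v_cor: np.ndarray         # (n, 2) drift truth
    xy: np.ndarray            # (n, 2) Earth-frame positions
    surfacing_start: np.ndarray  # indices where a surfacing begins

    def dr_velocity(self) -> DrVelocity:
        return DrVelocity(t=self.t, v=self.v_water.copy())


@dataclass
class SyntheticDataset:
    truth: TruthTrack
    sensors: SensorSeries
    fixes: FixSeries
    config: SimConfig
    seed: int | None


def _ar1_series(n, mean, sd, corr_time, rng):
    phi = np.exp(-1.0 / corr_time)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(mean, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + eps[i - 1]
    return x


def simulate_truth(config: SimConfig, seed=None) -> TruthTrack:
    """Simulate the 1-Hz true movement trace and drift path.

    Flow-noise level drives speed (log-linearly, with lognormal scatter
    sigma_L); pitch and depth follow a surface/descent/bottom/ascent cycle;
    heading is a wrapped Gaussian random walk.  The velocity correction is
    constant within each dive cycle and jumps at surfacing starts with
    variance sigma^2 times the elapsed time, i.e. a Gaussian random walk
    observed at the surfacing scale.
    """
    rng = np.random.default_rng(seed)
    n = int(round(config.duration))
    t = np.arange(n, dtype=float)

    level = _ar1_series(n, config.level_mean, config.level_sd,
                        config.level_corr_time, rng)
    # lognormal speed scatter around the flow-noise relation; correlated over
    # ~10 s (flow-noise residuals are not white at 1 Hz)
    eps = _ar1_series(n, 0.0, config.sigma_L, 10.0, rng) if config.sigma_L > 0 \
        else np.zeros(n)
    speed = np.exp(config.beta0 + config.beta1 * level + eps)

    heading = np.empty(n)
    heading[0] = rng.uniform(-180.0, 180.0)
    steps = rng.normal(0.0, config.heading_sd, size=n - 1)
    heading[1:] = heading[0] + np.cumsum(steps)
    heading = wrap_angle(heading)

    # dive-cycle state machine for pitch/depth
    depth = np.zeros(n)
    pitch = np.zeros(n)
    surf_start = [0]
    c = config
    phase_of = []
    tc = 0.0
    for i in range(n):
        ph = tc % c.cycle
        if ph < c.surface_duration:
            phase = "surface"
        elif ph < c.surface_duration + c.descent_duration:
            phase = "descent"
        elif ph < c.surface_duration + c.descent_duration + c.bottom_duration:
            phase = "bottom"
        else:
            phase = "ascent"
        phase_of.append(phase)
        tc += 1.0
    sp = np.sin(np.radians(c.dive_pitch))
    for i in range(1, n):
        phase = phase_of[i]
        prev = depth[i - 1]
        if phase == "surface":
            depth[i] = 0.0
            pitch[i] = 0.0
            if phase_of[i - 1] != "surface":
                surf_start.append(i)
        elif phase == "descent":
            pitch[i] = -c.dive_pitch
            depth[i] = prev + speed[i] * sp
        elif phase == "bottom":
            pitch[i] = 0.0
            depth[i] = prev
        else:  # ascent
            rise = speed[i] * sp
            if prev - rise <= 0.0:
                depth[i] = 0.0
                pitch[i] = 0.0
            else:
                pitch[i] = c.dive_pitch
                depth[i] = prev - rise

    h = np.radians(heading)
    horiz = speed * np.cos(np.radians(pitch))
    v_water = np.column_stack([horiz * np.sin(h), horiz * np.cos(h)])

    # drift: RW at the surfacing scale, constant in between
    surf_start = np.asarray(sorted(set(surf_start)), dtype=int)
    v_cor = np.empty((n, 2))
    sig = np.array([c.sigma_x, c.sigma_y])
    cur = rng.normal(0.0, 0.02, size=2)
    last = 0
    v_cor[:] = cur
    for s in surf_start[1:]:
        cur = cur + rng.normal(size=2) * sig * np.sqrt(s - last)
        v_cor[s:] = cur
        last = s

    xy = np.zeros((n, 2))
    np.cumsum((v_water + v_cor)[:-1], axis=0, out=xy[1:])
    return TruthTrack(t=t, depth=depth, pitch=pitch, heading=heading, speed=speed,
                      level=level, v_water=v_water, v_cor=v_cor, xy=xy,
                      surfacing_start=surf_start)


def simulate_sensors(truth: TruthTrack, config: SimConfig) -> SensorSeries:
    """Sensor record read off the truth.

    Depth, pitch and heading are exact (a highly accurate sensor suite); the
    flow-noise level is the series that drove the speed, so the pipeline's
    log-linear regression of depth-rate speed on level re-estimates
    (beta0, beta1) without attenuation and a residual SD near sigma_L.
    """
    return SensorSeries(t=truth.t.copy(), depth=truth.depth.copy(),
                        pitch=truth.pitch.copy(), heading=truth.heading.copy(),
                        noise_level=truth.level.copy())


def _wrapped_cauchy_deg(rho, size, rng):
    if rho == 0:
        return rng.uniform(-180.0, 180.0, size=size)
    draws = stats.wrapcauchy.rvs(rho, size=size, random_state=rng)
    return wrap_angle(np.degrees(draws))


def _boat_track(truth: TruthTrack, config: SimConfig, rng) -> np.ndarray:
    """Smoothed pursuit of the whale at a standoff distance."""
    n = truth.t.size
    ang = rng.uniform(0, 2 * np.pi)
    boat = np.empty((n, 2))
    boat[0] = truth.xy[0] + config.boat_standoff * np.array([np.sin(ang), np.cos(ang)])
    max_step = 5.0  # m/s boat speed cap
    for i in range(1, n):
        offset = boat[i - 1] - truth.xy[i]
        dist = np.hypot(*offset)
        # steer toward the standoff circle around the whale
        target = truth.xy[i] + offset / max(dist, 1e-9) * config.boat_standoff
        step = target - boat[i - 1]
        d = np.hypot(*step)
        if d > max_step:
            step *= max_step / d
        boat[i] = boat[i - 1] + step
    return boat


def simulate_fixes(truth: TruthTrack, config: SimConfig,
                   gps_model: GpsErrorModel | None = None,
                   vis_model: VisualErrorModel | None = None,
                   seed=None, recenter: bool = True):
    """Emit GPS and visual fixes from the truth.

    GPS fixes occur at surfacing starts (probability ``gps_fix_prob``, at
    least ``gps_min_interval`` apart) with per-dimension scaled-t errors for
    a drawn satellite count; visual fixes occur during surfacings roughly
    every ``visual_interval`` with Normal percent-range and wrapped-Cauchy
    bearing errors from a simulated pursuit boat.  With ``recenter`` the
    coordinates are shifted so the first observation is the origin, matching
    the convention that the local frame is anchored at the first observed
    position.  Returns (fixes, shift) with ``shift`` the applied offset.
    """
    gps_model = gps_model or reference_gps_error_model()
    vis_model = vis_model or reference_visual_error_model()
    rng = np.random.default_rng(seed)
    scale = config.noise_scale

    gps_t, gps_xy, gps_q = [], [], []
    last_fix = -np.inf
    for s in truth.surfacing_start:
        if truth.t[s] - last_fix < config.gps_min_interval:
            continue
        if rng.uniform() > config.gps_fix_prob:
            continue
        nsat = rng.choice(config.nsat_values, p=config.nsat_probs)
        q = int(min(nsat - 3, 6))
        err = np.array([
            stats.t.rvs(df=gps_model.nu["x"][q - 1], scale=gps_model.sigma["x"][q - 1],
                        random_state=rng),
            stats.t.rvs(df=gps_model.nu["y"][q - 1], scale=gps_model.sigma["y"][q - 1],
                        random_state=rng),
        ])
        gps_t.append(truth.t[s])
        gps_xy.append(truth.xy[s] + scale * err)
        gps_q.append(q)
        last_fix = truth.t[s]

    vis_t, vis_r, vis_phi, vis_m, vis_boat = [], [], [], [], []
    boat = _boat_track(truth, config, rng)
    next_vis = config.visual_interval * rng.uniform(0.5, 1.0)
    surfacing = truth.depth < 1.0
    for s in truth.surfacing_start:
        if truth.t[s] < next_vis:
            continue
        i = min(s + int(rng.integers(0, 10)), truth.t.size - 1)
        if not surfacing[i]:
            i = s
        dxy = truth.xy[i] - boat[i]
        r = float(np.hypot(*dxy))
        if r < 1.0:
            continue
        phi = float(np.degrees(np.arctan2(dxy[0], dxy[1])))
        m = 2 if rng.uniform() < config.vis_lrf_prob else 1
        r_obs = r * (1.0 + scale * rng.normal(0.0, vis_model.sigma_r[m] / 100.0))
        phi_obs = wrap_angle(phi + scale * _wrapped_cauchy_deg(vis_model.rho, None, rng))
        vis_t.append(truth.t[i])
        vis_r.append(max(r_obs, 1.0))
        vis_phi.append(float(phi_obs))
        vis_m.append(m)
        vis_boat.append(boat[i])
        next_vis = truth.t[i] + config.visual_interval

    fixes = FixSeries.from_parts(
        gps_t=gps_t, gps_xy=np.array(gps_xy).reshape(-1, 2), gps_q=gps_q,
        vis_t=vis_t, vis_r=vis_r, vis_phi=vis_phi, vis_method=vis_m,
        vis_boat_xy=np.array(vis_boat).reshape(-1, 2),
    )
    shift = np.zeros(2)
    if recenter and len(fixes):
        if fixes.kind[0] == "gps":
            shift = -fixes.xy[0].copy()
        else:
            b = np.radians(fixes.phi[0])
            shift = -(fixes.boat_xy[0] + fixes.r[0] * np.array([np.sin(b), np.cos(b)]))
        fixes.xy += shift
        fixes.boat_xy += shift
    return fixes, shift


def simulate_dataset(config: SimConfig | None = None, seed=None,
                     gps_model: GpsErrorModel | None = None,
                     vis_model: VisualErrorModel | None = None) -> SyntheticDataset:
    """One full synthetic deployment; all randomness flows from ``seed``.

    The truth track is shifted into the frame anchored at the first observed
    position, so truth and fixes share coordinates.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_truth, s_fix = ss.spawn(2)
    truth = simulate_truth(config, s_truth)
    sensors = simulate_sensors(truth, config)
    fixes, shift = simulate_fixes(truth, config, gps_model, vis_model, seed=s_fix)
    truth.xy = truth.xy + shift
    return SyntheticDataset(truth=truth, sensors=sensors, fixes=fixes,
                            config=config, seed=seed)


# ---------------------------------------------------------------------------
# calibration-test data


def simulate_gps_calibration(gps_model: GpsErrorModel | None = None,
                             n_per_bin: int = 500, loggers=("L1", "L2", "L3"),
                             origin=(69.68, 18.99), seed=None) -> pd.DataFrame:
    """Stationary-logger test records with known scaled-t errors.

    Returns a frame with columns (lat, lon, nsat, residual, logger_id)
    emulating loggers at a fixed position; residuals are drawn so a small
    fraction exceeds the >30 exclusion threshold.
    """
    gps_model = gps_model or reference_gps_error_model()
    rng = np.random.default_rng(seed)
    frame = LocalFrame(origin_lat=origin[0], origin_lon=origin[1])
    rows = []
    for li, logger in enumerate(loggers):
        base = np.array([30.0 * li, -20.0 * li])  # loggers spaced apart
        for q in range(1, 7):
            nsat = 3 + q if q < 6 else 9 + rng.integers(0, 4, size=n_per_bin)
            nsat = np.broadcast_to(nsat, (n_per_bin,))
            ex = stats.t.rvs(df=gps_model.nu["x"][q - 1], scale=gps_model.sigma["x"][q - 1],
                             size=n_per_bin, random_state=rng)
            ey = stats.t.rvs(df=gps_model.nu["y"][q - 1], scale=gps_model.sigma["y"][q - 1],
                             size=n_per_bin, random_state=rng)
            lat, lon = local_to_geodetic(base[0] + ex, base[1] + ey, frame)
            resid = rng.exponential(8.0, size=n_per_bin)
            rows.append(pd.DataFrame({
                "lat": lat, "lon": lon, "nsat": nsat, "residual": resid,
                "logger_id": logger,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_visual_calibration(vis_model: VisualErrorModel | None = None,
                                n: int = 220, seed=None) -> pd.DataFrame:
    """Buoy-test records: true and estimated range/bearing pairs."""
    vis_model = vis_model or reference_visual_error_model()
    rng = np.random.default_rng(seed)
    truth_r = np.exp(rng.uniform(np.log(50.0), np.log(1000.0), size=n))
    est_r = truth_r * (1.0 + rng.normal(vis_model.mu_r / 100.0,
                                        vis_model.sigma_r[1] / 100.0, size=n))
    truth_b = rng.uniform(-180.0, 180.0, size=n)
    est_b = wrap_angle(truth_b + vis_model.mu_phi
                       + _wrapped_cauchy_deg(vis_model.rho, n, rng))
    return pd.DataFrame({
        "true_range_m": truth_r, "est_range_m": est_r,
        "true_bearing_deg": truth_b, "est_bearing_deg": est_b,
    })
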