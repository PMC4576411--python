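"""Tag-stream pre-processing into the 1-Hz sensor record.

The dead-reckoning inputs are depth, body pitch, compass heading and an
uncalibrated flow-noise level, all on a common 1-Hz grid.  Raw 50-Hz streams
are decimated with a DC-accurate anti-aliasing filter; pitch and heading can
be derived from tri-axial acceleration and magnetic field with the standard
tilt-compensated compass construction.  Speed-through-water is estimated from
depth rate during steep dives, regressed log-linearly on flow-noise level,
and predicted from noise over the whole record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SensorSeries",
    "SpeedModel",
    "decimate_to_1hz",
    "pitch_heading_from_accel_mag",
    "lowpass_zero_delay",
    "speed_from_depth_rate",
    "fit_speed_model",
    "predict_speed",
    "interpolate_shallow_speed",
]


@dataclass
class SensorSeries:
    """1-Hz tag record: time (s), depth (m), pitch (deg), heading (deg),
    flow-noise level (uncalibrated) and speed-through-water (m/s)."""

    t: np.ndarray
    depth: np.ndarray
    pitch: np.ndarray
    heading: np.ndarray
    noise_level: np.ndarray | None = None
    speed: np.ndarray | None = None
    delta: float = 1.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("depth", "pitch", "heading", "noise_level", "speed"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"{name} misaligned with time grid")
                setattr(self, name, v)
        if np.any(np.abs(self.pitch) > 90.0 + 1e-9):
            raise ValueError("pitch outside [-90, 90] degrees")
        if self.speed is not None and np.nanmin(self.speed) < 0:
            raise ValueError("speed must be non-negative")

    def __len__(self):
        return self.t.size


@dataclass
class SpeedModel:
    """Log-linear flow-noise speed model: log(s) ~ N(b0 + b1 L, sigma_L)."""

    beta0: float
    beta1: float
    sigma_L: float
    n: int = 0
    se_beta0: float = field(default=np.nan)
    se_beta1: float = field(default=np.nan)

    def __post_init__(self):
        if self.sigma_L < 0:
            raise ValueError("residual SD must be non-negative")


def decimate_to_1hz(x, fs: float):
    """Decimate a regularly sampled stream to 1 Hz.

    Polyphase FIR resampling with a unity-DC-gain linear-phase anti-aliasing
    filter; a constant input returns the same constant exactly and ramps are
    preserved (edges handled by linear-extension padding).
    """
    x = np.asarray(x, dtype=float)
    ratio = float(fs)
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("sampling rate must be an integer multiple of 1 Hz")
    ratio = int(round(ratio))
    if ratio == 1:
        return x.copy()
    return signal.resample_poly(x, up=1, down=ratio, padtype="line")


def pitch_heading_from_accel_mag(accel, mag, declination: float = 0.0):
    """Pitch and heading from tag-frame acceleration and magnetic field.

    Tag axes: x caudo-rostral (forward), y lateral (right), z dorso-ventral,
    with a level, stationary tag reading accel = (0, 0, -1) g.  Pitch is the
    angle of the longitudinal axis above the horizontal; heading is the
    tilt-corrected compass direction (degrees clockwise from north, plus an
    optional declination offset).  Returns (pitch_deg, heading_deg,
    unreliable) where ``unreliable`` flags near-vertical samples (|p| > 89
    degrees) whose heading is ill-conditioned.
    """
    a = np.asarray(accel, dtype=float).reshape(-1, 3)
    m = np.asarray(mag, dtype=float).reshape(-1, 3)
    if np.any(np.linalg.norm(a, axis=1) == 0) or np.any(np.linalg.norm(m, axis=1) == 0):
        raise ValueError("zero-norm accelerometer or magnetometer sample")
    ax, ay, az = a.T
    pitch = np.arctan2(ax, np.hypot(ay, az))
    roll = np.arctan2(-ay, -az)
    sr, cr = np.sin(roll), np.cos(roll)
    sp, cp = np.sin(pitch), np.cos(pitch)
    mx, my, mz = m.T
    # de-rotate the magnetometer into the horizontal plane (gimballed compass)
    mh_x = mx * cp + my * sp * sr + mz * sp * cr
    mh_y = my * cr - mz * sr
    heading = np.arctan2(-mh_y, mh_x) + np.radians(declination)
    from .geoframe import wrap_angle

    pitch_deg = np.degrees(pitch)
    heading_deg = wrap_angle(np.degrees(heading))
    unreliable = np.abs(pitch_deg) > 89.0
    if a.shape[0] == 1:
        return float(pitch_deg[0]), float(heading_deg[0]), bool(unreliable[0])
    return pitch_deg, np.atleast_1d(heading_deg), unreliable


def lowpass_zero_delay(x, fc: float = 0.15, fs: float = 1.0):
    """Zero-group-delay FIR low-pass (forward-backward filtered).

    Removes fluke-stroke-band oscillation from pitch and noise-level series
    before the speed regression.  DC gain is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 6.0 / fc * fs:
        raise ValueError("series too short for the requested cut-off")
    numtaps = int(4.0 * fs / fc) | 1  # odd, ~4 cycles of the cut-off
    taps = signal.firwin(numtaps, fc, fs=fs)
    return signal.filtfilt(taps, [1.0], x, padtype="even")


def speed_from_depth_rate(depth, pitch, min_pitch: float = 50.0, delta: float = 1.0):
    """Speed-through-water from depth rate during steep ascents/descents.

    s = |d(depth)/dt| / |sin(pitch)| wherever |pitch| > ``min_pitch`` degrees
    (central-difference depth rate); NaN elsewhere.
    """
    depth = np.asarray(depth, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    rate = np.gradient(depth, delta)
    steep = np.abs(pitch) > min_pitch
    s = np.full_like(depth, np.nan)
    s[steep] = np.abs(rate[steep]) / np.abs(np.sin(np.radians(pitch[steep])))
    return s


def fit_speed_model(speeds, levels) -> SpeedModel:
    """OLS of log speed on flow-noise level; residual SD on the log scale.

    Non-positive speed estimates (depth-rate outliers) are dropped before the
    regression.
    """
    import statsmodels.api as sm

    s = np.asarray(speeds, dtype=float)
    L = np.asarray(levels, dtype=float)
    keep = np.isfinite(s) & np.isfinite(L) & (s > 0)
    s, L = s[keep], L[keep]
    if s.size < 30:
        raise ValueError("need at least 30 positive speed estimates")
    if np.ptp(L) == 0:
        raise ValueError("flow-noise level is constant; slope unidentifiable")
    res = sm.OLS(np.log(s), sm.add_constant(L)).fit()
    resid_sd = float(np.sqrt(res.ssr / res.nobs)) if res.nobs > 2 else 0.0
    return SpeedModel(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        sigma_L=resid_sd,
        n=int(res.nobs),
        se_beta0=float(res.bse[0]),
        se_beta1=float(res.bse[1]),
    )


def predict_speed(levels, model: SpeedModel):
    """Median-scale speed prediction s = exp(b0 + b1 L)."""
    L = np.asarray(levels, dtype=float)
    return np.exp(model.beta0 + model.beta1 * L)


def interpolate_shallow_speed(speed, depth, threshold: float = 5.0):
    """Replace speed during shallow (<``threshold`` m) periods.

    Flow noise is contaminated by surface noise at shallow depth, so within
    each maximal shallow run the speed is linearly interpolated between the
    last preceding and first following deep-water values; runs touching the
    record ends are held at the nearest defined value.
    """
    speed = np.asarray(speed, dtype=float).copy()
    depth = np.asarray(depth, dtype=float)
    shallow = depth < threshold
    if not shallow.any():
        return speed
    n = speed.size
    idx = np.flatnonzero(np.diff(np.concatenate(([False], shallow, [False])).astype(int)))
    for start, stop in idx.reshape(-1, 2):  # [start, stop) shallow runs
        left = start - 1
        right = stop  # first deep sample after the run
        if left < 0 and right >= n:
            continue
        if left < 0:
            speed[start:stop] = speed[right]
        elif right >= n:
            speed[start:stop] = speed[left]
        else:
            w = np.arange(1, stop - start + 1) / (stop - start + 1)
            speed[start:stop] = speed[left] + w * (speed[right] - speed[left])
    return speed
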