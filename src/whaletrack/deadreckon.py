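"""Dead-reckoning velocities, displacements and baseline track methods.

The whale's horizontal water-frame velocity is reconstructed from
speed-through-water, pitch and compass heading; integrating it gives the
uncorrected ("pseudo") track whose error grows with time.  Per-segment
displacement sums between position-fix times are the inputs to the
state-space process model.  Two baseline track constructions used in
cross-validation also live here: "forced-point" dead-reckoning (stretched
with a constant per-segment velocity bias so it passes through every fix) and
plain linear interpolation between fixes.

Heading convention: compass headings (degrees clockwise from true north) are
accepted as input, and velocity is computed as

    v = s * cos(p) * (sin h, cos h)   in (east, north).

Written with the velocity components as (cos h, sin h), the same expression
holds with the axes read as (north, east); the compass form above is the one
consistent with reporting bearings as the four-quadrant arctangent of
east-over-north displacement, and is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensors import SensorSeries

__all__ = [
    "DrVelocity",
    "dr_velocity",
    "segment_displacements",
    "uncorrected_track",
    "forced_point_track",
    "linear_interpolation_track",
]

_MAX_GAP_S = 10.0
_MAX_GAP_FRACTION = 0.10


@dataclass
class DrVelocity:
    """1-Hz horizontal water-frame velocity: times (s) and (east, north) m/s."""

    t: np.ndarray
    v: np.ndarray
    delta: float = 1.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (self.t.size, 2):
            raise ValueError("velocity must be (n, 2) east/north")


def _fill_speed_gaps(t, s):
    bad = ~np.isfinite(s)
    if not bad.any():
        return s
    if bad.mean() > _MAX_GAP_FRACTION:
        raise ValueError(
            f"{bad.mean():.0%} of speed samples undefined (limit {_MAX_GAP_FRACTION:.0%})"
        )
    # bounded linear interpolation across gaps
    idx = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
    for start, stop in idx.reshape(-1, 2):
        if (stop - start) * np.median(np.diff(t)) > _MAX_GAP_S:
            raise ValueError(f"speed gap of {stop - start} samples exceeds {_MAX_GAP_S} s")
    good = ~bad
    out = s.copy()
    out[bad] = np.interp(t[bad], t[good], s[good])
    return out


def dr_velocity(series: SensorSeries) -> DrVelocity:
    """Water-frame velocity from speed, pitch and heading (Earth-referenced).

    Short speed gaps (<= 10 s) are filled by linear interpolation; a record
    with more than 10 % undefined speed raises.
    """
    if series.speed is None:
        raise ValueError("sensor series has no speed estimates")
    s = _fill_speed_gaps(series.t, series.speed)
    p = np.radians(series.pitch)
    h = np.radians(series.heading)
    horiz = s * np.cos(p)
    return DrVelocity(
        t=series.t, v=np.column_stack([horiz * np.sin(h), horiz * np.cos(h)]),
        delta=series.delta,
    )


def _fix_indices(v: DrVelocity, fix_times) -> np.ndarray:
    """Snap fix times to the nearest 1-Hz sample index."""
    ft = np.asarray(fix_times, dtype=float)
    if np.any(np.diff(ft) <= 0):
        raise ValueError("fix times must be strictly increasing")
    if ft.min() < v.t[0] - v.delta / 2 or ft.max() > v.t[-1] + v.delta / 2:
        raise ValueError("fix time outside the sensor record span")
    idx = np.clip(np.round((ft - v.t[0]) / v.delta).astype(int), 0, v.t.size - 1)
    if np.any(np.diff(idx) == 0):
        raise ValueError("fix times coincide on the 1-Hz grid")
    return idx


def _cumulative_track(v: DrVelocity) -> np.ndarray:
    """Positions from 0 under x_{i+1} = x_i + v_i * delta_i."""
    steps = v.v * v.delta
    track = np.zeros_like(v.v)
    np.cumsum(steps[:-1], axis=0, out=track[1:])
    return track


def segment_displacements(v: DrVelocity, fix_times):
    """Dead-reckoned displacement per inter-fix segment.

    Sums v_i * delta_i over samples in each half-open interval
    [t_j, t_{j+1}), with fix times snapped to the 1-Hz grid.  Returns
    ``(d, delta)`` with d of shape (J-1, 2) and delta the segment durations.
    """
    idx = _fix_indices(v, fix_times)
    cum = _cumulative_track(v)
    d = cum[idx[1:]] - cum[idx[:-1]]
    delta = (idx[1:] - idx[:-1]) * v.delta
    return d, delta


def uncorrected_track(x1, v: DrVelocity) -> np.ndarray:
    """1-Hz dead-reckoning track from initial position ``x1`` (east, north)."""
    return np.asarray(x1, dtype=float) + _cumulative_track(v)


def forced_point_track(v: DrVelocity, fix_times, fix_xy) -> np.ndarray:
    """Dead-reckoning track stretched to pass exactly through every fix.

    Within each inter-fix segment a constant velocity bias
    b_j = (fix_{j+1} - fix_j - d_j) / delta_j is added; before the first and
    after the last fix the nearest segment's bias applies, anchored so the
    track still interpolates the end fixes.
    """
    fix_xy = np.asarray(fix_xy, dtype=float)
    if fix_xy.ndim != 2 or fix_xy.shape[0] < 2:
        raise ValueError("need at least two planar fixes")
    idx = _fix_indices(v, fix_times)
    cum = _cumulative_track(v)
    d = cum[idx[1:]] - cum[idx[:-1]]
    delta = ((idx[1:] - idx[:-1]) * v.delta)[:, None]
    bias = (np.diff(fix_xy, axis=0) - d) / delta

    seg = np.clip(np.searchsorted(idx, np.arange(v.t.size), side="right") - 1, 0, len(idx) - 2)
    anchor_idx = idx[seg]
    dt = (np.arange(v.t.size) - anchor_idx)[:, None] * v.delta
    return fix_xy[seg] + (cum - cum[anchor_idx]) + bias[seg] * dt


def linear_interpolation_track(fix_times, fix_xy, times) -> np.ndarray:
    """Piecewise-linear track through the fixes, constant outside their span."""
    ft = np.asarray(fix_times, dtype=float)
    xy = np.asarray(fix_xy, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need at least two fixes")
    times = np.asarray(times, dtype=float)
    return np.column_stack(
        [np.interp(times, ft, xy[:, 0]), np.interp(times, ft, xy[:, 1])]
    )
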