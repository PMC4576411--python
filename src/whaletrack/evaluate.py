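"""Cross-validation of track-reconstruction methods.

Held-out Fastloc-GPS fixes measure how well each track type predicts
out-of-set positions: the state-space model's mean posterior track, linear
interpolation between GPS fixes, linear interpolation between visual fixes,
and forced-point dead-reckoning computed with constant speed or with the
flow-noise speed.  Two designs are supported: leaving out every 10th GPS fix
(10 folds, each fix validated once) and leaving out alternating blocks of
five consecutive fixes (10 offset iterations, 50 % omitted each time, each
fix validated five times).  Errors are Euclidean distances in the local
frame, pooled over folds and averaged per satellite bin.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from .calibrate import GpsErrorModel, VisualErrorModel
from .deadreckon import (DrVelocity, forced_point_track, linear_interpolation_track,
                         segment_displacements)
from .ssm import FixSeries, McmcConfig, fit_mcmc, posterior_mean_track

__all__ = ["crossval", "positional_error", "plot_crossval", "CV_METHODS"]

CV_METHODS = ("ssm_mean", "interp_gps", "interp_visual",
              "forced_constant_speed", "forced_flow_speed")


def positional_error(track_t, track_xy, fix_t, fix_xy) -> float:
    """Euclidean distance between a fix and the track at its time
    (nearest 1-Hz sample)."""
    track_t = np.asarray(track_t, dtype=float)
    if fix_t < track_t[0] - 0.5 or fix_t > track_t[-1] + 0.5:
        raise ValueError("fix time outside the track span")
    i = int(np.clip(np.round(fix_t - track_t[0]), 0, track_t.size - 1))
    d = np.asarray(track_xy)[i] - np.asarray(fix_xy, dtype=float)
    return float(np.hypot(d[0], d[1]))


def _visual_positions(fixes: FixSeries):
    """Visual fixes converted to planar positions via boat + range/bearing."""
    v = fixes.kind == "visual"
    b = np.radians(fixes.phi[v])
    xy = fixes.boat_xy[v] + fixes.r[v, None] * np.column_stack([np.sin(b), np.cos(b)])
    return fixes.t[v], xy


def _folds(n_gps: int, mode: str):
    """Yield validation masks over the GPS fix indices."""
    idx = np.arange(n_gps)
    if mode == "single_10pct":
        for k in range(10):
            yield idx % 10 == k
    elif mode == "block5_50pct":
        for offset in range(10):
            yield ((idx + offset) // 5) % 2 == 0
    else:
        raise ValueError(f"unknown cross-validation mode: {mode}")


def crossval(fixes: FixSeries, v: DrVelocity, gps_model: GpsErrorModel,
             vis_model: VisualErrorModel | None = None,
             mode: str = "single_10pct",
             mcmc_config: McmcConfig | None = None,
             constant_speed: float | None = None,
             align_window: float = 5.0) -> pd.DataFrame:
    """Cross-validate the five track types against held-out GPS fixes.

    Per fold, each track type is rebuilt from the training fixes only (the
    visual-interpolation baseline additionally drops visual fixes in the
    held-out surfacings or block intervals) and evaluated at every validation
    GPS fix.  Returns a frame with columns (method, q, n, mean_m, sem_m),
    validation fixes pooled over folds before per-bin averaging.
    """
    mcmc_config = mcmc_config or McmcConfig(iterations=6000, burn_in=2000, thin=4, seed=0)
    gps_mask = fixes.kind == "gps"
    gps_idx = np.flatnonzero(gps_mask)
    if gps_idx.size < 20:
        raise ValueError("need at least 20 GPS fixes for cross-validation")

    if constant_speed is None:
        speeds = np.hypot(v.v[:, 0], v.v[:, 1])
        constant_speed = float(np.mean(speeds))
    unit = np.zeros_like(v.v)
    norm = np.hypot(v.v[:, 0], v.v[:, 1])
    ok = norm > 1e-9
    unit[ok] = v.v[ok] / norm[ok, None]
    v_const = DrVelocity(t=v.t, v=unit * constant_speed, delta=v.delta)

    records = []
    for fold_no, val_mask in enumerate(_folds(gps_idx.size, mode)):
        val_obs = gps_idx[val_mask]
        if val_obs.size == 0 or gps_idx.size - val_obs.size < 2:
            warnings.warn(f"fold {fold_no}: too few fixes, skipped", stacklevel=2)
            continue
        keep = np.ones(len(fixes), dtype=bool)
        keep[val_obs] = False
        train = fixes.subset(keep)

        # visual fixes in the held-out surfacings / block intervals excluded
        vis_keep = keep.copy()
        if mode == "single_10pct":
            for i in val_obs:
                vis_keep &= ~((fixes.kind == "visual") & (fixes.t == fixes.t[i]))
        else:
            val_in_gps = np.flatnonzero(val_mask)
            runs = np.split(val_in_gps, np.flatnonzero(np.diff(val_in_gps) > 1) + 1)
            for run in runs:
                if run.size:
                    blk_t = fixes.t[gps_idx[run]]
                    lo, hi = blk_t.min() - align_window, blk_t.max() + align_window
                    vis_keep &= ~((fixes.kind == "visual")
                                  & (fixes.t >= lo) & (fixes.t <= hi))
        train_vis = fixes.subset(vis_keep)

        tracks = {}
        gps_train = train.subset(train.kind == "gps")
        if len(gps_train) >= 2:
            tracks["interp_gps"] = linear_interpolation_track(
                gps_train.t, gps_train.xy, v.t)
            tracks["forced_constant_speed"] = forced_point_track(
                v_const, gps_train.t, gps_train.xy)
            tracks["forced_flow_speed"] = forced_point_track(
                v, gps_train.t, gps_train.xy)
        vt, vxy = _visual_positions(train_vis)
        if vt.size >= 2:
            tracks["interp_visual"] = linear_interpolation_track(vt, vxy, v.t)

        times = np.unique(train.t)
        d, delta = segment_displacements(v, times)
        post = fit_mcmc(train, d, delta, gps_model, vis_model, config=mcmc_config)
        tracks["ssm_mean"] = posterior_mean_track(post, v)

        for i in val_obs:
            for method, track in tracks.items():
                err = positional_error(v.t, track, fixes.t[i], fixes.xy[i])
                records.append({"method": method, "q": int(fixes.q[i]),
                                "fold": fold_no, "error_m": err})

    raw = pd.DataFrame.from_records(records)
    if raw.empty:
        raise RuntimeError("no validation errors computed")
    out = (raw.groupby(["method", "q"])["error_m"]
           .agg(n="size", mean_m="mean", sem_m=lambda e: e.std(ddof=1) / np.sqrt(len(e)))
           .reset_index())
    out.attrs["raw"] = raw
    return out


def plot_crossval(table: pd.DataFrame, path=None):
    """Mean +/- 2 SEM cross-validation error per satellite bin and method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    markers = dict(zip(CV_METHODS, "oxsv^"))
    for k, method in enumerate(CV_METHODS):
        sub = table[table["method"] == method].sort_values("q")
        if sub.empty:
            continue
        ax.errorbar(sub["q"] + 0.05 * (k - 2), sub["mean_m"], 2 * sub["sem_m"],
                    marker=markers.get(method, "o"), linestyle="none",
                    capsize=3, label=method)
    ax.set_xlabel("satellite bin (4, 5, 6, 7, 8, >8)")
    ax.set_ylabel("cross-validation error (m, mean ± 2 s.e.m.)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
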