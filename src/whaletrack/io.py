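"""File formats: CSV readers/writers, error-model files, posterior export.

Timestamps in files are either ISO-8601 UTC strings (column ``time``) or
numeric seconds since track start (column ``t_s``); internally everything is
seconds since track start.  Error models travel as YAML key-value files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import GpsErrorModel, VisualErrorModel
from .geoframe import LocalFrame, geodetic_to_local, local_to_geodetic
from .sensors import SensorSeries
from .ssm import FixSeries, SsmPosterior

__all__ = [
    "read_time_column", "read_sensor_csv", "write_sensor_csv",
    "read_gps_test_csv", "read_visual_test_csv",
    "write_error_models", "read_error_models",
    "read_fixes_csv", "write_fixes_csv",
    "write_track_csv", "write_posterior_summary", "write_posterior_netcdf",
]


def read_time_column(df: pd.DataFrame) -> np.ndarray:
    """Seconds since the first row from a ``t_s`` or ISO ``time`` column."""
    if "t_s" in df.columns:
        return df["t_s"].to_numpy(dtype=float)
    if "time" in df.columns:
        ts = pd.to_datetime(df["time"], utc=True)
        return (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    raise ValueError("no time column: expected 't_s' (seconds) or 'time' (ISO-8601)")


def read_sensor_csv(path) -> SensorSeries:
    df = pd.read_csv(path)
    required = {"depth_m", "pitch_deg", "heading_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensor file missing columns: {sorted(missing)}")
    return SensorSeries(
        t=read_time_column(df),
        depth=df["depth_m"].to_numpy(),
        pitch=df["pitch_deg"].to_numpy(),
        heading=df["heading_deg"].to_numpy(),
        noise_level=df["noise_level"].to_numpy() if "noise_level" in df else None,
        speed=df["speed_ms"].to_numpy() if "speed_ms" in df else None,
    )


def write_sensor_csv(series: SensorSeries, path) -> None:
    df = pd.DataFrame({"t_s": series.t, "depth_m": series.depth,
                       "pitch_deg": series.pitch, "heading_deg": series.heading})
    if series.noise_level is not None:
        df["noise_level"] = series.noise_level
    if series.speed is not None:
        df["speed_ms"] = series.speed
    df.to_csv(path, index=False)


def read_gps_test_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"lat", "lon", "nsat", "residual", "logger_id"} - set(df.columns)
    if missing:
        raise ValueError(f"GPS test file missing columns: {sorted(missing)}")
    return df


def read_visual_test_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"est_range_m", "true_range_m", "est_bearing_deg",
               "true_bearing_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"visual test file missing columns: {sorted(missing)}")
    return df


def write_error_models(path, gps: GpsErrorModel | None = None,
                       vis: VisualErrorModel | None = None) -> None:
    doc = {}
    if gps is not None:
        doc["gps"] = {
            "mu": {d: [float(v) for v in gps.mu[d]] for d in ("x", "y")},
            "sigma": {d: [float(v) for v in gps.sigma[d]] for d in ("x", "y")},
            "nu": {d: [float(v) for v in gps.nu[d]] for d in ("x", "y")},
            "se": {k: [float(x) for x in v] for k, v in gps.se.items()},
        }
    if vis is not None:
        doc["visual"] = {
            "mu_r_pct": float(vis.mu_r),
            "sigma_r_pct": {int(k): float(v) for k, v in vis.sigma_r.items()},
            "mu_phi_deg": float(vis.mu_phi),
            "rho": float(vis.rho),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_error_models(path):
    doc = yaml.safe_load(Path(path).read_text())
    gps = vis = None
    if "gps" in doc:
        g = doc["gps"]
        gps = GpsErrorModel(mu=g["mu"], sigma=g["sigma"], nu=g["nu"],
                            se=g.get("se", {}))
    if "visual" in doc:
        v = doc["visual"]
        vis = VisualErrorModel(mu_r=v["mu_r_pct"],
                               sigma_r={int(k): x for k, x in v["sigma_r_pct"].items()},
                               mu_phi=v["mu_phi_deg"], rho=v["rho"])
    return gps, vis


def write_fixes_csv(fixes: FixSeries, path, frame: LocalFrame | None = None) -> None:
    df = pd.DataFrame({
        "t_s": fixes.t, "kind": fixes.kind,
        "x_m": fixes.xy[:, 0], "y_m": fixes.xy[:, 1], "nsat_bin": fixes.q,
        "range_m": fixes.r, "bearing_deg": fixes.phi, "range_method": fixes.method,
        "boat_x_m": fixes.boat_xy[:, 0], "boat_y_m": fixes.boat_xy[:, 1],
    })
    if frame is not None:
        g = fixes.kind == "gps"
        lat = np.full(len(fixes), np.nan)
        lon = np.full(len(fixes), np.nan)
        if g.any():
            lat[g], lon[g] = local_to_geodetic(fixes.xy[g, 0], fixes.xy[g, 1], frame)
        df["lat"], df["lon"] = lat, lon
    df.to_csv(path, index=False)


def read_fixes_csv(path, frame: LocalFrame | None = None) -> FixSeries:
    df = pd.read_csv(path)
    t = read_time_column(df)
    if "x_m" in df.columns:
        xy = df[["x_m", "y_m"]].to_numpy()
        boat = df[["boat_x_m", "boat_y_m"]].to_numpy() if "boat_x_m" in df else np.full((len(df), 2), np.nan)
    elif frame is not None and "lat" in df.columns:
        x, y = geodetic_to_local(df["lat"].to_numpy(), df["lon"].to_numpy(), frame)
        xy = np.column_stack([x, y])
        boat = np.full((len(df), 2), np.nan)
        if "boat_lat" in df.columns:
            bx, by = geodetic_to_local(df["boat_lat"].to_numpy(),
                                       df["boat_lon"].to_numpy(), frame)
            boat = np.column_stack([bx, by])
    else:
        raise ValueError("fixes file needs x_m/y_m columns, or lat/lon plus a frame")
    q = df["nsat_bin"].to_numpy(int) if "nsat_bin" in df else np.zeros(len(df), int)
    return FixSeries(
        t=t, kind=df["kind"].to_numpy(object), xy=xy, q=q,
        r=df.get("range_m", pd.Series(np.nan, index=df.index)).to_numpy(float),
        phi=df.get("bearing_deg", pd.Series(np.nan, index=df.index)).to_numpy(float),
        method=df.get("range_method", pd.Series(0, index=df.index)).to_numpy(int),
        boat_xy=boat,
    )


def write_track_csv(t, xy, path, frame: LocalFrame | None = None, depth=None) -> None:
    df = pd.DataFrame({"t_s": np.asarray(t, float),
                       "x_m": np.asarray(xy)[:, 0], "y_m": np.asarray(xy)[:, 1]})
    if depth is not None:
        df["depth_m"] = depth
    if frame is not None:
        df["lat"], df["lon"] = local_to_geodetic(df["x_m"].to_numpy(),
                                                 df["y_m"].to_numpy(), frame)
    df.to_csv(path, index=False)


def write_posterior_summary(post: SsmPosterior, path) -> None:
    """Posterior mean/SD/95 % CI and split R-hat per parameter, as CSV."""
    rows = []

    def add(name, flat, rh):
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append({"parameter": name, "mean": flat.mean(), "sd": flat.std(ddof=1),
                     "ci2.5": lo, "ci97.5": hi, "rhat": float(rh)})

    for k, dim in enumerate("xy"):
        add(f"sigma_{dim}", post.flat("sigma")[:, k], post.rhat["sigma"][k])
        add(f"x1_{dim}", post.flat("x1")[:, k], post.rhat["x1"][k])
    v = post.flat("v_cor")
    for j in range(v.shape[1]):
        for k, dim in enumerate("xy"):
            add(f"v_cor[{j + 1}]_{dim}", v[:, j, k], post.rhat["v_cor"][j, k])
    pd.DataFrame(rows).to_csv(path, index=False)


def write_posterior_netcdf(post: SsmPosterior, path) -> None:
    import xarray as xr

    ds = xr.Dataset(
        {
            "x1": (("chain", "draw", "dim"), post.x1),
            "v_cor": (("chain", "draw", "segment", "dim"), post.v_cor),
            "sigma": (("chain", "draw", "dim"), post.sigma),
        },
        coords={"dim": ["x", "y"], "segment_time": ("segment", post.times[:-1])},
        attrs={"iterations": post.config.iterations, "burn_in": post.config.burn_in,
               "thin": post.config.thin, "chains": post.config.chains,
               "seed": -1 if post.config.seed is None else post.config.seed},
    )
    ds.to_netcdf(path, engine="scipy")
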