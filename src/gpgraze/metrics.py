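"""Grazing-personality behaviour metrics.

Eighteen daily metrics are computed from terrain-annotated GPS fixes per
cow-day, then aggregated across a deployment into 35 per-cow variables: the
across-day mean of every daily metric plus the across-day coefficient of
variation (CV) of all of them except the farm-centred mean elevation.  A
shipped transformation map (square root, natural log, cube root, square or
identity per variable) mirrors the standard variable list row for row.

Daily metrics
-------------
dist_ho        horizontal distance, sum of planar steps (m/d)
dist_ve        vertical distance, sum of |elevation changes| (m/d)
ele_range      daily max - min elevation (m)
ele_gain       sum of positive elevation changes (m/d)
ele_mean_farm  daily mean elevation minus the farm grand mean (m)
ele85_farm     daily 85th elevation quantile minus the farm grand mean (m)
ele15_farm     daily 15th elevation quantile minus the farm grand mean (m)
slope_mean / slope_max / slope85 / slope15   daily slope statistics (deg)
hr_mcp         100% minimum-convex-polygon home range (ha/d)
sp_tortuosity  dist_ho / hr_mcp (m/ha)
adj_dist_ho    dist_ho - herd minimum that day + 3500 (m/d)
adj_ele_mean   mean elevation - herd minimum that day + 350 (m)
rel_ele_range  cow elevation range / herd elevation range (0-1)
rel_ele_mean   (mean elevation - herd min) / herd elevation range (0-1)
rel_slope_range  cow slope range / herd slope range (0-1)

The two "adjusted" anchors (3500 m, 350 m) keep the herd-relative variables
on the rough scale of the raw means.  Quantiles use linear interpolation
between order statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

__all__ = [
    "DAILY_METRICS",
    "CV_METRICS",
    "PROFILE_VARIABLES",
    "TRANSFORM_MAP",
    "daily_distance_metrics",
    "daily_elevation_slope_stats",
    "daily_home_range_mcp",
    "daily_tortuosity",
    "compute_daily_metrics",
    "herd_day_context",
    "adjusted_and_relative_metrics",
    "farm_centred_metrics",
    "aggregate_cow",
    "compute_cow_profiles",
    "apply_transforms",
]

ADJ_DIST_ANCHOR_M = 3500.0
ADJ_ELE_ANCHOR_M = 350.0

DAILY_METRICS = [
    "dist_ho", "dist_ve", "ele_range", "ele_gain",
    "ele_mean_farm", "ele85_farm", "ele15_farm",
    "slope_mean", "slope_max", "slope85", "slope15",
    "hr_mcp", "sp_tortuosity",
    "adj_dist_ho", "adj_ele_mean",
    "rel_ele_range", "rel_ele_mean", "rel_slope_range",
]
# every daily metric gets a CV except the farm-centred mean elevation
CV_METRICS = [m for m in DAILY_METRICS if m != "ele_mean_farm"]
PROFILE_VARIABLES = DAILY_METRICS + [f"{m}_cv" for m in CV_METRICS]

TRANSFORM_MAP = {
    "dist_ho": "sqrt",
    "dist_ve": "log",
    "ele_range": "identity",
    "ele_gain": "sqrt",
    "ele_mean_farm": "identity",
    "ele85_farm": "identity",
    "ele15_farm": "identity",
    "slope_mean": "sqrt",
    "slope_max": "cbrt",
    "slope85": "cbrt",
    "slope15": "cbrt",
    "hr_mcp": "log",
    "sp_tortuosity": "log",
    "adj_dist_ho": "identity",
    "adj_ele_mean": "square",
    "rel_ele_range": "cbrt",
    "rel_ele_mean": "cbrt",
    "rel_slope_range": "cbrt",
    "dist_ho_cv": "identity",
    "dist_ve_cv": "log",
    "ele_range_cv": "log",
    "ele_gain_cv": "log",
    "ele85_farm_cv": "log",
    "ele15_farm_cv": "log",
    "slope_mean_cv": "log",
    "slope_max_cv": "log",
    "slope85_cv": "log",
    "slope15_cv": "log",
    "hr_mcp_cv": "log",
    "sp_tortuosity_cv": "log",
    "adj_dist_ho_cv": "log",
    "adj_ele_mean_cv": "cbrt",
    "rel_ele_range_cv": "log",
    "rel_ele_mean_cv": "cbrt",
    "rel_slope_range_cv": "log",
}

_FORWARD = {
    "identity": lambda x: x,
    "log": np.log,
    "sqrt": np.sqrt,
    "cbrt": np.cbrt,
    "square": np.square,
}
_INVERSE = {
    "identity": lambda x: x,
    "log": np.exp,
    "sqrt": np.square,
    "cbrt": lambda x: x**3,
    "square": np.sqrt,
}


# --------------------------------------------------------------------- daily
def daily_distance_metrics(day_fixes: pd.DataFrame) -> dict:
    """dist_ho, dist_ve and ele_gain for one cow-day (>= 2 fixes)."""
    if len(day_fixes) < 2:
        raise ValueError("need at least 2 fixes for distance metrics")
    de = np.diff(day_fixes["easting_m"].to_numpy(float))
    dn = np.diff(day_fixes["northing_m"].to_numpy(float))
    dz = np.diff(day_fixes["elevation_m"].to_numpy(float))
    return {
        "dist_ho": float(np.hypot(de, dn).sum()),
        "dist_ve": float(np.abs(dz).sum()),
        "ele_gain": float(np.clip(dz, 0, None).sum()),
    }


def daily_elevation_slope_stats(day_fixes: pd.DataFrame) -> dict:
    """Elevation/slope summary statistics for one cow-day."""
    z = day_fixes["elevation_m"].to_numpy(float)
    s = day_fixes["slope_deg"].to_numpy(float)
    return {
        "ele_range": float(z.max() - z.min()),
        "ele_mean": float(z.mean()),
        "ele85": float(np.quantile(z, 0.85)),
        "ele15": float(np.quantile(z, 0.15)),
        "slope_mean": float(s.mean()),
        "slope_max": float(s.max()),
        "slope_min": float(s.min()),
        "slope85": float(np.quantile(s, 0.85)),
        "slope15": float(np.quantile(s, 0.15)),
    }


def daily_home_range_mcp(day_fixes: pd.DataFrame) -> float:
    """100% minimum-convex-polygon area of the day's fixes, hectares.

    Fewer than 3 unique fixes, or collinear fixes, have no positive hull
    area; the day is treated as missing (NaN) for this metric so tortuosity
    never divides by zero.
    """
    pts = day_fixes[["easting_m", "northing_m"]].drop_duplicates().to_numpy(float)
    if len(pts) < 3:
        return float("nan")
    area_m2 = MultiPoint(pts).convex_hull.area
    if area_m2 <= 0:
        return float("nan")
    return area_m2 / 1e4


def daily_tortuosity(dist_ho: float, hr_mcp: float) -> float:
    """Movement tortuosity (m/ha): daily distance over daily MCP area."""
    if not np.isfinite(hr_mcp) or hr_mcp <= 0:
        return float("nan")
    return dist_ho / hr_mcp


def compute_daily_metrics(clean_fixes: pd.DataFrame) -> pd.DataFrame:
    """One row of intra-cow daily metrics per cow-day.

    Expects QC'd fixes annotated with ``elevation_m`` and ``slope_deg``.
    Herd-relative and farm-centred variables are added later
    (:func:`adjusted_and_relative_metrics`, :func:`farm_centred_metrics`)
    because they need same-day herd context and the final analysis cohort.
    """
    t = pd.to_datetime(clean_fixes["timestamp_iso8601"])
    dates = t.dt.date
    rows = []
    for (cow, date), grp in clean_fixes.groupby(["cow_id", dates], sort=True):
        if len(grp) < 2:
            continue
        row = {
            "cow_id": cow,
            "farm_id": grp["farm_id"].iloc[0],
            "genotype": grp["genotype"].iloc[0] if "genotype" in grp else "",
            "date": date,
            "n_fixes": len(grp),
        }
        row.update(daily_distance_metrics(grp))
        row.update(daily_elevation_slope_stats(grp))
        row["hr_mcp"] = daily_home_range_mcp(grp)
        row["sp_tortuosity"] = daily_tortuosity(row["dist_ho"], row["hr_mcp"])
        row["ele_min"] = float(grp["elevation_m"].min())
        row["ele_max"] = float(grp["elevation_m"].max())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- herd-level
def herd_day_context(daily: pd.DataFrame) -> pd.DataFrame:
    """Same-day herd context per farm-day, over the retained cows.

    ``herd_min_dist`` is the minimum cow daily distance; elevation and slope
    extrema are taken over the cows' daily extrema.  Farm-days with fewer
    than two cows are dropped (herd-relative metrics undefined).
    """
    g = daily.groupby(["farm_id", "date"])
    ctx = g.agg(
        n_cows=("cow_id", "nunique"),
        herd_min_dist=("dist_ho", "min"),
        herd_min_ele=("ele_min", "min"),
        herd_max_ele=("ele_max", "max"),
        herd_min_slope=("slope_min", "min"),
        herd_max_slope=("slope_max", "max"),
    ).reset_index()
    ctx["herd_ele_range"] = ctx["herd_max_ele"] - ctx["herd_min_ele"]
    ctx["herd_slope_range"] = ctx["herd_max_slope"] - ctx["herd_min_slope"]
    return ctx.loc[ctx["n_cows"] >= 2].reset_index(drop=True)


def adjusted_and_relative_metrics(
    daily: pd.DataFrame, context: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Add the herd-anchored and herd-relative daily variables.

    adj_dist_ho = dist_ho - herd_min_dist + 3500
    adj_ele_mean = ele_mean - herd_min_ele + 350
    rel_ele_range = ele_range / herd_ele_range
    rel_ele_mean = (ele_mean - herd_min_ele) / herd_ele_range
    rel_slope_range = (slope_max - slope_min) / herd_slope_range

    Cow-days without herd context (single-cow farm-days) or with a zero herd
    range get NaN for the affected variables.
    """
    if context is None:
        context = herd_day_context(daily)
    out = daily.merge(context, on=["farm_id", "date"], how="left")
    out["adj_dist_ho"] = out["dist_ho"] - out["herd_min_dist"] + ADJ_DIST_ANCHOR_M
    out["adj_ele_mean"] = out["ele_mean"] - out["herd_min_ele"] + ADJ_ELE_ANCHOR_M
    ele_rng = out["herd_ele_range"].where(out["herd_ele_range"] > 0)
    slope_rng = out["herd_slope_range"].where(out["herd_slope_range"] > 0)
    out["rel_ele_range"] = out["ele_range"] / ele_rng
    out["rel_ele_mean"] = (out["ele_mean"] - out["herd_min_ele"]) / ele_rng
    out["rel_slope_range"] = (out["slope_max"] - out["slope_min"]) / slope_rng
    return out


def farm_centred_metrics(
    daily: pd.DataFrame, cohort_cow_ids=None
) -> pd.DataFrame:
    """Centre elevation statistics on the farm grand mean elevation.

    The grand mean is the mean of the daily mean elevations over all
    cow-days of the analysis cohort on that farm (``cohort_cow_ids=None``
    means every cow present).  It must be recomputed whenever cohort
    membership changes, so this is the last per-day step before
    aggregation.
    """
    out = daily.copy()
    basis = out if cohort_cow_ids is None else out.loc[out["cow_id"].isin(set(cohort_cow_ids))]
    if not len(basis):
        raise ValueError("empty analysis cohort: cannot centre farm elevations")
    grand = basis.groupby("farm_id")["ele_mean"].mean().rename("farm_grand_ele")
    out = out.merge(grand, on="farm_id", how="left")
    out["ele_mean_farm"] = out["ele_mean"] - out["farm_grand_ele"]
    out["ele85_farm"] = out["ele85"] - out["farm_grand_ele"]
    out["ele15_farm"] = out["ele15"] - out["farm_grand_ele"]
    return out


# --------------------------------------------------------------- aggregation
def aggregate_cow(cow_daily: pd.DataFrame, min_days: int = 7) -> dict:
    """Aggregate one cow's daily table into the 35 profile variables.

    Per metric the mean over valid days; per CV metric the sample
    (n-1) coefficient of variation over the same days.  Days missing a
    specific metric (e.g. undefined tortuosity) are omitted from that
    metric's aggregation only.  A metric with across-day mean exactly zero
    has an undefined CV (NaN, flagged for imputation downstream).
    """
    if len(cow_daily) < min_days:
        raise ValueError(
            f"cow {cow_daily['cow_id'].iloc[0]!r}: {len(cow_daily)} valid days "
            f"< required {min_days}"
        )
    row = {
        "cow_id": cow_daily["cow_id"].iloc[0],
        "farm_id": cow_daily["farm_id"].iloc[0],
        "genotype": cow_daily["genotype"].iloc[0],
        "n_days": len(cow_daily),
    }
    for m in DAILY_METRICS:
        vals = cow_daily[m].dropna().to_numpy(float)
        row[m] = vals.mean() if len(vals) else float("nan")
        if m in CV_METRICS:
            if len(vals) >= 2 and row[m] != 0:
                row[f"{m}_cv"] = vals.std(ddof=1) / row[m]
            else:
                row[f"{m}_cv"] = float("nan")
    return row


def compute_cow_profiles(
    daily: pd.DataFrame,
    cohort_cow_ids=None,
    min_days: int = 7,
) -> pd.DataFrame:
    """Daily metric table -> per-cow profile table (35 variables + labels).

    ``daily`` must already carry the herd-relative columns; the farm-centred
    columns are (re)computed here against ``cohort_cow_ids`` so the centring
    always reflects the current analysis cohort.
    """
    full = farm_centred_metrics(daily, cohort_cow_ids)
    if cohort_cow_ids is not None:
        full = full.loc[full["cow_id"].isin(set(cohort_cow_ids))]
    rows = [
        aggregate_cow(grp, min_days=min_days)
        for _, grp in full.groupby("cow_id", sort=True)
        if len(grp) >= min_days
    ]
    return pd.DataFrame(rows, columns=["cow_id", "farm_id", "genotype", "n_days"] + PROFILE_VARIABLES)


# ---------------------------------------------------------------- transforms
def apply_transforms(
    profiles: pd.DataFrame,
    transform_map: dict | None = None,
    on_invalid: str = "error",
) -> tuple[pd.DataFrame, list]:
    """Apply the per-variable transformation map to a profile table.

    ``on_invalid`` controls log/sqrt of non-positive values: ``"error"``
    (default) raises; ``"offset"`` adds half the smallest positive observed
    value before a log of zeros (negatives still raise); ``"skip"`` leaves
    that variable untransformed.  Returns ``(transformed table, provenance
    log)`` where the log records every variable whose transform was offset
    or skipped.
    """
    tmap = TRANSFORM_MAP if transform_map is None else transform_map
    out = profiles.copy()
    log = []
    for var, name in tmap.items():
        if var not in out.columns:
            continue
        fn = _FORWARD[name]
        col = out[var].to_numpy(float)
        finite = col[np.isfinite(col)]
        needs_positive = name in ("log", "sqrt")
        if needs_positive and len(finite) and finite.min() <= 0:
            if on_invalid == "error":
                raise ValueError(
                    f"{name} transform of non-positive values in {var!r}"
                )
            if on_invalid == "offset" and finite.min() == 0 and name == "log":
                pos = finite[finite > 0]
                eps = 0.5 * pos.min() if len(pos) else 1.0
                out[var] = fn(col + eps)
                log.append({"variable": var, "action": "offset", "offset": eps})
                continue
            log.append({"variable": var, "action": "skipped", "transform": name})
            continue
        out[var] = fn(col)
    return out, log


def inverse_transform(values, name: str):
    """Inverse of a named transform (positive branch for square)."""
    return _INVERSE[name](values)
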