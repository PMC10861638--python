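"""Trajectory quality control.

Cleans raw fix tables into analysis-ready, terrain-annotated daily traces:
terrain annotation (elevation, slope, aspect per fix), speed/turn based GPS
outlier removal, calendar-day segmentation with a handling-day exclusion
calendar, the 75% fix-rate rule (216 of 288 scheduled fixes at a 5-minute
interval), the seven-valid-day deployment minimum, and hill-day labelling
(herd-median fix slope strictly greater than 8 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .terrain import TerrainModel

__all__ = [
    "annotate_terrain",
    "compute_step_quantities",
    "remove_gps_outliers",
    "segment_days",
    "filter_fix_rate",
    "filter_deployment_length",
    "label_hill_days",
    "qc_cow",
    "qc_herd",
    "QCReport",
]

HILL_SLOPE_THRESHOLD_DEG = 8.0
MIN_FIX_FRACTION = 0.75
MIN_VALID_DAYS = 7


@dataclass
class QCReport:
    """Bookkeeping for a QC run: every input fix is either retained or logged."""

    n_input_fixes: int = 0
    n_outlier_fixes: int = 0
    days_excluded: dict = field(default_factory=lambda: {"handling": 0, "low_fix_rate": 0})
    cows_dropped_short_deployment: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input_fixes": self.n_input_fixes,
            "n_outlier_fixes": self.n_outlier_fixes,
            "days_excluded": dict(self.days_excluded),
            "cows_dropped_short_deployment": list(self.cows_dropped_short_deployment),
        }


def annotate_terrain(
    fixes: pd.DataFrame, terrain: TerrainModel, method: str = "nearest"
) -> pd.DataFrame:
    """Annotate each fix with elevation (m), slope and aspect (degrees).

    Sampling is from the terrain's elevation grid and its derived Horn
    slope/aspect grids; ``method`` is ``'nearest'`` (default, the convention
    of raster point extraction) or ``'bilinear'``.  Fixes more than half a
    cell outside the terrain extent raise a :class:`ValueError` naming the
    offending fix.
    """
    out = fixes.copy()
    e = out["easting_m"].to_numpy(float)
    n = out["northing_m"].to_numpy(float)
    out["elevation_m"] = np.asarray(terrain.sample(e, n, "elevation", method))
    out["slope_deg"] = np.asarray(terrain.sample(e, n, "slope", method))
    out["aspect_deg"] = np.asarray(terrain.sample(e, n, "aspect", method))
    return out


def compute_step_quantities(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-fix step length (m), duration (s), speed (m/s) and signed turning
    angle (degrees) between consecutive retained fixes of one cow.

    The step quantities at row *i* describe the move *into* fix *i*; the
    first fix has no inbound step (NaN).  Distances use easting/northing
    only (planar metres).
    """
    out = fixes.copy()
    t = pd.to_datetime(out["timestamp_iso8601"])
    if not t.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted increasing within a cow")
    de = out["easting_m"].diff()
    dn = out["northing_m"].diff()
    out["step_m"] = np.hypot(de, dn)
    out["step_duration_s"] = t.diff().dt.total_seconds()
    out["speed_mps"] = out["step_m"] / out["step_duration_s"]
    head = np.arctan2(dn, de)
    turn = np.degrees(np.diff(head.to_numpy(), prepend=np.nan))
    turn = (turn + 180.0) % 360.0 - 180.0
    out["turn_deg"] = turn
    return out


def remove_gps_outliers(
    fixes: pd.DataFrame,
    max_speed: float = 2.5,
    max_turn_at_speed: float = 170.0,
    spike_speed: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove fixes with physically implausible speed/turn.

    A fix is removed when its implied inbound AND outbound speeds both
    exceed ``max_speed`` (a teleported lone spike), or when its turning
    angle exceeds ``max_turn_at_speed`` while both adjacent speeds exceed
    ``spike_speed`` (the out-and-back signature of a position spike).  Step
    quantities are recomputed after each pass until no fix is removed, so
    the operation is idempotent.

    Returns ``(retained, removal_log)``; their row counts sum to the input.
    """
    if len(fixes) < 3:
        return compute_step_quantities(fixes), fixes.iloc[0:0].copy()
    work = fixes.reset_index(drop=True)
    removed = []
    while True:
        work = compute_step_quantities(work)
        v_in = work["speed_mps"].to_numpy()
        v_out = np.append(v_in[1:], np.nan)
        turn = np.abs(work["turn_deg"].to_numpy())
        both_fast = (v_in > max_speed) & (v_out > max_speed)
        spike = (
            (turn > max_turn_at_speed)
            & (v_in > spike_speed)
            & (v_out > spike_speed)
        )
        bad = np.nan_to_num(both_fast | spike, nan=False)
        if not bad.any():
            break
        removed.append(work.loc[bad])
        work = work.loc[~bad].reset_index(drop=True)
        if len(work) < 3:
            break
    log = (
        pd.concat(removed, ignore_index=True)
        if removed
        else work.iloc[0:0].copy()
    )
    return work, log


def segment_days(
    fixes: pd.DataFrame,
    exclusion_calendar: pd.DataFrame | None = None,
    tz_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Split one cow's fixes by calendar date and flag handling days.

    ``exclusion_calendar`` is a table with columns ``farm_id, date`` (reason
    optional); matching farm-dates are flagged excluded with reason
    ``"handling"``.  The day boundary is local midnight shifted by
    ``tz_offset_hours``.  Returns a per-day table (one row per DayTrace).
    """
    t = pd.to_datetime(fixes["timestamp_iso8601"])
    if not t.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted increasing within a cow")
    dates = (t + pd.Timedelta(hours=tz_offset_hours)).dt.date
    excluded_dates = set()
    if exclusion_calendar is not None and len(exclusion_calendar):
        cal = exclusion_calendar.copy()
        cal["date"] = pd.to_datetime(cal["date"]).dt.date
        farms = set(fixes["farm_id"].unique())
        excluded_dates = {
            d for f, d in zip(cal["farm_id"], cal["date"]) if f in farms
        }
    rows = []
    for date, grp in fixes.groupby(dates, sort=True):
        handling = date in excluded_dates
        rows.append(
            {
                "cow_id": grp["cow_id"].iloc[0],
                "farm_id": grp["farm_id"].iloc[0],
                "date": date,
                "n_fixes": len(grp),
                "excluded": handling,
                "exclusion_reason": "handling" if handling else "",
            }
        )
    return pd.DataFrame(rows)


def filter_fix_rate(
    day_table: pd.DataFrame,
    scheduled_per_day: int = 288,
    min_fraction: float = MIN_FIX_FRACTION,
) -> pd.DataFrame:
    """Exclude days whose retained fix count is below 75% of scheduled.

    The boundary is inclusive: at the 5-minute schedule of 288 fixes/day a
    day with exactly 216 retained fixes is kept, 215 is excluded.  Days
    already excluded (handling) keep their original reason - each excluded
    day carries exactly one primary reason.
    """
    out = day_table.copy()
    threshold = min_fraction * scheduled_per_day
    low = (out["n_fixes"] < threshold) & ~out["excluded"]
    out.loc[low, "excluded"] = True
    out.loc[low, "exclusion_reason"] = "low_fix_rate"
    out["scheduled_fixes"] = scheduled_per_day
    return out


def filter_deployment_length(
    day_table: pd.DataFrame, min_days: int = MIN_VALID_DAYS
) -> bool:
    """True iff the cow has at least ``min_days`` non-excluded days."""
    return int((~day_table["excluded"]).sum()) >= min_days


def label_hill_days(
    annotated_fixes: pd.DataFrame,
    threshold_deg: float = HILL_SLOPE_THRESHOLD_DEG,
    tz_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Per farm-day hill flag: herd-median fix slope strictly above 8 degrees.

    Operates on the retained, slope-annotated fixes of the whole herd.
    Farm-days with no fixes do not appear (flag undefined).
    """
    t = pd.to_datetime(annotated_fixes["timestamp_iso8601"])
    dates = (t + pd.Timedelta(hours=tz_offset_hours)).dt.date
    grouped = annotated_fixes.groupby([annotated_fixes["farm_id"], dates])[
        "slope_deg"
    ].median()
    out = grouped.reset_index()
    out.columns = ["farm_id", "date", "herd_median_slope_deg"]
    out["hill_day"] = out["herd_median_slope_deg"] > threshold_deg
    return out


def qc_cow(
    fixes: pd.DataFrame,
    terrain: TerrainModel,
    exclusion_calendar: pd.DataFrame | None = None,
    max_speed: float = 2.5,
    max_turn_at_speed: float = 170.0,
    scheduled_per_day: int | None = None,
    sampling: str = "nearest",
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full QC for one cow: annotate, de-spike, segment, filter.

    Returns ``(retained annotated fixes restricted to valid days, day
    table)``; an empty fix frame means the cow failed the deployment-length
    filter.
    """
    if report is None:
        report = QCReport()
    report.n_input_fixes += len(fixes)
    annotated = annotate_terrain(fixes, terrain, method=sampling)
    retained, removal_log = remove_gps_outliers(
        annotated, max_speed=max_speed, max_turn_at_speed=max_turn_at_speed
    )
    report.n_outlier_fixes += len(removal_log)
    if scheduled_per_day is None:
        scheduled_per_day = 288
    days = segment_days(retained, exclusion_calendar)
    days = filter_fix_rate(days, scheduled_per_day=scheduled_per_day)
    for reason, cnt in days.loc[days["excluded"], "exclusion_reason"].value_counts().items():
        report.days_excluded[reason] = report.days_excluded.get(reason, 0) + int(cnt)
    if not filter_deployment_length(days):
        report.cows_dropped_short_deployment.append(fixes["cow_id"].iloc[0])
        return retained.iloc[0:0], days
    valid_dates = set(days.loc[~days["excluded"], "date"])
    t = pd.to_datetime(retained["timestamp_iso8601"]).dt.date
    kept = retained.loc[t.isin(valid_dates)].reset_index(drop=True)
    return kept, days


def qc_herd(
    fixes: pd.DataFrame,
    terrains: dict[str, TerrainModel],
    exclusion_calendar: pd.DataFrame | None = None,
    fix_interval_s: int = 300,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, QCReport]:
    """QC an entire multi-farm fix table.

    Returns ``(clean annotated fixes, day table, hill-day table, report)``.
    """
    report = QCReport()
    scheduled = 86400 // fix_interval_s
    clean_frames, day_frames = [], []
    for cow_id, cow_fixes in fixes.groupby("cow_id", sort=True):
        farm = cow_fixes["farm_id"].iloc[0]
        kept, days = qc_cow(
            cow_fixes.reset_index(drop=True),
            terrains[farm],
            exclusion_calendar,
            scheduled_per_day=scheduled,
            report=report,
            **kwargs,
        )
        if len(kept):
            clean_frames.append(kept)
        day_frames.append(days)
    clean = (
        pd.concat(clean_frames, ignore_index=True)
        if clean_frames
        else fixes.iloc[0:0]
    )
    day_table = pd.concat(day_frames, ignore_index=True) if day_frames else pd.DataFrame()
    hills = label_hill_days(clean) if len(clean) else pd.DataFrame(
        columns=["farm_id", "date", "herd_median_slope_deg", "hill_day"]
    )
    return clean, day_table, hills, report
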