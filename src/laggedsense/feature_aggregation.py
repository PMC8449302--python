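"""Two-week feature windows, full-sample standardisation, unit-weighted groups.

Every check-in anchors two windows: *preceding* (the 14 days ending the day
before the check-in) and *proceeding* (the 14 days starting on the check-in
day).  GPS features are computed over the whole window; communication, app
and semantic-location features are daily values averaged over the window's
valid days.  Base features are then z-scored across the full sample of
participant-windows and averaged into the unit-weighted feature groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import SCHEDULE, CohortBundle
from .gps_features import (GPS_FEATURES, cluster_locations,
                           compute_gps_features, label_stationary)
from .semantic_comm_app import (APP_FEATURES, COMM_FEATURES,
                                SEMANTIC_FEATURES, daily_app_durations,
                                daily_comm_aggregates,
                                daily_semantic_durations, local_date,
                                propagate_semantic_labels)

logger = logging.getLogger("laggedsense")

WINDOW_DAYS = 14
MIN_VALID_DAYS = 7

BASE_FEATURES: list[str] = (GPS_FEATURES + SEMANTIC_FEATURES
                            + COMM_FEATURES + APP_FEATURES)

#: unit-weighted feature groups: group value = mean of member z-scores
FEATURE_GROUPS: dict[str, list[str]] = {
    "Locations": ["n_clusters", "location_variance"],
    "Time": ["entropy", "normalized_entropy", "circadian_movement"],
    "Transitions": ["total_distance", "avg_velocity"],
    "Home": ["sem_home_min"],
    "Work": ["sem_work_min"],
    "Shopping": ["sem_shopping_min"],
    "Social": ["sem_social_min"],
    "Religious": ["sem_religious_min"],
    "Exercise": ["sem_exercise_min"],
    "Calls": ["calls_n_in", "calls_n_out", "calls_total_seconds"],
    "Text Messages": ["sms_n_in", "sms_n_out", "sms_total_chars"],
    "Active Apps": ["app_active_min"],
    "Information Apps": ["app_information_min"],
    "Social Apps": ["app_social_min"],
}

ALL_CHECKIN_WEEKS = tuple(sorted(set().union(*map(set, SCHEDULE.values()))))


@dataclass
class FeatureConfig:
    window_days: int = WINDOW_DAYS
    min_valid_days: int = MIN_VALID_DAYS
    speed_threshold_kmh: float = 1.0
    max_cluster_radius_m: float = 500.0
    match_radius_m: float = 200.0
    app_category_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def window_span(checkin_week: int, side: str,
                window_days: int = WINDOW_DAYS) -> tuple[int, int]:
    """Inclusive (first, last) study-day index of the window.

    Study day = 7 × week at the check-in.  Preceding windows end the day
    before the check-in; proceeding windows start on the check-in day.
    """
    d = 7 * checkin_week
    if side == "preceding":
        return d - window_days, d - 1
    if side == "proceeding":
        return d, d + window_days - 1
    raise ValueError(f"side must be 'preceding' or 'proceeding', got {side!r}")


def build_window(gps: pd.DataFrame, daily: pd.DataFrame,
                 label_map: pd.DataFrame, checkin_week: int, side: str,
                 start_date, tz_offset_hours: float,
                 config: FeatureConfig) -> dict:
    """Base-feature values for one participant × check-in × side.

    ``daily`` holds per-day comm/app aggregates (columns ``day`` plus the
    daily feature columns).  GPS features come from a window-level
    computation; daily features are means over days with sensor data.
    Returns a dict of base features plus ``valid_days``; all features are
    NaN when fewer than ``min_valid_days`` days have data.
    """
    first, last = window_span(checkin_week, side, config.window_days)
    row: dict = {"week": checkin_week, "side": side}

    if len(gps):
        day = (local_date(gps["t"], tz_offset_hours)
               .map(lambda d: (d - start_date).days))
        in_win = gps[(day >= first) & (day <= last)]
    else:
        in_win = gps
    valid_days = int(in_win["t"].dt.date.nunique()) if len(in_win) else 0
    row["valid_days"] = valid_days
    if valid_days < config.min_valid_days:
        row.update({f: np.nan for f in BASE_FEATURES})
        return row

    track = label_stationary(in_win, config.speed_threshold_kmh)
    clusters = cluster_locations(track, config.max_cluster_radius_m,
                                 seed=config.seed)
    row.update(compute_gps_features(track, clusters))

    cats = propagate_semantic_labels(label_map, clusters, config.match_radius_m)
    sem = daily_semantic_durations(track, clusters, cats, tz_offset_hours)
    # mean over the window's sensed days; a sensed day without qualifying
    # visits (or without events, below) counts as 0, not missing
    for f in SEMANTIC_FEATURES:
        row[f] = (float(sem[f].sum()) if len(sem) else 0.0) / valid_days

    sub = daily.loc[(daily["day"] >= first) & (daily["day"] <= last)]
    for f in COMM_FEATURES + APP_FEATURES:
        vals = sub[f] if f in sub.columns else pd.Series(dtype=float)
        row[f] = float(vals.sum()) / valid_days
    return row


def _participant_daily(comm: pd.DataFrame, apps: pd.DataFrame,
                       start_date, tz: float,
                       config: FeatureConfig) -> pd.DataFrame:
    frames = []
    c = daily_comm_aggregates(comm, tz)
    if len(c):
        frames.append(c.set_index("date"))
    a = daily_app_durations(apps, config.app_category_map, tz)
    if len(a):
        frames.append(a.set_index("date"))
    if not frames:
        return pd.DataFrame(columns=["day", *COMM_FEATURES, *APP_FEATURES])
    daily = pd.concat(frames, axis=1).fillna(0.0).reset_index()
    daily["day"] = daily["date"].map(lambda d: (d - start_date).days)
    return daily


def extract_feature_windows(bundle: CohortBundle,
                            config: FeatureConfig | None = None) -> pd.DataFrame:
    """Base-feature table: one row per participant × check-in week × side."""
    config = config or FeatureConfig()
    rows = []
    demo = bundle.demographics.set_index(
        bundle.demographics["participant_id"].astype(str))
    for pid in bundle.participant_ids:
        tz = float(demo.at[pid, "tz_offset_hours"]) if "tz_offset_hours" in demo else 0.0
        start = pd.to_datetime(demo.at[pid, "start_date"]).date()
        gps = bundle.gps[bundle.gps["participant_id"].astype(str) == pid]
        comm = bundle.comm[bundle.comm["participant_id"].astype(str) == pid]
        apps = bundle.apps[bundle.apps["participant_id"].astype(str) == pid]
        labels = bundle.semantic_labels[
            bundle.semantic_labels["participant_id"].astype(str) == pid]
        daily = _participant_daily(comm, apps, start, tz, config)
        for week in ALL_CHECKIN_WEEKS:
            for side in ("preceding", "proceeding"):
                row = build_window(gps, daily, labels, week, side,
                                   start, tz, config)
                row["participant_id"] = pid
                rows.append(row)
    cols = ["participant_id", "week", "side", "valid_days", *BASE_FEATURES]
    return pd.DataFrame(rows)[cols]


def standardize_features(windows: pd.DataFrame,
                         feature_cols: list[str] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score each base feature across the full sample of windows.

    Uses the n−1 denominator; missing entries stay missing; zero-variance
    features standardise to all zeros with a warning.  Returns the
    standardised table and a (feature, mean, sd) frame for reproducibility.
    """
    feature_cols = feature_cols or [c for c in BASE_FEATURES if c in windows.columns]
    out = windows.copy()
    stats = []
    for c in feature_cols:
        vals = out[c].astype(float)
        mean = vals.mean()
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"feature {c!r} has zero variance; "
                          "standardized to zeros", stacklevel=2)
            out[c] = np.where(vals.notna(), 0.0, np.nan)
            stats.append({"feature": c, "mean": mean, "sd": 0.0})
        else:
            out[c] = (vals - mean) / sd
            stats.append({"feature": c, "mean": mean, "sd": sd})
    return out, pd.DataFrame(stats)


def aggregate_groups(z_windows: pd.DataFrame,
                     groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Unit-weighted group values: mean of member z-scores.

    A group is missing only when all its members are missing; otherwise it
    is the mean of the present members.
    """
    groups = groups or FEATURE_GROUPS
    for g, members in groups.items():
        unknown = [m for m in members if m not in z_windows.columns]
        if unknown:
            raise ValueError(f"group {g!r} refers to unknown feature(s) {unknown}")
    keep = [c for c in ("participant_id", "week", "side", "valid_days")
            if c in z_windows.columns]
    out = z_windows[keep].copy()
    for g, members in groups.items():
        out[g] = z_windows[members].astype(float).mean(axis=1, skipna=True)
    return out


def compute_group_windows(bundle: CohortBundle,
                          config: FeatureConfig | None = None) -> pd.DataFrame:
    """Full chain: extract → standardise → aggregate into the 14 groups."""
    base = extract_feature_windows(bundle, config)
    z, _ = standardize_features(base)
    return aggregate_groups(z)
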