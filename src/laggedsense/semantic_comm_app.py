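"""Daily aggregates: semantic-location durations, communication, app use.

Semantic labels are collected during assessment weeks as (centroid,
category) pairs; between assessment weeks they are propagated to newly
observed location clusters by nearest labelled centroid.  Daily durations
credit one 5-minute sampling interval per stationary fix (or foreground
app sample); dwell episodes shorter than the 10-minute visit rule
(fewer than 3 consecutive fixes in a cluster) are credited to no category.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort_io import APP_CATEGORIES, SEMANTIC_CATEGORIES
from .gps_features import (FIX_INTERVAL_S, LocationClusterSet,
                           StationaryLabeledTrack, haversine_km)

logger = logging.getLogger("laggedsense")

MATCH_RADIUS_M = 200.0
#: a visit counts only with at least this many consecutive fixes (>=15 min)
MIN_VISIT_FIXES = 3

COMM_FEATURES = ["calls_n_in", "calls_n_out", "calls_total_seconds",
                 "sms_n_in", "sms_n_out", "sms_total_chars"]
APP_FEATURES = ["app_active_min", "app_information_min", "app_social_min"]
SEMANTIC_FEATURES = [f"sem_{c}_min" for c in SEMANTIC_CATEGORIES if c != "other"]


def local_date(t: pd.Series, tz_offset_hours: float = 0.0) -> pd.Series:
    """Calendar date after shifting UTC timestamps to local time."""
    return (t + pd.to_timedelta(tz_offset_hours, unit="h")).dt.date


def propagate_semantic_labels(label_map: pd.DataFrame,
                              clusters: LocationClusterSet,
                              match_radius_m: float = MATCH_RADIUS_M) -> list[str]:
    """Category per cluster: nearest labelled centroid within the match
    radius, else "other".  Ties break by distance then lexicographic
    category.  Idempotent and deterministic."""
    if clusters.k == 0:
        return []
    if label_map is None or len(label_map) == 0:
        logger.warning("propagate_semantic_labels: empty label map, "
                       "all clusters -> other")
        return ["other"] * clusters.k

    lm = label_map.sort_values("category", kind="stable").reset_index(drop=True)
    out = []
    for clat, clon in clusters.centroids:
        d_m = haversine_km(clat, clon,
                           lm["centroid_lat"].to_numpy(float),
                           lm["centroid_lon"].to_numpy(float)) * 1000
        i = int(np.argmin(d_m))  # first occurrence = lexicographically least category on ties
        out.append(str(lm.at[i, "category"]) if d_m[i] <= match_radius_m
                   else "other")
    return out


def _visit_episodes(labels: np.ndarray) -> np.ndarray:
    """Mask of fixes belonging to runs of >= MIN_VISIT_FIXES equal labels."""
    n = len(labels)
    keep = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if j - i >= MIN_VISIT_FIXES:
            keep[i:j] = True
        i = j
    return keep


def daily_semantic_durations(track: StationaryLabeledTrack,
                             clusters: LocationClusterSet,
                             cluster_categories: list[str],
                             tz_offset_hours: float = 0.0) -> pd.DataFrame:
    """Minutes per semantic category per local day.

    Credits FIX_INTERVAL per stationary fix whose cluster is labelled,
    counting only dwell episodes of at least MIN_VISIT_FIXES consecutive
    fixes in the same cluster.  Returns one row per day with the
    ``sem_<category>_min`` columns ("other" is dropped downstream).
    """
    cols = [f"sem_{c}_min" for c in SEMANTIC_CATEGORIES]
    stat = track.stationary
    if len(stat) == 0 or clusters.k == 0:
        return pd.DataFrame(columns=["date", *cols])
    labels = clusters.labels
    keep = _visit_episodes(labels)
    cats = np.array([cluster_categories[c] for c in labels])
    dates = local_date(stat["t"].reset_index(drop=True), tz_offset_hours).to_numpy()

    df = pd.DataFrame({"date": dates[keep], "category": cats[keep]})
    if len(df) == 0:
        return pd.DataFrame(columns=["date", *cols])
    mins = (df.groupby(["date", "category"]).size() * (FIX_INTERVAL_S / 60.0))
    wide = mins.unstack(fill_value=0.0)
    for c in SEMANTIC_CATEGORIES:
        if c not in wide.columns:
            wide[c] = 0.0
    wide = wide[list(SEMANTIC_CATEGORIES)]
    wide.columns = cols
    return wide.reset_index()


def daily_comm_aggregates(events: pd.DataFrame,
                          tz_offset_hours: float = 0.0,
                          date=None) -> pd.DataFrame:
    """Per-day sums of call/SMS counts, call seconds and message characters.

    ``date`` restricts the output to a single local day when given.
    """
    if len(events) == 0:
        out = pd.DataFrame(columns=["date", *COMM_FEATURES])
        return out
    ev = events.copy()
    ev["date"] = local_date(ev["t"], tz_offset_hours)
    rows = []
    for d, g in ev.groupby("date"):
        calls = g[g["kind"] == "call"]
        sms = g[g["kind"] == "sms"]
        rows.append({
            "date": d,
            "calls_n_in": int((calls["direction"] == "incoming").sum()),
            "calls_n_out": int((calls["direction"] == "outgoing").sum()),
            "calls_total_seconds": float(calls["magnitude"].sum()),
            "sms_n_in": int((sms["direction"] == "incoming").sum()),
            "sms_n_out": int((sms["direction"] == "outgoing").sum()),
            "sms_total_chars": float(sms["magnitude"].sum()),
        })
    out = pd.DataFrame(rows)
    if date is not None:
        out = out[out["date"] == date].reset_index(drop=True)
    return out


def categorize_apps(app_ids: pd.Series, category_map: dict[str, str]) -> pd.Series:
    """Map app ids to {active, information, social, other}; unmapped -> other."""
    cat = app_ids.map(category_map).fillna("other")
    bad = set(cat.unique()) - set(APP_CATEGORIES)
    if bad:
        raise ValueError(f"category map assigns unknown categories: {sorted(bad)}")
    return cat


def daily_app_durations(samples: pd.DataFrame,
                        category_map: dict[str, str],
                        tz_offset_hours: float = 0.0,
                        date=None) -> pd.DataFrame:
    """Minutes per app category per local day (5 min credit per sample)."""
    cols = [f"app_{c}_min" for c in APP_CATEGORIES]
    if len(samples) == 0:
        return pd.DataFrame(columns=["date", *cols])
    df = pd.DataFrame({
        "date": local_date(samples["t"], tz_offset_hours),
        "category": categorize_apps(samples["app_id"], category_map).to_numpy(),
    })
    mins = df.groupby(["date", "category"]).size() * (FIX_INTERVAL_S / 60.0)
    wide = mins.unstack(fill_value=0.0)
    for c in APP_CATEGORIES:
        if c not in wide.columns:
            wide[c] = 0.0
    wide = wide[list(APP_CATEGORIES)]
    wide.columns = cols
    out = wide.reset_index()
    if date is not None:
        out = out[out["date"] == date].reset_index(drop=True)
    return out
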