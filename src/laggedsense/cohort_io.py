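"""Cohort file I/O, schema validation, and demographic summaries.

A cohort lives on disk as one directory per participant, each holding one
UTF-8 CSV per event stream::

    <root>/<participant_id>/gps.csv              t, lat, lon
    <root>/<participant_id>/comm.csv             t, kind, direction, magnitude
    <root>/<participant_id>/apps.csv             t, app_id
    <root>/<participant_id>/assessments.csv      week, measure, total, item_1..item_N
    <root>/<participant_id>/semantic_labels.csv  centroid_lat, centroid_lon, category, week
    <root>/<participant_id>/demographics.csv     age, gender, race, tz_offset_hours, start_date

Timestamps are ISO-8601 UTC.  Item columns are present only on baseline
(week 0) rows.  In memory the cohort is a :class:`CohortBundle` of
cohort-level pandas DataFrames keyed by ``participant_id``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("laggedsense")

# symptom measures: (n items, max per-item score, max total)
MEASURES = {
    "PHQ8": (8, 3, 24),
    "GAD7": (7, 3, 21),
    "SPIN": (17, 4, 68),
}

#: scheduled check-in weeks per measure (week 0 = baseline)
SCHEDULE = {
    "PHQ8": (0, 1, 4, 7, 10, 13, 16),
    "GAD7": (0, 4, 7, 10, 13, 16),
    "SPIN": (0, 4, 7, 10, 13, 16),
}

#: post-baseline check-ins used for lagged change pairs (six PHQ-8
#: check-ins yield five pairs; five GAD-7/SPIN check-ins yield four)
PAIR_WEEKS = {
    "PHQ8": (1, 4, 7, 10, 13, 16),
    "GAD7": (4, 7, 10, 13, 16),
    "SPIN": (4, 7, 10, 13, 16),
}

APP_CATEGORIES = ("active", "information", "social", "other")
SEMANTIC_CATEGORIES = ("home", "work", "shopping", "social",
                       "religious", "exercise", "other")

STREAM_COLUMNS = {
    "gps": ["t", "lat", "lon"],
    "comm": ["t", "kind", "direction", "magnitude"],
    "apps": ["t", "app_id"],
    "semantic_labels": ["centroid_lat", "centroid_lon", "category", "week"],
    "demographics": ["age", "gender", "race", "tz_offset_hours", "start_date"],
}


class SchemaError(ValueError):
    """A stream file is missing a required column."""


class CohortValidationError(ValueError):
    """One or more rows violate a stream invariant."""

    def __init__(self, report: list[dict]):
        self.report = report
        lines = "; ".join(
            f"{r['participant_id']}/{r['stream']} row {r['row']}: {r['error']}"
            for r in report[:10]
        )
        super().__init__(f"{len(report)} validation error(s): {lines}")


@dataclass
class CohortBundle:
    """All streams of a cohort as cohort-level DataFrames.

    ``assessments`` has columns ``participant_id, week, measure, total``;
    ``baseline_items`` is wide, one row per participant with columns
    ``PHQ8_1..8, GAD7_1..7, SPIN_1..17``.
    """

    gps: pd.DataFrame
    comm: pd.DataFrame
    apps: pd.DataFrame
    assessments: pd.DataFrame
    baseline_items: pd.DataFrame
    semantic_labels: pd.DataFrame
    demographics: pd.DataFrame
    truth: dict = field(default_factory=dict)  # synthetic ground truth, if any

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.demographics["participant_id"].astype(str))

    @property
    def n_participants(self) -> int:
        return len(self.demographics)


def item_columns(measure: str) -> list[str]:
    n_items, _, _ = MEASURES[measure]
    return [f"{measure}_{i}" for i in range(1, n_items + 1)]


ALL_ITEM_COLUMNS = sum((item_columns(m) for m in MEASURES), [])


def empty_bundle() -> CohortBundle:
    return CohortBundle(
        gps=pd.DataFrame(columns=["participant_id", "t", "lat", "lon"]),
        comm=pd.DataFrame(columns=["participant_id", "t", "kind",
                                   "direction", "magnitude"]),
        apps=pd.DataFrame(columns=["participant_id", "t", "app_id"]),
        assessments=pd.DataFrame(columns=["participant_id", "week",
                                          "measure", "total"]),
        baseline_items=pd.DataFrame(columns=["participant_id", *ALL_ITEM_COLUMNS]),
        semantic_labels=pd.DataFrame(columns=["participant_id", "centroid_lat",
                                              "centroid_lon", "category", "week"]),
        demographics=pd.DataFrame(columns=["participant_id", *STREAM_COLUMNS["demographics"]]),
    )


# ---------------------------------------------------------------------------
# validation

def _validate_participant(pid: str, streams: dict[str, pd.DataFrame]) -> list[dict]:
    """Row-level invariant checks; returns a list of error records."""
    errors: list[dict] = []

    def err(stream, row, msg):
        errors.append({"participant_id": pid, "stream": stream,
                       "row": int(row), "error": msg})

    gps = streams.get("gps")
    if gps is not None and len(gps):
        bad_lat = gps.index[(gps["lat"] < -90) | (gps["lat"] > 90)]
        for i in bad_lat:
            err("gps", i, f"lat={gps.at[i, 'lat']} out of [-90, 90]")
        bad_lon = gps.index[(gps["lon"] < -180) | (gps["lon"] > 180)]
        for i in bad_lon:
            err("gps", i, f"lon={gps.at[i, 'lon']} out of [-180, 180]")
        t = gps["t"].astype("int64").to_numpy()
        not_increasing = np.where(np.diff(t) <= 0)[0]
        for i in not_increasing:
            err("gps", i + 1, "timestamps not strictly increasing")

    comm = streams.get("comm")
    if comm is not None and len(comm):
        for i in comm.index[comm["magnitude"] < 0]:
            err("comm", i, f"negative magnitude {comm.at[i, 'magnitude']}")
        for i in comm.index[~comm["kind"].isin(["call", "sms"])]:
            err("comm", i, f"unknown kind {comm.at[i, 'kind']!r}")

    assess = streams.get("assessments")
    if assess is not None and len(assess):
        for i, row in assess.iterrows():
            m = row["measure"]
            if m not in MEASURES:
                err("assessments", i, f"unknown measure {m!r}")
                continue
            _, _, max_total = MEASURES[m]
            if not (0 <= row["total"] <= max_total):
                err("assessments", i,
                    f"{m} total {row['total']} out of [0, {max_total}]")
            cols = [c for c in item_columns(m) if c in assess.columns]
            if cols and row[cols].notna().all():
                if int(row[cols].sum()) != int(row["total"]):
                    err("assessments", i,
                        f"{m} items sum to {int(row[cols].sum())}, "
                        f"total is {int(row['total'])}")
    return errors


# ---------------------------------------------------------------------------
# load / save

def load_cohort(root_path: str | Path, strict: bool = True) -> CohortBundle:
    """Load and validate a cohort directory.

    Parameters
    ----------
    root_path
        Directory containing one sub-directory per participant.
    strict
        If True (default) raise :class:`CohortValidationError` when any row
        violates an invariant; if False, attach the error report to the
        returned bundle's ``truth["validation_errors"]`` instead.
    """
    root = Path(root_path)
    part_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.exists() else []
    if not part_dirs:
        logger.warning("load_cohort: no participant directories under %s", root)
        return empty_bundle()

    frames: dict[str, list[pd.DataFrame]] = {k: [] for k in
        ["gps", "comm", "apps", "assessments", "baseline_items",
         "semantic_labels", "demographics"]}
    all_errors: list[dict] = []

    for d in part_dirs:
        pid = d.name
        streams: dict[str, pd.DataFrame] = {}
        for stream, cols in STREAM_COLUMNS.items():
            path = d / f"{stream}.csv"
            if not path.exists():
                continue
            df = pd.read_csv(path, float_precision="round_trip")
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(
                    f"{path}: missing required column(s) {missing}")
            if "t" in df.columns:
                df["t"] = pd.to_datetime(df["t"], utc=True)
            streams[stream] = df
        apath = d / "assessments.csv"
        if apath.exists():
            adf = pd.read_csv(apath, float_precision="round_trip")
            for c in ["week", "measure", "total"]:
                if c not in adf.columns:
                    raise SchemaError(f"{apath}: missing required column(s) ['{c}']")
            streams["assessments"] = adf

        all_errors.extend(_validate_participant(pid, streams))

        for stream, df in streams.items():
            if stream == "assessments":
                base = df[df["week"] == 0]
                item_cols = [c for c in ALL_ITEM_COLUMNS if c in df.columns]
                if len(base) and item_cols:
                    wide = {"participant_id": pid}
                    for _, row in base.iterrows():
                        for c in item_columns(row["measure"]):
                            if c in df.columns and pd.notna(row[c]):
                                wide[c] = int(row[c])
                    frames["baseline_items"].append(pd.DataFrame([wide]))
                out = df[["week", "measure", "total"]].copy()
            else:
                out = df.copy()
            out.insert(0, "participant_id", pid)
            frames[stream].append(out)
        logger.info("loaded %s: %s", pid,
                    {k: len(v) for k, v in streams.items()})

    if all_errors and strict:
        raise CohortValidationError(all_errors)

    def cat(key, empty_cols):
        lst = frames[key]
        return (pd.concat(lst, ignore_index=True) if lst
                else pd.DataFrame(columns=empty_cols))

    e = empty_bundle()
    bundle = CohortBundle(
        gps=cat("gps", e.gps.columns),
        comm=cat("comm", e.comm.columns),
        apps=cat("apps", e.apps.columns),
        assessments=cat("assessments", e.assessments.columns),
        baseline_items=cat("baseline_items", e.baseline_items.columns),
        semantic_labels=cat("semantic_labels", e.semantic_labels.columns),
        demographics=cat("demographics", e.demographics.columns),
    )
    if all_errors:
        bundle.truth["validation_errors"] = all_errors
    return bundle


def save_cohort(bundle: CohortBundle, root_path: str | Path) -> None:
    """Write a bundle back to the per-participant CSV layout."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    for pid in bundle.participant_ids:
        d = root / str(pid)
        d.mkdir(exist_ok=True)
        for stream in ["gps", "comm", "apps", "semantic_labels", "demographics"]:
            df = getattr(bundle, stream)
            sub = df[df["participant_id"].astype(str) == str(pid)].drop(
                columns=["participant_id"])
            if "t" in sub.columns:
                sub = sub.copy()
                sub["t"] = sub["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
            sub.to_csv(d / f"{stream}.csv", index=False, float_format="%.17g")
        assess = bundle.assessments
        sub = assess[assess["participant_id"].astype(str) == str(pid)].drop(
            columns=["participant_id"]).copy()
        items = bundle.baseline_items
        prow = items[items["participant_id"].astype(str) == str(pid)]
        if len(prow):
            for c in ALL_ITEM_COLUMNS:
                if c in prow.columns and pd.notna(prow.iloc[0][c]):
                    measure = c.rsplit("_", 1)[0]
                    mask = (sub["week"] == 0) & (sub["measure"] == measure)
                    sub.loc[mask, c] = int(prow.iloc[0][c])
        sub.to_csv(d / "assessments.csv", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# summaries

def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 digit rounds to 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """``round(100 * count / total, ndigits)`` with half-up rounding."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)


def cohort_summary(bundle: CohortBundle) -> dict:
    """n, age mean/SD, and category counts/percentages for gender and race."""
    demo = bundle.demographics
    n = len(demo)
    if n == 0:
        return {"n": 0, "age_mean": float("nan"), "age_sd": float("nan"),
                "gender": {}, "race": {}}
    summary = {
        "n": n,
        "age_mean": float(demo["age"].mean()),
        "age_sd": float(demo["age"].std(ddof=1)) if n > 1 else float("nan"),
    }
    for col in ("gender", "race"):
        counts = demo[col].value_counts()
        summary[col] = {
            str(cat): {"count": int(c), "total": n, "pct": percentage(int(c), n)}
            for cat, c in counts.items()
        }
    return summary
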