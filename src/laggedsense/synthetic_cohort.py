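"""Synthetic cohort generator with a tunable lagged behaviour→symptom coupling.

The generative model mirrors the structure the analysis assumes:

* four latent symptom-profile groups (minimal symptoms; depression +
  social anxiety; depression + anxiety; multiple comorbidities) with
  group-specific baseline item distributions;
* a daily latent behavioural-activation state ``B`` per participant
  (stationary AR(1)) that drives mobility, communication and app use;
* symptom totals at each check-in built as group mean + person intercept
  + AR(1) person process + a coupling term λ·z(B̄) on the 2-week window
  *preceding* the check-in, with λ calibrated numerically so that the
  correlation between sensor-window change and subsequent symptom change
  equals ``coupling_rho``;
* optional reverse coupling (symptom level shifting behaviour in the
  *proceeding* window), default 0;
* missing-not-at-random assessment dropout (probability increasing in
  baseline severity) and whole missing sensor days.

Two tiers share this latent model.  ``generate_cohort`` emits full event
streams (GPS fixes, call/SMS logs, app samples, semantic labels) for
end-to-end runs through feature extraction.  ``generate_feature_cohort``
emits window-level base features directly (z-scale, with a configurable
loading of the coupled group's members on B̄) and is the fast route for
Monte-Carlo studies of the inference chain, where thousands of full
GPS-trace extractions would dominate the run time without informing the
statistics under study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort_io import (MEASURES, PAIR_WEEKS, SCHEDULE, CohortBundle,
                        empty_bundle, item_columns)
from .feature_aggregation import (ALL_CHECKIN_WEEKS, BASE_FEATURES,
                                  FEATURE_GROUPS, window_span)

logger = logging.getLogger("laggedsense")

STUDY_DAYS = 112           # 16 weeks
START_DATE = date(2020, 1, 6)
SLOTS_PER_DAY = 288        # 5-minute cadence
GROUP_NAMES = ("minimal", "dep_social", "dep_anx", "multi")

#: group mean totals per measure, echoing the four qualitative profiles
DEFAULT_GROUP_MEANS = {
    "minimal":    {"PHQ8": 3.0,  "GAD7": 3.0,  "SPIN": 10.0},
    "dep_social": {"PHQ8": 12.0, "GAD7": 5.0,  "SPIN": 35.0},
    "dep_anx":    {"PHQ8": 15.0, "GAD7": 12.0, "SPIN": 12.0},
    "multi":      {"PHQ8": 18.0, "GAD7": 15.0, "SPIN": 45.0},
}

DEFAULT_APP_CATEGORY_MAP = {
    "chat": "active", "mail": "active", "maps": "active",
    "youtube": "information", "browser": "information", "news": "information",
    "facebook": "social", "instagram": "social", "snapchat": "social",
    "clock": "other",
}

ANCHOR_CATEGORIES = ("home", "work", "shopping", "social",
                     "exercise", "religious")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``coupling_rho`` is the target correlation between the change in the
    coupled sensor group (preceding windows) and the subsequent symptom
    change; ``reverse_coupling_rho`` targets the symptom-change →
    proceeding-window-change correlation and defaults to 0.
    """

    n_participants: int = 200
    group_weights: tuple = (0.312, 0.252, 0.245, 0.191)
    group_means: dict = field(default_factory=lambda:
                              {g: dict(v) for g, v in DEFAULT_GROUP_MEANS.items()})
    ar_coef: float = 0.5           # AR(1) of symptom totals across check-ins
    sigma_symptom: float = 3.0     # innovation SD on the PHQ-8 scale
    person_sd: float = 2.0         # between-person intercept SD
    coupling_rho: float = 0.0
    reverse_coupling_rho: float = 0.0
    coupled_groups: tuple = ("Locations",)
    coupled_measures: tuple = ("PHQ8",)
    feature_loading: float = 0.95  # loading of coupled members on z(B̄)
    b_ar: float = 0.9              # daily AR(1) of the latent state B
    n_anchors: int = 4
    gps_noise_m: float = 10.0
    assessment_missing_rate: float = 0.0
    missingness_severity_slope: float = 0.0
    sensor_missing_day_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.group_weights) - 1.0) > 1e-8:
            raise ValueError("group_weights must sum to 1")
        if len(self.group_weights) != len(GROUP_NAMES):
            raise ValueError(f"expected {len(GROUP_NAMES)} group weights")
        for name in ("coupling_rho", "reverse_coupling_rho"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        for name in ("assessment_missing_rate", "sensor_missing_day_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_anchors < 1:
            raise ValueError("n_anchors must be >= 1")


# ---------------------------------------------------------------------------
# latent states and assessments

def _draw_groups(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    return rng.choice(len(GROUP_NAMES), size=config.n_participants,
                      p=np.asarray(config.group_weights))


def _latent_b(rng: np.random.Generator, n: int, n_days: int,
              phi: float) -> np.ndarray:
    """Stationary AR(1) per participant, marginal variance 1."""
    b = np.empty((n, n_days))
    b[:, 0] = rng.normal(size=n)
    innov_sd = np.sqrt(1 - phi ** 2)
    for d in range(1, n_days):
        b[:, d] = phi * b[:, d - 1] + innov_sd * rng.normal(size=n)
    return b


def _baseline_items(rng: np.random.Generator, group: str, measure: str,
                    config: SimConfig) -> np.ndarray:
    n_items, max_item, _ = MEASURES[measure]
    target = config.group_means[GROUP_NAMES[group] if isinstance(group, (int, np.integer))
                                else group][measure]
    p = np.clip(target / (n_items * max_item), 0.02, 0.98)
    return rng.binomial(max_item, p, size=n_items)


def _window_mean(b: np.ndarray, day_offset: int, week: int, side: str
                 ) -> np.ndarray:
    """Mean of B over the window's days; clipped to the simulated range."""
    first, last = window_span(week, side)
    lo = max(0, first + day_offset)
    hi = min(b.shape[1] - 1, last + day_offset)
    if hi < lo:
        return np.full(b.shape[0], np.nan)
    return b[:, lo:hi + 1].mean(axis=1)


def _calibrate_lambda(rho: float, d_sn: np.ndarray, d_zb: np.ndarray,
                      d_a: np.ndarray) -> float:
    """λ such that corr(ΔSn, Δa + λ·ΔzB) hits the target rho.

    Solved from the empirical second moments of the cohort itself:
    λ = sign(ρ)·sqrt( ρ²·var(Δa) / (c₁² − ρ²·var(ΔzB)) ) with
    c₁ = cov(ΔSn, ΔzB)/sd(ΔSn).
    """
    if rho == 0:
        return 0.0
    ok = np.isfinite(d_sn) & np.isfinite(d_zb)
    c1 = (np.cov(d_sn[ok], d_zb[ok])[0, 1]) / np.std(d_sn[ok], ddof=1)
    v_z = np.var(d_zb[ok], ddof=1)
    v_a = np.var(d_a, ddof=1)
    denom = c1 ** 2 - rho ** 2 * v_z
    if denom <= 0:
        raise ValueError("coupling_rho exceeds the attainable correlation "
                         "given the sensor features' loading on B")
    return np.sign(rho) * np.sqrt(rho ** 2 * v_a / denom)


def _symptom_tables(rng: np.random.Generator, groups: np.ndarray,
                    zb_pre: dict[str, dict[int, np.ndarray]],
                    d_sn_for_calib: dict[str, np.ndarray],
                    config: SimConfig,
                    pids: list[str]) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assessments (long) + wide baseline items + ground-truth lambdas."""
    n = len(groups)
    rows, item_rows, lambdas = [], [], {}

    # baseline items and totals
    items_by_measure = {}
    for measure in MEASURES:
        items = np.stack([_baseline_items(rng, int(groups[i]), measure, config)
                          for i in range(n)])
        items_by_measure[measure] = items
    for i in range(n):
        rec = {"participant_id": pids[i]}
        for measure in MEASURES:
            for j, c in enumerate(item_columns(measure)):
                rec[c] = int(items_by_measure[measure][i, j])
        item_rows.append(rec)

    for measure in MEASURES:
        _, _, max_total = MEASURES[measure]
        sigma = config.sigma_symptom * max_total / 24.0
        mu = np.array([config.group_means[GROUP_NAMES[g]][measure]
                       for g in groups])
        u = rng.normal(0, config.person_sd * max_total / 24.0, size=n)
        weeks = PAIR_WEEKS[measure]
        phi = config.ar_coef
        a = np.empty((n, len(weeks)))
        a[:, 0] = rng.normal(0, sigma / np.sqrt(1 - phi ** 2), size=n)
        for j in range(1, len(weeks)):
            a[:, j] = phi * a[:, j - 1] + rng.normal(0, sigma, size=n)

        lam = 0.0
        if measure in config.coupled_measures and config.coupling_rho != 0:
            zb = np.column_stack([zb_pre[measure][w] for w in weeks])
            d_zb = np.diff(zb, axis=1).ravel()
            d_a = np.diff(a, axis=1).ravel()
            lam = _calibrate_lambda(config.coupling_rho,
                                    d_sn_for_calib[measure], d_zb, d_a)
        lambdas[measure] = float(lam)

        zb = np.column_stack([zb_pre[measure][w] for w in weeks])
        totals = mu[:, None] + u[:, None] + a + lam * np.nan_to_num(zb)
        totals = np.clip(np.rint(totals), 0, max_total).astype(int)

        base_totals = items_by_measure[measure].sum(axis=1)
        for i in range(n):
            rows.append({"participant_id": pids[i], "week": 0,
                         "measure": measure, "total": int(base_totals[i])})
            for j, w in enumerate(weeks):
                rows.append({"participant_id": pids[i], "week": int(w),
                             "measure": measure, "total": int(totals[i, j])})

    assessments = pd.DataFrame(rows)
    baseline_items = pd.DataFrame(item_rows)
    return assessments, baseline_items, lambdas


def _demographics(rng: np.random.Generator, pids: list[str]) -> pd.DataFrame:
    n = len(pids)
    return pd.DataFrame({
        "participant_id": pids,
        "age": np.clip(np.rint(rng.normal(39, 12, n)), 18, 70).astype(int),
        "gender": rng.choice(["female", "male", "nonbinary"], n,
                             p=[0.79, 0.19, 0.02]),
        "race": rng.choice(["white", "black", "asian", "other"], n,
                           p=[0.80, 0.08, 0.06, 0.06]),
        "tz_offset_hours": 0.0,
        "start_date": START_DATE.isoformat(),
    })


# ---------------------------------------------------------------------------
# feature-level tier

def generate_feature_cohort(config: SimConfig
                            ) -> tuple[CohortBundle, pd.DataFrame]:
    """Window-level base features + assessments from the latent model.

    Returns (bundle, windows): ``bundle`` carries assessments, baseline
    items and demographics (event streams empty); ``windows`` is the
    base-feature table (participant × check-in week × side) ready for
    ``standardize_features`` / ``aggregate_groups``.  The latent state is
    simulated 2 weeks past both study ends so every window is complete.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [f"P{i:04d}" for i in range(n)]
    groups = _draw_groups(rng, config)

    day_offset = 14                       # array col 0 = study day −14
    n_days = STUDY_DAYS + 28
    b = _latent_b(rng, n, n_days, config.b_ar)

    weeks = sorted({w for ws in PAIR_WEEKS.values() for w in ws})
    raw = {(w, s): _window_mean(b, day_offset, w, s)
           for w in weeks for s in ("preceding", "proceeding")}
    allvals = np.concatenate([v for v in raw.values()])
    m, sd = np.nanmean(allvals), np.nanstd(allvals, ddof=1)
    zb = {k: (v - m) / sd for k, v in raw.items()}

    coupled = {f for g in config.coupled_groups for f in FEATURE_GROUPS[g]}
    load = config.feature_loading
    rows = []
    feats: dict[tuple, dict[str, np.ndarray]] = {}
    for (w, s), z in zb.items():
        fvals = {}
        for f in BASE_FEATURES:
            lf = load if f in coupled else 0.0
            fvals[f] = lf * z + np.sqrt(1 - lf ** 2) * rng.normal(size=n)
        feats[(w, s)] = fvals

    # forward-calibration inputs: coupled-group change across pre windows
    d_sn_calib = {}
    for measure in config.coupled_measures:
        g0 = config.coupled_groups[0]
        members = FEATURE_GROUPS[g0]
        pw = PAIR_WEEKS[measure]
        gvals = np.column_stack([
            np.mean([feats[(w, "preceding")][f] for f in members], axis=0)
            for w in pw])
        d_sn_calib[measure] = np.diff(gvals, axis=1).ravel()

    zb_pre = {measure: {w: zb[(w, "preceding")] for w in PAIR_WEEKS[measure]}
              for measure in MEASURES}
    assessments, baseline_items, lambdas = _symptom_tables(
        rng, groups, zb_pre, d_sn_calib, config, pids)

    if config.reverse_coupling_rho != 0:
        _add_reverse_coupling(rng, feats, assessments, config, pids)

    for (w, s), fvals in feats.items():
        for i in range(n):
            row = {"participant_id": pids[i], "week": w, "side": s,
                   "valid_days": 14}
            row.update({f: float(fvals[f][i]) for f in BASE_FEATURES})
            rows.append(row)
    windows = pd.DataFrame(rows)[["participant_id", "week", "side",
                                  "valid_days", *BASE_FEATURES]]

    bundle = empty_bundle()
    bundle.assessments = assessments
    bundle.baseline_items = baseline_items
    bundle.demographics = _demographics(rng, pids)
    bundle.truth = {"group": dict(zip(pids, (GROUP_NAMES[g] for g in groups))),
                    "lambda": lambdas, "config": config}
    if config.assessment_missing_rate or config.sensor_missing_day_rate:
        bundle = inject_missingness(bundle, config, rng)
    return bundle, windows


def _add_reverse_coupling(rng, feats, assessments, config, pids):
    """Shift coupled members of proceeding windows by κ·z(Sx at check-in),
    with κ solved numerically so corr(ΔSx, ΔSn′) hits the target."""
    measure = config.coupled_measures[0]
    pw = PAIR_WEEKS[measure]
    a = assessments[assessments["measure"] == measure]
    tot = a.pivot_table(index=a["participant_id"].astype(str),
                        columns="week", values="total").reindex(
        index=pids, columns=pw).to_numpy(float)
    zs = (tot - np.nanmean(tot)) / np.nanstd(tot, ddof=1)
    d_zs = np.diff(zs, axis=1).ravel()

    members = [f for g in config.coupled_groups for f in FEATURE_GROUPS[g]]
    gvals = np.column_stack([
        np.mean([feats[(w, "proceeding")][f] for f in members], axis=0)
        for w in pw])
    d_g0 = np.diff(gvals, axis=1).ravel()

    rho = config.reverse_coupling_rho

    def f(kappa):
        d = d_g0 + kappa * d_zs
        return np.corrcoef(d_zs, d)[0, 1] - rho

    kappa = brentq(f, -50, 50)
    for j, w in enumerate(pw):
        for feat in members:
            feats[(w, "proceeding")][feat] = (
                feats[(w, "proceeding")][feat] + kappa * zs[:, j])


# ---------------------------------------------------------------------------
# event-level tier

def generate_gps_day(anchors: np.ndarray, b_t: float, gps_noise_m: float,
                     rng: np.random.Generator,
                     day_start: pd.Timestamp | None = None) -> pd.DataFrame:
    """One synthetic day of 288 five-minute GPS fixes.

    The participant dwells at the home anchor (row 0) and makes a
    Poisson-distributed number of outings — mean increasing in the
    behavioural activation ``b_t`` — to the other anchors, travelling in a
    straight line at one interpolated fix per 2.5 km (≈30 km/h) and
    dwelling at least 30 minutes (6 fixes) per visit.  Gaussian jitter of
    ``gps_noise_m`` metres is added to every fix.
    """
    n_anchor = len(anchors)
    slot_anchor = np.zeros(SLOTS_PER_DAY, dtype=int)
    frac = np.full(SLOTS_PER_DAY, np.nan)   # travel interpolation fraction
    travel_from = np.zeros(SLOTS_PER_DAY, dtype=int)

    if n_anchor > 1:
        n_out = min(int(rng.poisson(max(0.05, 1.0 + 0.7 * b_t))), 4)
        cursor = 96                          # 08:00
        for _ in range(n_out):
            target = int(rng.integers(1, n_anchor))
            d_km = _anchor_distance_km(anchors[0], anchors[target])
            n_travel = max(1, int(np.ceil(d_km / 2.5)))
            dwell = int(rng.integers(6, 25))
            start = cursor + int(rng.integers(0, 12))
            end = start + n_travel + dwell + n_travel
            if end > 240:                    # back home by 20:00
                break
            for k in range(n_travel):        # outbound
                slot_anchor[start + k] = target
                frac[start + k] = (k + 1) / (n_travel + 1)
                travel_from[start + k] = 0
            slot_anchor[start + n_travel: start + n_travel + dwell] = target
            for k in range(n_travel):        # inbound
                s = start + n_travel + dwell + k
                slot_anchor[s] = target
                frac[s] = 1.0 - (k + 1) / (n_travel + 1)
                travel_from[s] = 0
            cursor = end + 6                 # >=30 min home between outings

    lat = anchors[slot_anchor, 0].astype(float).copy()
    lon = anchors[slot_anchor, 1].astype(float).copy()
    moving = ~np.isnan(frac)
    if moving.any():
        f = frac[moving]
        a0 = anchors[travel_from[moving]]
        a1 = anchors[slot_anchor[moving]]
        lat[moving] = a0[:, 0] + f * (a1[:, 0] - a0[:, 0])
        lon[moving] = a0[:, 1] + f * (a1[:, 1] - a0[:, 1])

    if gps_noise_m > 0:
        lat0 = float(anchors[0, 0])
        lat += rng.normal(0, gps_noise_m / 111_320.0, SLOTS_PER_DAY)
        lon += rng.normal(0, gps_noise_m / (111_320.0 *
                                            np.cos(np.radians(lat0))),
                          SLOTS_PER_DAY)

    if day_start is None:
        day_start = pd.Timestamp("2020-01-06", tz="UTC")
    t = day_start + pd.to_timedelta(np.arange(SLOTS_PER_DAY) * 300, unit="s")
    return pd.DataFrame({"t": t, "lat": lat, "lon": lon})


def _anchor_distance_km(a, b) -> float:
    from .gps_features import haversine_km
    return float(haversine_km(a[0], a[1], b[0], b[1]))


def _make_anchors(rng: np.random.Generator, n_anchors: int) -> tuple[np.ndarray, list[str]]:
    home = np.array([41.8 + rng.uniform(-0.05, 0.05),
                     -87.7 + rng.uniform(-0.05, 0.05)])
    anchors = [home]
    cats = ["home"]
    pool = ["work"] + list(rng.permutation(
        ["shopping", "social", "exercise", "religious"]))
    for i in range(n_anchors - 1):
        d_km = rng.uniform(0.8, 3.0)
        bearing = rng.uniform(0, 2 * np.pi)
        dlat = d_km * np.cos(bearing) / 111.32
        dlon = d_km * np.sin(bearing) / (111.32 * np.cos(np.radians(home[0])))
        anchors.append(home + [dlat, dlon])
        cats.append(pool[i % len(pool)])
    return np.asarray(anchors), cats


APP_CATALOG = list(DEFAULT_APP_CATEGORY_MAP)


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Full event-stream cohort: 16 weeks of GPS, comm and app streams plus
    scheduled assessments, driven by the shared latent model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [f"P{i:04d}" for i in range(n)]
    groups = _draw_groups(rng, config)
    b = _latent_b(rng, n, STUDY_DAYS, config.b_ar)

    gps_frames, comm_frames, app_frames, label_frames = [], [], [], []
    for i, pid in enumerate(pids):
        anchors, cats = _make_anchors(rng, config.n_anchors)
        day_rows_gps, day_rows_comm, day_rows_app = [], [], []
        for d in range(STUDY_DAYS):
            day_start = pd.Timestamp(START_DATE + timedelta(days=d), tz="UTC")
            gps = generate_gps_day(anchors, float(b[i, d]),
                                   config.gps_noise_m, rng, day_start)
            day_rows_gps.append(gps)

            n_ev = rng.poisson(2.5 * np.exp(0.25 * b[i, d]))
            if n_ev:
                secs = np.sort(rng.integers(0, 86_400, n_ev))
                kind = rng.choice(["call", "sms"], n_ev, p=[0.4, 0.6])
                mag = np.where(kind == "call",
                               rng.exponential(120, n_ev).astype(int) + 1,
                               rng.poisson(80, n_ev))
                day_rows_comm.append(pd.DataFrame({
                    "t": day_start + pd.to_timedelta(secs, unit="s"),
                    "kind": kind,
                    "direction": rng.choice(["incoming", "outgoing"], n_ev),
                    "magnitude": mag,
                }))

            p_use = min(0.5, 0.10 * np.exp(0.25 * b[i, d]))
            used = np.nonzero(rng.random(SLOTS_PER_DAY) < p_use)[0]
            if len(used):
                day_rows_app.append(pd.DataFrame({
                    "t": day_start + pd.to_timedelta(used * 300 + 60, unit="s"),
                    "app_id": rng.choice(APP_CATALOG, len(used)),
                }))

        for frames, acc in ((day_rows_gps, gps_frames),
                            (day_rows_comm, comm_frames),
                            (day_rows_app, app_frames)):
            if frames:
                df = pd.concat(frames, ignore_index=True)
                df.insert(0, "participant_id", pid)
                acc.append(df)
        label_frames.append(pd.DataFrame({
            "participant_id": pid,
            "centroid_lat": anchors[:, 0], "centroid_lon": anchors[:, 1],
            "category": cats, "week": 4,
        }))

    # symptoms coupled to z(B̄) of the preceding windows; for the event tier
    # the calibration proxy is B̄ itself (features are extracted downstream)
    weeks = sorted({w for ws in PAIR_WEEKS.values() for w in ws})
    raw = {w: _window_mean(b, 0, w, "preceding") for w in weeks}
    allv = np.concatenate(list(raw.values()))
    zb = {w: (v - allv.mean()) / allv.std(ddof=1) for w, v in raw.items()}
    d_sn_calib = {}
    for measure in config.coupled_measures:
        pw = PAIR_WEEKS[measure]
        mat = np.column_stack([zb[w] for w in pw])
        d_sn_calib[measure] = np.diff(mat, axis=1).ravel()
    zb_pre = {measure: {w: zb[w] for w in PAIR_WEEKS[measure]}
              for measure in MEASURES}
    assessments, baseline_items, lambdas = _symptom_tables(
        rng, groups, zb_pre, d_sn_calib, config, pids)

    bundle = empty_bundle()
    bundle.gps = pd.concat(gps_frames, ignore_index=True)
    bundle.comm = (pd.concat(comm_frames, ignore_index=True)
                   if comm_frames else bundle.comm)
    bundle.apps = (pd.concat(app_frames, ignore_index=True)
                   if app_frames else bundle.apps)
    bundle.semantic_labels = pd.concat(label_frames, ignore_index=True)
    bundle.assessments = assessments
    bundle.baseline_items = baseline_items
    bundle.demographics = _demographics(rng, pids)
    bundle.truth = {"group": dict(zip(pids, (GROUP_NAMES[g] for g in groups))),
                    "lambda": lambdas, "config": config}
    if config.assessment_missing_rate or config.sensor_missing_day_rate:
        bundle = inject_missingness(bundle, config, rng)
    return bundle


# ---------------------------------------------------------------------------
# missingness

def inject_missingness(bundle: CohortBundle, config: SimConfig,
                       rng: np.random.Generator | None = None) -> CohortBundle:
    """Remove assessments (missing-not-at-random) and whole sensor days.

    Post-baseline assessments are dropped with probability
    expit(logit(rate) + slope·z(baseline PHQ-8)), so dropout increases
    with baseline severity when the slope is positive; the marginal rate
    stays near ``assessment_missing_rate``.  Whole sensor days are removed
    uniformly at ``sensor_missing_day_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    rate = config.assessment_missing_rate
    slope = config.missingness_severity_slope

    out = CohortBundle(**{k: getattr(bundle, k).copy() for k in
                          ("gps", "comm", "apps", "assessments",
                           "baseline_items", "semantic_labels",
                           "demographics")},
                       truth=dict(bundle.truth))

    if rate > 0:
        a = out.assessments
        base = a[(a["measure"] == "PHQ8") & (a["week"] == 0)]
        sev = base.set_index(base["participant_id"].astype(str))["total"]
        z = ((sev - sev.mean()) / sev.std(ddof=1)).fillna(0.0)
        post = a["week"] > 0
        if rate >= 1:
            p = np.ones(post.sum())
        else:
            lo = logit(np.clip(rate, 1e-12, 1 - 1e-12))
            p = expit(lo + slope * a.loc[post, "participant_id"]
                      .astype(str).map(z).fillna(0.0).to_numpy())
        drop = a.loc[post].index[rng.random(int(post.sum())) < p]
        out.assessments = a.drop(index=drop).reset_index(drop=True)

    if config.sensor_missing_day_rate > 0:
        # a missing sensor day drops every stream for that participant-day
        keys = {}
        for stream in ("gps", "comm", "apps"):
            df = getattr(out, stream)
            keys[stream] = ((df["participant_id"].astype(str) + "|"
                             + df["t"].dt.date.astype(str))
                            if len(df) else pd.Series(dtype=str))
        all_days = pd.concat(keys.values()).unique()
        miss = set(all_days[rng.random(len(all_days))
                            < config.sensor_missing_day_rate])
        for stream in ("gps", "comm", "apps"):
            df = getattr(out, stream)
            if len(df):
                setattr(out, stream,
                        df[~keys[stream].isin(miss)].reset_index(drop=True))
    return out
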