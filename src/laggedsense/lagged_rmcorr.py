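"""Lagged change-pair construction, repeated-measures correlation, FDR.

The design: each symptom check-in is flanked by a 2-week sensor window on
either side.  For consecutive check-ins 1 and 2, the *sensor → symptom*
direction correlates the change in the preceding windows (Sn₂ − Sn₁) with
the symptom change (Sx₂ − Sx₁), so the sensed behaviour strictly precedes
the symptoms it is paired with; the *symptom → sensor* direction
correlates Sx₂ − Sx₁ with the change in the proceeding windows
(Sn′₂ − Sn′₁).  Correlations are repeated-measures correlations (common
within-participant slope, participant-specific intercepts), computed per
feature group × symptom measure × cluster × direction, with
Benjamini–Hochberg adjustment within each (measure × cluster × direction)
family of feature groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort_io import PAIR_WEEKS, SCHEDULE, percentage
from .feature_aggregation import FEATURE_GROUPS

logger = logging.getLogger("laggedsense")

DIRECTIONS = ("sensor->symptom", "symptom->sensor")


# ---------------------------------------------------------------------------
# change pairs

def build_change_pairs(assessments: pd.DataFrame, group_windows: pd.DataFrame,
                       measure: str, group: str) -> pd.DataFrame:
    """Lagged change pairs for one symptom measure and feature group.

    One row per participant × consecutive-check-in pair, with columns
    ``dSx`` (symptom change), ``dSn`` (change in the windows preceding each
    check-in) and ``dSn_prime`` (change in the proceeding windows).  If
    exactly one assessment of a pair is missing it is replaced by the
    participant's mean of observed scores on that measure; pairs with both
    assessments missing are dropped.  A missing sensor window leaves the
    corresponding direction's change NaN (the pair is discarded from that
    direction downstream).
    """
    weeks = PAIR_WEEKS[measure]
    a = assessments[assessments["measure"] == measure]
    all_totals = a.pivot_table(index=a["participant_id"].astype(str),
                               columns="week", values="total")
    all_totals = all_totals.reindex(columns=SCHEDULE[measure])
    totals = all_totals.reindex(columns=weeks)

    gw = group_windows
    sn = {}
    for side in ("preceding", "proceeding"):
        sub = gw[gw["side"] == side]
        sn[side] = sub.pivot_table(index=sub["participant_id"].astype(str),
                                   columns="week", values=group,
                                   dropna=False).reindex(columns=weeks)

    rows = []
    for pid, obs in totals.iterrows():
        # within-person fill mean uses every observed check-in, baseline included
        observed = all_totals.loc[pid].dropna()
        if len(observed) < 2:
            logger.info("participant %s: <2 observed %s assessments, no pairs",
                        pid, measure)
            continue
        fill = float(observed.mean())
        for j in range(len(weeks) - 1):
            w1, w2 = weeks[j], weeks[j + 1]
            s1, s2 = obs[w1], obs[w2]
            n_missing = int(pd.isna(s1)) + int(pd.isna(s2))
            if n_missing == 2:
                continue
            fill_flags = [w for w, s in ((w1, s1), (w2, s2)) if pd.isna(s)]
            s1 = fill if pd.isna(s1) else float(s1)
            s2 = fill if pd.isna(s2) else float(s2)

            def win(side, w):
                try:
                    return float(sn[side].at[pid, w])
                except KeyError:
                    return np.nan

            rows.append({
                "participant_id": pid, "pair": j, "w1": w1, "w2": w2,
                "dSx": s2 - s1,
                "dSn": win("preceding", w2) - win("preceding", w1),
                "dSn_prime": win("proceeding", w2) - win("proceeding", w1),
                "n_filled": n_missing, "filled_weeks": tuple(fill_flags),
            })
    return pd.DataFrame(rows, columns=["participant_id", "pair", "w1", "w2",
                                       "dSx", "dSn", "dSn_prime",
                                       "n_filled", "filled_weeks"])


# ---------------------------------------------------------------------------
# repeated-measures correlation

@dataclass
class RmCorr:
    r: float
    dof_inference: int   # N_obs − n_participants − 1
    dof_reported: float     # n · (k̄ − 1)
    p: float
    n_participants: int
    n_obs: int


def rmcorr(x: np.ndarray, y: np.ndarray, participant: np.ndarray) -> RmCorr:
    """Common within-participant correlation (shared slope, per-participant
    intercepts).

    Equivalent to the ANCOVA construction: demean x and y within each
    participant and correlate the centred series; r carries the sign of the
    shared slope and r² = SSx/(SSx + SSresid).  Participants contributing
    fewer than 2 complete pairs are excluded.  p is two-sided from a t
    distribution on N_obs − n_participants − 1 degrees of freedom.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "pid": np.asarray(participant)}).dropna()
    counts = df.groupby("pid").size()
    df = df[df["pid"].isin(counts[counts >= 2].index)]
    n_part = df["pid"].nunique()
    n_obs = len(df)
    if n_part < 2 or n_obs - n_part - 1 < 1:
        warnings.warn("rmcorr: not enough participants/observations",
                      stacklevel=2)
        return RmCorr(np.nan, 0, np.nan, np.nan, n_part, n_obs)

    g = df.groupby("pid")
    xc = df["x"] - g["x"].transform("mean")
    yc = df["y"] - g["y"].transform("mean")
    ssx = float((xc ** 2).sum())
    if ssx == 0 or float((yc ** 2).sum()) == 0:
        warnings.warn("rmcorr: no within-participant variance", stacklevel=2)
        return RmCorr(np.nan, 0, np.nan, np.nan, n_part, n_obs)

    r = float((xc * yc).sum() / np.sqrt(ssx * (yc ** 2).sum()))
    dof = n_obs - n_part - 1
    t = r * np.sqrt(dof / max(1e-300, 1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), dof))
    k_bar = n_obs / n_part
    return RmCorr(r=r, dof_inference=dof, dof_reported=n_part * (k_bar - 1),
                  p=p, n_participants=n_part, n_obs=n_obs)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1).

    The running minimum from the largest p downwards can make adjacent
    adjusted values identical.  NaNs pass through unadjusted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# full analysis table

def run_lagged_analysis(assessments: pd.DataFrame,
                        group_windows: pd.DataFrame,
                        clusters: pd.Series | None = None,
                        measures=("PHQ8", "GAD7", "SPIN"),
                        groups: dict | None = None) -> pd.DataFrame:
    """rmcorr table over measure × {full sample + clusters} × group × direction.

    ``clusters`` maps participant_id -> cluster index (optional).  BH
    adjustment is applied within each (measure, cluster, direction) family
    of feature groups.  Rows where the correlation is not estimable (e.g.
    a cluster with fewer than 2 eligible participants) carry NaN.
    """
    groups = groups or FEATURE_GROUPS
    samples: list[tuple[str, pd.Index | None]] = [("full", None)]
    if clusters is not None:
        for c in sorted(clusters.unique()):
            samples.append((f"cluster_{c}",
                            clusters.index[clusters == c]))

    rows = []
    for measure in measures:
        pair_cache = {g: build_change_pairs(assessments, group_windows,
                                            measure, g) for g in groups}
        for label, ids in samples:
            for direction in DIRECTIONS:
                col = "dSn" if direction == "sensor->symptom" else "dSn_prime"
                for g in groups:
                    pairs = pair_cache[g]
                    if ids is not None and len(pairs):
                        pairs = pairs[pairs["participant_id"].isin(
                            ids.astype(str))]
                    if len(pairs) == 0:
                        res = RmCorr(np.nan, 0, np.nan, np.nan, 0, 0)
                    else:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res = rmcorr(pairs[col].to_numpy(),
                                         pairs["dSx"].to_numpy(),
                                         pairs["participant_id"].to_numpy())
                    rows.append({
                        "measure": measure, "cluster": label, "group": g,
                        "direction": direction, "n": res.n_participants,
                        "n_obs": res.n_obs, "dof_reported": res.dof_reported,
                        "dof_inference": res.dof_inference,
                        "r_rm": res.r, "p_raw": res.p,
                    })
    table = pd.DataFrame(rows)
    table["p_bh"] = np.nan
    for _, idx in table.groupby(["measure", "cluster", "direction"]).groups.items():
        table.loc[idx, "p_bh"] = bh_adjust(table.loc[idx, "p_raw"])
    table["sig_05"] = table["p_bh"] < 0.05
    table["trend_10"] = table["p_bh"] < 0.10
    return table


# ---------------------------------------------------------------------------
# power and missingness

def power_sample_size(rho: float, alpha: float = 0.05, power: float = 0.90,
                      fisher_correction: bool = False) -> int:
    """Sample size for a two-sided test of a Pearson correlation.

    n = ((z₁₋α/₂ + z_power) / atanh(ρ))², truncated; with
    ``fisher_correction`` the small-sample +3 is added and the result
    rounded up instead.
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be in (0, 1) in absolute value")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z = (sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) / np.arctanh(abs(rho))
    n = z * z
    return int(np.ceil(n + 3)) if fisher_correction else int(np.trunc(n))


def summarize_missingness(assessments: pd.DataFrame,
                          n_participants: int) -> pd.DataFrame:
    """Missing / possible post-baseline assessments per measure.

    possible = n_participants × number of scheduled post-baseline
    check-ins; percent is half-up rounded to 2 decimals.  Also reports the
    mean baseline total of participants with at least one missing
    assessment on that measure.
    """
    rows = []
    for measure, weeks in SCHEDULE.items():
        post = [w for w in weeks if w > 0]
        possible = n_participants * len(post)
        a = assessments[(assessments["measure"] == measure)
                        & (assessments["week"] > 0)]
        observed = len(a)
        missing = possible - observed
        base = assessments[(assessments["measure"] == measure)
                           & (assessments["week"] == 0)]
        base = base.set_index(base["participant_id"].astype(str))["total"]
        per_pid = a.groupby(a["participant_id"].astype(str)).size()
        per_pid = per_pid.reindex(base.index, fill_value=0)
        with_missing = per_pid[per_pid < len(post)].index
        rows.append({
            "measure": measure, "missing": missing, "possible": possible,
            "percent": percentage(missing, possible, ndigits=2),
            "mean_baseline_if_missing":
                float(base.loc[with_missing].mean()) if len(with_missing)
                else np.nan,
            "mean_baseline_all": float(base.mean()) if len(base) else np.nan,
        })
    return pd.DataFrame(rows)
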