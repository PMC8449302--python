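"""Change pairs, rmcorr vs independent oracles, BH, power, missingness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import laggedsense as ls
from laggedsense.cohort_io import PAIR_WEEKS, SCHEDULE
from laggedsense.lagged_rmcorr import bh_adjust, build_change_pairs, rmcorr


def complete_assessments(pids, measure, totals_by_week):
    rows = []
    for pid in pids:
        for w in SCHEDULE[measure]:
            if w in totals_by_week:
                rows.append({"participant_id": pid, "week": w,
                             "measure": measure,
                             "total": totals_by_week[w]})
    return pd.DataFrame(rows)


def flat_windows(pids, value=0.0):
    rows = []
    for pid in pids:
        for w in (0, 1, 4, 7, 10, 13, 16):
            for side in ("preceding", "proceeding"):
                rows.append({"participant_id": pid, "week": w, "side": side,
                             "G": value, "valid_days": 14})
    return pd.DataFrame(rows)


# -- change pairs -----------------------------------------------------------

def test_phq8_six_checkins_yield_five_pairs():
    a = complete_assessments(["P1"], "PHQ8",
                             {w: 10 for w in SCHEDULE["PHQ8"]})
    pairs = build_change_pairs(a, flat_windows(["P1"]), "PHQ8", "G")
    assert len(pairs) == 5


@pytest.mark.parametrize("measure", ["GAD7", "SPIN"])
def test_gad7_spin_five_checkins_yield_four_pairs(measure):
    a = complete_assessments(["P1"], measure,
                             {w: 8 for w in SCHEDULE[measure]})
    pairs = build_change_pairs(a, flat_windows(["P1"]), measure, "G")
    assert len(pairs) == 4


def test_mean_fill_of_single_missing_assessment():
    """Observed (10, missing, 14, 12, 10, 14) -> fill with 12.0."""
    weeks = PAIR_WEEKS["PHQ8"]
    obs = dict(zip(weeks, [10, None, 14, 12, 10, 14]))
    totals = {w: v for w, v in obs.items() if v is not None}
    a = complete_assessments(["P1"], "PHQ8", totals)
    pairs = build_change_pairs(a, flat_windows(["P1"]), "PHQ8", "G")
    assert len(pairs) == 5
    # pair (weeks[0], weeks[1]): second member filled -> dSx = 12 - 10
    p0 = pairs[(pairs.w1 == weeks[0]) & (pairs.w2 == weeks[1])].iloc[0]
    assert p0["dSx"] == 2.0 and p0["n_filled"] == 1


def test_both_missing_pair_dropped():
    weeks = PAIR_WEEKS["PHQ8"]
    totals = {w: 10 for w in weeks[2:]}
    a = complete_assessments(["P1"], "PHQ8", totals)
    pairs = build_change_pairs(a, flat_windows(["P1"]), "PHQ8", "G")
    # (1,4) has both members missing and is dropped; (4,7) is mean-filled
    assert (1, 4) not in set(zip(pairs.w1, pairs.w2))
    assert set(zip(pairs.w1, pairs.w2)) == {(4, 7), (7, 10), (10, 13), (13, 16)}
    assert pairs.loc[(pairs.w1 == 4), "n_filled"].iloc[0] == 1


def test_single_observation_contributes_no_pairs():
    a = complete_assessments(["P1"], "PHQ8", {4: 10})
    pairs = build_change_pairs(a, flat_windows(["P1"]), "PHQ8", "G")
    assert len(pairs) == 0


def test_missing_sensor_window_leaves_direction_nan():
    a = complete_assessments(["P1"], "PHQ8",
                             {w: 10 for w in SCHEDULE["PHQ8"]})
    w = flat_windows(["P1"])
    w.loc[(w.week == 4) & (w.side == "preceding"), "G"] = np.nan
    pairs = build_change_pairs(a, w, "PHQ8", "G")
    bad = pairs[(pairs.w1 == 4) | (pairs.w2 == 4)]
    assert bad["dSn"].isna().all()
    assert pairs["dSn_prime"].notna().all()


# -- rmcorr -----------------------------------------------------------------

def test_perfect_within_person_association():
    pid = np.repeat(["a", "b"], 4)
    x = np.array([0, 1, 2, 3, 10, 11, 12, 13], float)
    y = x + np.repeat([0, 100], 4)
    assert rmcorr(x, y, pid).r == pytest.approx(1.0)
    assert rmcorr(x, -y, pid).r == pytest.approx(-1.0)


def test_rmcorr_matches_pingouin_and_lstsq_oracles():
    """r and p match both pingouin's ANCOVA and an explicit dummy-design
    least-squares fit to 1e-10 on random small instances."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(77)
    for trial in range(20):
        n_part = int(rng.integers(3, 11))
        ks = rng.integers(2, 7, n_part)
        pid = np.concatenate([[i] * k for i, k in enumerate(ks)])
        n = len(pid)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n) + pid * 0.3
        res = rmcorr(x, y, pid)

        df = pd.DataFrame({"x": x, "y": y, "pid": pid})
        ref = pg.rm_corr(df, "x", "y", "pid")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-10)
        assert res.dof_inference == int(ref["dof"].iloc[0])

        # independent matrix-algebra oracle: participant dummies + shared slope
        dummies = (pid[:, None] == np.unique(pid)[None, :]).astype(float)
        design = np.column_stack([dummies, x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_resid = float(resid @ resid)
        design0 = dummies
        beta0, *_ = np.linalg.lstsq(design0, y, rcond=None)
        resid0 = y - design0 @ beta0
        ss_x = float(resid0 @ resid0) - ss_resid
        r_oracle = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_resid))
        assert res.r == pytest.approx(r_oracle, abs=1e-10)


def test_rmcorr_invariant_to_per_participant_shifts():
    rng = np.random.default_rng(5)
    pid = np.repeat(np.arange(6), 5)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = rmcorr(x, y, pid)
    shift_x = x + np.repeat(rng.normal(0, 50, 6), 5)
    shift_y = y + np.repeat(rng.normal(0, 50, 6), 5)
    moved = rmcorr(shift_x, shift_y, pid)
    assert moved.r == pytest.approx(base.r, abs=1e-12)
    assert moved.p == pytest.approx(base.p, abs=1e-12)


def test_rmcorr_degenerate_inputs():
    pid = np.repeat([0, 1], 3)
    x = np.zeros(6)
    with pytest.warns(UserWarning):
        res = rmcorr(x, np.arange(6.0), pid)
    assert np.isnan(res.r)
    with pytest.warns(UserWarning):
        res = rmcorr(np.arange(4.0), np.arange(4.0), np.arange(4))  # 1 obs each
    assert np.isnan(res.r)


def test_dof_conventions():
    pid = np.repeat(np.arange(4), 5)
    rng = np.random.default_rng(1)
    res = rmcorr(rng.normal(size=20), rng.normal(size=20), pid)
    assert res.dof_inference == 20 - 4 - 1
    assert res.dof_reported == pytest.approx(4 * (5 - 1))  # n(k̄−1)


# -- BH ---------------------------------------------------------------------

def test_bh_hand_computed_step_up():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_empty():
    np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
    assert bh_adjust([]).size == 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_adjusted_at_least_raw_and_monotone(ps):
    adj = bh_adjust(ps)
    assert (adj >= np.asarray(ps) - 1e-12).all()
    assert (adj <= 1 + 1e-12).all()
    order = np.argsort(ps)
    assert (np.diff(adj[order]) >= -1e-12).all()


# -- power and missingness --------------------------------------------------

def test_power_sample_size_reference_value():
    assert ls.power_sample_size(0.2, 0.05, 0.90) == 255


def test_power_monotone_decreasing_in_effect_size():
    ns = [ls.power_sample_size(r, 0.05, 0.90)
          for r in (0.1, 0.2, 0.5, 0.9, 0.9999)]
    assert all(a >= b for a, b in zip(ns, ns[1:]))
    assert ns[-1] <= 1


def test_power_invalid_inputs():
    with pytest.raises(ValueError):
        ls.power_sample_size(0.0)
    with pytest.raises(ValueError):
        ls.power_sample_size(0.2, alpha=1.5)


def test_missingness_summary_arithmetic():
    """282 participants; 277 missing PHQ-8 of 1692 possible -> 16.37%."""
    rng = np.random.default_rng(0)
    rows = []
    n = 282
    drop_phq = set(rng.choice(n * 6, 277, replace=False))
    drop_gad = set(rng.choice(n * 5, 104, replace=False))
    for i in range(n):
        pid = f"P{i}"
        for m in ("PHQ8", "GAD7", "SPIN"):
            rows.append({"participant_id": pid, "week": 0, "measure": m,
                         "total": int(rng.integers(0, 20))})
        for j, w in enumerate(PAIR_WEEKS["PHQ8"]):
            if i * 6 + j not in drop_phq:
                rows.append({"participant_id": pid, "week": w,
                             "measure": "PHQ8", "total": 10})
        for j, w in enumerate(PAIR_WEEKS["GAD7"]):
            if i * 5 + j not in drop_gad:
                rows.append({"participant_id": pid, "week": w,
                             "measure": "GAD7", "total": 8})
            rows.append({"participant_id": pid, "week": w,
                         "measure": "SPIN", "total": 20})
    summary = ls.summarize_missingness(pd.DataFrame(rows), n)
    s = summary.set_index("measure")
    assert s.at["PHQ8", "missing"] == 277
    assert s.at["PHQ8", "possible"] == 1692
    assert s.at["PHQ8", "percent"] == 16.37
    assert s.at["GAD7", "possible"] == 1410
    assert s.at["GAD7", "percent"] == 7.38
    assert s.at["SPIN", "missing"] == 0
    assert s.at["SPIN", "percent"] == 0.0


def test_run_lagged_analysis_structure_and_determinism(feature_cohort):
    bundle, windows = feature_cohort
    z, _ = ls.standardize_features(windows)
    gw = ls.aggregate_groups(z)
    t1 = ls.run_lagged_analysis(bundle.assessments, gw, measures=("PHQ8",))
    t2 = ls.run_lagged_analysis(bundle.assessments, gw, measures=("PHQ8",))
    pd.testing.assert_frame_equal(t1, t2)
    assert set(t1["direction"]) == {"sensor->symptom", "symptom->sensor"}
    assert len(t1) == 14 * 2
    assert (t1["p_bh"] >= t1["p_raw"] - 1e-12).all()
    assert t1["r_rm"].abs().max() <= 1.0


def test_clustered_analysis_reports_each_cluster(feature_cohort):
    bundle, windows = feature_cohort
    gw = ls.aggregate_groups(ls.standardize_features(windows)[0])
    sol = ls.assign_clusters(bundle.baseline_items, bundle.assessments, k=4,
                             n_init=10, seed=0)
    table = ls.run_lagged_analysis(bundle.assessments, gw, sol.assignments,
                                   measures=("PHQ8",))
    assert set(table["cluster"]) == {"full", "cluster_0", "cluster_1",
                                     "cluster_2", "cluster_3"}
    # BH families are per measure x cluster x direction
    fam = table.groupby(["measure", "cluster", "direction"]).size()
    assert (fam == 14).all()
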