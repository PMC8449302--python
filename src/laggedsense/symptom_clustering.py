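"""k-means symptom-profile clustering on baseline questionnaire items.

Participants are clustered on their raw baseline item vectors (8 PHQ-8 +
7 GAD-7 + 17 SPIN items), k chosen by the elbow heuristic operationalised
as the maximum second difference of the inertia curve.  Cluster indices
are relabelled by ascending mean baseline PHQ-8 total so that cluster 0 is
always the least-depressed profile, making labels reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort_io import MEASURES, item_columns

logger = logging.getLogger("laggedsense")

N_INIT = 50
K_RANGE = range(1, 9)


@dataclass
class ClusterSolution:
    k: int
    assignments: pd.Series          # participant_id -> cluster index
    centroids: np.ndarray           # (k, n_items) in item space
    mean_totals: pd.DataFrame       # per-cluster mean total per measure
    inertia_curve: dict[int, float]


def _item_matrix(baseline_items: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    cols = [c for m in MEASURES for c in item_columns(m)
            if c in baseline_items.columns]
    mat = baseline_items.set_index(
        baseline_items["participant_id"].astype(str))[cols].astype(float)
    complete = mat.dropna()
    n_drop = len(mat) - len(complete)
    if n_drop:
        logger.warning("%d participant(s) with missing baseline items excluded",
                       n_drop)
    return complete, cols


def scan_k(baseline_items: pd.DataFrame, k_range=K_RANGE,
           n_init: int = N_INIT, seed: int = 0) -> dict[int, float]:
    """Best-of-n_init k-means inertia for each k; deterministic given seed."""
    mat, _ = _item_matrix(baseline_items)
    x = mat.to_numpy()
    curve = {}
    for k in k_range:
        if k > len(x):
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        curve[k] = float(km.inertia_)
    return curve


def elbow_k(inertia_curve: dict[int, float]) -> int:
    """k with the maximum second difference of inertia (needs >= 3 points)."""
    ks = sorted(inertia_curve)
    if len(ks) < 3:
        return ks[-1]
    second = {ks[i]: (inertia_curve[ks[i - 1]] - 2 * inertia_curve[ks[i]]
                      + inertia_curve[ks[i + 1]])
              for i in range(1, len(ks) - 1)}
    return max(second, key=second.get)


def assign_clusters(baseline_items: pd.DataFrame,
                    assessments: pd.DataFrame, k: int = 4,
                    n_init: int = N_INIT, seed: int = 0,
                    inertia_curve: dict[int, float] | None = None
                    ) -> ClusterSolution:
    """Cluster participants into k symptom profiles.

    ``assessments`` supplies baseline totals for the per-cluster measure
    means used in naming; clusters are re-indexed by ascending mean PHQ-8.
    """
    mat, cols = _item_matrix(baseline_items)
    if k > len(mat):
        raise ValueError(f"k={k} exceeds {len(mat)} complete participants")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(mat.to_numpy())
    raw = pd.Series(km.labels_, index=mat.index, name="cluster")

    base = assessments[assessments["week"] == 0]
    totals = base.pivot_table(index=base["participant_id"].astype(str),
                              columns="measure", values="total")
    mean_phq = raw.groupby(raw).apply(
        lambda idx: totals.reindex(idx.index)["PHQ8"].mean()
        if "PHQ8" in totals else 0.0)
    order = {old: new for new, old in enumerate(mean_phq.sort_values().index)}
    assignments = raw.map(order)
    centroids = km.cluster_centers_[
        sorted(order, key=order.get)] if k > 1 else km.cluster_centers_

    mean_totals = (totals.reindex(assignments.index)
                   .groupby(assignments).mean())
    mean_totals.index.name = "cluster"
    return ClusterSolution(k=k, assignments=assignments, centroids=centroids,
                           mean_totals=mean_totals,
                           inertia_curve=inertia_curve or {})
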