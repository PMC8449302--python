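"""GPS mobility features over a two-week sensing window.

Implements the classic smartphone-mobility feature set: stationary /
transition labelling by instantaneous speed, adaptive k-means location
clustering, and seven window-level features — location variance, number of
location clusters, location entropy (raw and normalised), circadian
movement, total distance travelled, and average velocity.

All features are computed over the whole window rather than per day:
cluster counts and 24-hour periodicity are window-level constructs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle
from sklearn.cluster import KMeans

logger = logging.getLogger("laggedsense")

EARTH_RADIUS_KM = 6371.0
#: guards log() of zero variance / spectral energy
LOG_EPS = 1e-10
#: default speed above which a fix is in transition
SPEED_THRESHOLD_KMH = 1.0
#: default maximum cluster radius for adaptive k-means
MAX_CLUSTER_RADIUS_M = 500.0
#: sampling gaps longer than this break transition segments
MAX_GAP_MIN = 30.0
#: nominal sampling cadence
FIX_INTERVAL_S = 300
#: period band (hours) whose spectral energy defines circadian movement
CIRCADIAN_BAND_H = (23.5, 24.5)

GPS_FEATURES = ["location_variance", "n_clusters", "entropy",
                "normalized_entropy", "circadian_movement",
                "total_distance", "avg_velocity"]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class StationaryLabeledTrack:
    """Fixes with per-fix speed (km/h), state, and gap flags.

    ``fixes`` keeps the input columns plus ``speed`` (km/h, from the
    preceding fix), ``state`` ("stationary" / "transition") and ``gap``
    (True when the segment ending at this fix exceeds the gap limit, so no
    distance may be imputed across it).
    """

    fixes: pd.DataFrame

    @property
    def stationary(self) -> pd.DataFrame:
        return self.fixes[self.fixes["state"] == "stationary"]


def label_stationary(fixes: pd.DataFrame,
                     speed_threshold_kmh: float = SPEED_THRESHOLD_KMH,
                     max_gap_min: float = MAX_GAP_MIN) -> StationaryLabeledTrack:
    """Label each fix stationary or in transition by instantaneous speed.

    Speed at fix *i* is haversine(fix i−1, fix i) / Δt; the first fix
    inherits the second fix's state.  Segments spanning a sampling gap
    longer than ``max_gap_min`` are flagged and treated as stationary.
    """
    df = fixes.reset_index(drop=True).copy()
    n = len(df)
    if n < 2:
        logger.warning("label_stationary: <2 fixes, all-stationary track")
        df["speed"] = 0.0
        df["state"] = "stationary"
        df["gap"] = False
        return StationaryLabeledTrack(df)

    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    t = df["t"].to_numpy("datetime64[ns]").astype("int64") / 1e9  # seconds
    seg_km = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_h = np.diff(t) / 3600.0
    speed = np.concatenate([[0.0], seg_km / dt_h])
    gap = np.concatenate([[False], np.diff(t) > max_gap_min * 60.0])

    state = np.where((speed > speed_threshold_kmh) & ~gap,
                     "transition", "stationary")
    state[0] = state[1] if n > 1 else "stationary"
    speed[gap] = 0.0
    df["speed"] = speed
    df["state"] = state
    df["gap"] = gap
    return StationaryLabeledTrack(df)


@dataclass
class LocationClusterSet:
    """Adaptive k-means clusters of the stationary fixes.

    ``centroids`` is (k, 2) lat/lon; ``labels`` aligns with the stationary
    fixes' positional order; ``dwell_seconds`` credits one sampling
    interval per member fix.
    """

    centroids: np.ndarray
    labels: np.ndarray           # cluster index per stationary fix
    dwell_seconds: np.ndarray    # per cluster

    @property
    def k(self) -> int:
        return len(self.centroids)


def _to_local_xy(lat: np.ndarray, lon: np.ndarray, lat0: float) -> np.ndarray:
    """Equirectangular projection to metres around reference latitude."""
    kx = EARTH_RADIUS_KM * 1000 * np.cos(np.radians(lat0)) * np.pi / 180
    ky = EARTH_RADIUS_KM * 1000 * np.pi / 180
    return np.column_stack([lon * kx, lat * ky])


def cluster_locations(track: StationaryLabeledTrack,
                      max_cluster_radius_m: float = MAX_CLUSTER_RADIUS_M,
                      seed: int = 0) -> LocationClusterSet:
    """k-means on stationary fixes, incrementing k from 1 until every member
    lies within ``max_cluster_radius_m`` of its centroid."""
    stat = track.stationary
    if len(stat) == 0:
        return LocationClusterSet(np.empty((0, 2)), np.empty(0, dtype=int),
                                  np.empty(0))
    lat = stat["lat"].to_numpy(float)
    lon = stat["lon"].to_numpy(float)
    lat0 = float(lat.mean())
    xy = _to_local_xy(lat, lon, lat0)
    n_unique = len(np.unique(xy, axis=0))

    for k in range(1, len(stat) + 1):
        if k > n_unique:
            k = n_unique
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(xy)
        labels = km.labels_
        # member distance check in true haversine metres
        cent_lat = np.array([lat[labels == c].mean() for c in range(k)])
        cent_lon = np.array([lon[labels == c].mean() for c in range(k)])
        d_m = haversine_km(lat, lon, cent_lat[labels], cent_lon[labels]) * 1000
        if d_m.max() <= max_cluster_radius_m or k == n_unique:
            dwell = np.array([FIX_INTERVAL_S * np.sum(labels == c)
                              for c in range(k)], dtype=float)
            return LocationClusterSet(np.column_stack([cent_lat, cent_lon]),
                                      labels, dwell)
    raise AssertionError("unreachable")


def _circadian_energy(t_s: np.ndarray, y: np.ndarray,
                      band_h=CIRCADIAN_BAND_H, n_freq: int = 24) -> float:
    """Lomb–Scargle spectral power summed over the 24 h period band."""
    y = y - y.mean()
    if np.allclose(y, 0):
        return 0.0
    periods = np.linspace(band_h[0] * 3600, band_h[1] * 3600, n_freq)
    omega = 2 * np.pi / periods
    power = lombscargle(t_s, y, omega, normalize=False)
    # scipy returns A^2*n/4-scaled power; normalise to variance fraction
    return float(np.sum(power) * 2.0 / (len(y) * y.var()))


def compute_gps_features(track: StationaryLabeledTrack,
                         clusters: LocationClusterSet | None = None,
                         eps: float = LOG_EPS) -> dict[str, float]:
    """The seven window-level mobility features.

    Entropy is −Σ pᵢ ln pᵢ over per-cluster dwell fractions (nats);
    normalised entropy divides by ln k and is defined 0 at k = 1.
    Circadian movement is log of the Lomb–Scargle energy of the latitude
    and longitude series summed over 23.5–24.5 h periods.  Distance and
    velocity come from transition segments only, skipping gap segments.
    """
    missing = {f: float("nan") for f in GPS_FEATURES}
    df = track.fixes
    if len(df) < 2:
        return missing
    if clusters is None:
        clusters = cluster_locations(track)

    stat = track.stationary
    out: dict[str, float] = {}
    if len(stat):
        out["location_variance"] = float(np.log(
            stat["lat"].to_numpy().var() + stat["lon"].to_numpy().var() + eps))
    else:
        out["location_variance"] = float("nan")

    k = clusters.k
    out["n_clusters"] = float(k) if k else float("nan")
    if k >= 1:
        p = clusters.dwell_seconds / clusters.dwell_seconds.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
        out["entropy"] = entropy
        out["normalized_entropy"] = entropy / np.log(k) if k > 1 else 0.0
    else:
        out["entropy"] = out["normalized_entropy"] = float("nan")

    t_s = df["t"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    energy = (_circadian_energy(t_s, df["lat"].to_numpy(float))
              + _circadian_energy(t_s, df["lon"].to_numpy(float)))
    out["circadian_movement"] = float(np.log(energy + eps))

    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    seg_km = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    is_transition = (df["state"].to_numpy() == "transition")[1:]
    not_gap = ~df["gap"].to_numpy()[1:]
    use = is_transition & not_gap
    total = float(seg_km[use].sum())
    out["total_distance"] = total
    if total > 0:
        speeds = df["speed"].to_numpy(float)[1:][use]
        out["avg_velocity"] = float(np.average(speeds, weights=seg_km[use]))
    else:
        out["avg_velocity"] = 0.0
    return out
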