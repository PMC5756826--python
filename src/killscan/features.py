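"""Spatiotemporal characterization of detected clusters.

Seven variables summarize each cluster for the univariate comparisons and
the predictive models: spread (standard distance of member fixes about the
mean center, m), nGPSObs (member fix count), duration (hours, first to last
member fix, floored at 1), occupation (nGPSObs / duration — a residency
index that may exceed 1 for fully contiguous hourly clusters), return events
(maximal runs of absent hourly slots inside the cluster's span), starting
time of day (day/night/twilight of the first member fix) and season.  The
search start point for field crews is the member fix nearest the mean
center — a point the animal actually occupied, unlike the centroid itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import SpaceTimeCluster
from .telemetry import TimeOfDayConfig, Trajectory, label_season, label_time_of_day

__all__ = [
    "ClusterFeatures",
    "standard_distance",
    "temporal_features",
    "search_start",
    "characterize",
    "features_to_frame",
]


@dataclass
class ClusterFeatures:
    cluster_id: str
    animal_id: str
    spread: float  # meters
    n_gps_obs: int
    duration: float  # hours, floored at 1
    occupation: float  # n_gps_obs / duration
    return_events: int
    stod: str  # day | night | twilight
    season: str  # spring | summer | fall | out_of_season
    sex: str | None = None
    age_class: str | None = None


def standard_distance(x, y=None) -> float:
    """Standard distance of a point set about its mean center:
    sqrt(mean((x - xbar)^2) + mean((y - ybar)^2)).  Translation invariant."""
    if y is None:
        pts = np.asarray(x, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ValueError("standard_distance of an empty point set")
    return float(math.sqrt(np.mean((x - x.mean()) ** 2) + np.mean((y - y.mean()) ** 2)))


def temporal_features(
    member_t: np.ndarray,
    nominal_interval_hours: float = 1.0,
) -> tuple[float, float, int]:
    """(duration, occupation, return_events) from member fix times.

    duration = hours first-to-last member fix, floored at 1 so single-hour
    clusters don't divide by zero.  occupation = n / duration.  A return
    event is a maximal run of expected hourly slots strictly inside the span
    with no member fix — missing fixes count as absence, the only observable
    definition of "left and returned" from hourly data.
    """
    member_t = np.asarray(member_t, dtype="datetime64[s]")
    n = len(member_t)
    if n == 0:
        raise ValueError("no member fixes")
    member_t = np.sort(member_t)
    span_h = float((member_t[-1] - member_t[0]).astype("timedelta64[s]").astype(float) / 3600.0)
    duration = max(span_h, 1.0)
    occupation = n / duration
    # slot index of each member relative to the first, in nominal intervals
    rel = (member_t - member_t[0]).astype("timedelta64[s]").astype(float) / 3600.0
    slots = np.unique(np.round(rel / nominal_interval_hours).astype(int))
    gaps = int(np.sum(np.diff(slots) > 1))
    return duration, occupation, gaps


def search_start(member_x: np.ndarray, member_y: np.ndarray,
                 member_t: np.ndarray | None = None) -> int:
    """Index of the member fix nearest the mean center (tie: earliest).

    Field crews start their spiral search here rather than at the centroid,
    which the animal may never have occupied."""
    x = np.asarray(member_x, dtype=float)
    y = np.asarray(member_y, dtype=float)
    if len(x) == 0:
        raise ValueError("no member fixes")
    d = np.hypot(x - x.mean(), y - y.mean())
    if member_t is not None:
        t = np.asarray(member_t)
        best = np.flatnonzero(np.isclose(d, d.min()))
        return int(best[np.argmin(t[best])])
    return int(np.argmin(d))


def characterize(
    cluster: SpaceTimeCluster,
    traj: Trajectory,
    tod: TimeOfDayConfig | None = None,
    tz_offset_hours: float = 0.0,
) -> ClusterFeatures:
    """Assemble the seven-variable feature record for one cluster.

    SToD and season come from the chronologically first member fix.  A first
    fix outside the three field seasons is labeled ``out_of_season`` and the
    record retained."""
    if tod is None:
        tod = TimeOfDayConfig(scheme="clock", tz_offset_hours=tz_offset_hours)
    ids = set(cluster.member_fix_ids)
    mask = np.array([fid in ids for fid in traj.fix_ids], dtype=bool)
    if not mask.any():
        raise ValueError("cluster members not found in trajectory")
    mx, my, mt = traj.x[mask], traj.y[mask], traj.t[mask]
    duration, occupation, returns = temporal_features(mt, traj.nominal_interval)
    first = pd.Timestamp(mt.min())
    return ClusterFeatures(
        cluster_id=cluster.cluster_id,
        animal_id=cluster.animal_id,
        spread=standard_distance(mx, my),
        n_gps_obs=int(mask.sum()),
        duration=duration,
        occupation=occupation,
        return_events=returns,
        stod=label_time_of_day(first, tod),
        season=label_season(first, tz_offset_hours),
        sex=traj.sex,
        age_class=traj.age_class,
    )


def features_to_frame(features: list[ClusterFeatures]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in features])
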