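"""Windowed kill-site detection pipeline.

A collared animal's fix record is split into 14-day windows overlapping by
7 days (so a residency bout straddling one arbitrary boundary is intact in
the neighboring window), each window is scanned with the STPSS, significant
clusters are pooled and de-duplicated (the same bout found in two
overlapping windows shares member fixes), and clusters are ranked for field
visits.  A retrospective labeler marks arbitrary locations as falling
within/outside the detected clusters — the design used to validate the
protocol against randomly visited GPS locations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stpss import Cylinder, ScanConfig, ScanResult, scan_window
from .telemetry import Trajectory

__all__ = [
    "Window",
    "SpaceTimeCluster",
    "make_windows",
    "detect_clusters",
    "deduplicate",
    "select_visits",
    "label_points",
    "detection_probability",
    "clusters_to_frame",
    "clusters_to_geojson",
    "export_satscan",
]

WINDOW_DAYS = 14
STRIDE_DAYS = 7


@dataclass(frozen=True)
class Window:
    """One 14-day scan period; consecutive windows overlap by 7 days."""

    start: np.datetime64
    end: np.datetime64
    index: int
    animal_id: str | None = None


@dataclass
class SpaceTimeCluster:
    """A significant cluster with provenance back to its source window."""

    cluster_id: str
    animal_id: str
    window_index: int
    cylinder: Cylinder
    alpha: float

    @property
    def significant(self) -> bool:
        return self.cylinder.p is not None and self.cylinder.p <= self.alpha

    @property
    def member_fix_ids(self) -> frozenset[str]:
        return self.cylinder.member_fix_ids

    @property
    def n_fixes(self) -> int:
        return self.cylinder.c

    @property
    def start_time(self) -> np.datetime64:
        return self.cylinder.t_start_time

    @property
    def end_time(self) -> np.datetime64:
        return self.cylinder.t_end_time

    @property
    def duration_hours(self) -> float:
        dt = (self.cylinder.t_end_time - self.cylinder.t_start_time)
        return float(dt.astype("timedelta64[s]").astype(float) / 3600.0)


def make_windows(t0, t1, animal_id: str | None = None) -> list[Window]:
    """Overlapping scan windows covering [t0, t1].

    Windows are [t0 + 7k, t0 + 7k + 14) days for k = 0..K with
    K = max(0, floor((t1 - t0)/7d) - 1).  Every instant in [t0, t1] falls in
    at least one window; instants more than 7 days from both ends fall in
    exactly two.  The final window may extend past t1 (scanned with whatever
    fixes exist).
    """
    t0 = np.datetime64(pd.Timestamp(t0).to_datetime64(), "s")
    t1 = np.datetime64(pd.Timestamp(t1).to_datetime64(), "s")
    if t1 <= t0:
        raise ValueError("t1 must be after t0")
    stride = np.timedelta64(STRIDE_DAYS * 86400, "s")
    width = np.timedelta64(WINDOW_DAYS * 86400, "s")
    span_strides = int((t1 - t0) // stride)
    K = max(0, span_strides - 1)  # windows k = 0..K
    return [
        Window(start=t0 + k * stride, end=t0 + k * stride + width, index=k,
               animal_id=animal_id)
        for k in range(K + 1)
    ]


def detect_clusters(
    traj: Trajectory,
    config: ScanConfig,
    t0=None,
    t1=None,
) -> list[SpaceTimeCluster]:
    """Scan every window of *traj* and collect significant clusters.

    Each window's scan gets its own RNG stream derived from
    ``config.rng_seed`` and the window index, so results are deterministic
    under a fixed seed and independent of how many windows run.  Errors in
    one window do not abort the others.
    """
    if len(traj) == 0:
        return []
    t0 = traj.t[0] if t0 is None else np.datetime64(pd.Timestamp(t0).to_datetime64(), "s")
    t1 = traj.t[-1] if t1 is None else np.datetime64(pd.Timestamp(t1).to_datetime64(), "s")
    if t1 <= t0:
        t1 = t0 + np.timedelta64(1, "s")
    windows = make_windows(t0, t1, animal_id=traj.animal_id)
    seed_seq = np.random.SeedSequence(config.rng_seed if config.rng_seed is not None else 0)
    child_seeds = seed_seq.spawn(len(windows))
    out: list[SpaceTimeCluster] = []
    for win, child in zip(windows, child_seeds):
        piece = traj.slice_time(win.start, win.end)
        if len(piece) < config.min_observed:
            continue
        win_config = ScanConfig(
            max_radius=config.max_radius,
            max_span=config.max_span,
            n_replicates=config.n_replicates,
            alpha=config.alpha,
            min_observed=config.min_observed,
            rng_seed=int(child.generate_state(1)[0] % (2**31)),
        )
        try:
            result: ScanResult = scan_window(piece, win_config)
        except Exception:  # pragma: no cover - per-window isolation
            continue
        for i, cyl in enumerate(result.significant):
            out.append(
                SpaceTimeCluster(
                    cluster_id=f"{traj.animal_id}-w{win.index}-c{i}",
                    animal_id=traj.animal_id,
                    window_index=win.index,
                    cylinder=cyl,
                    alpha=config.alpha,
                )
            )
    return out


def deduplicate(clusters: list[SpaceTimeCluster]) -> list[SpaceTimeCluster]:
    """Collapse duplicate clusters found in overlapping windows.

    Two clusters of the same animal are duplicates iff their member-fix sets
    intersect (window overlap guarantees a re-found bout shares fixes).
    Within each duplicate group the largest-GLR cluster is kept (tie: the
    earlier window).  Idempotent; never increases the cluster count.
    """
    by_animal: dict[str, list[SpaceTimeCluster]] = {}
    for cl in clusters:
        by_animal.setdefault(cl.animal_id, []).append(cl)
    kept: list[SpaceTimeCluster] = []
    for animal in by_animal:
        group = by_animal[animal]
        # union-find over member-set intersection
        parent = list(range(len(group)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        fix_owner: dict[str, int] = {}
        for i, cl in enumerate(group):
            for f in cl.member_fix_ids:
                if f in fix_owner:
                    ri, rj = find(i), find(fix_owner[f])
                    if ri != rj:
                        parent[ri] = rj
                else:
                    fix_owner[f] = i
        comps: dict[int, list[SpaceTimeCluster]] = {}
        for i, cl in enumerate(group):
            comps.setdefault(find(i), []).append(cl)
        for comp in comps.values():
            best = min(comp, key=lambda cl: (-cl.cylinder.log_glr, cl.window_index))
            kept.append(best)
    kept.sort(key=lambda cl: (cl.animal_id, cl.start_time.astype("int64")
                              if cl.start_time is not None else 0))
    return kept


def select_visits(
    clusters: list[SpaceTimeCluster],
    per_bear_per_week: int = 2,
    extra_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[SpaceTimeCluster]:
    """Field-visit selection: the largest clusters per animal per ISO week
    plus a seeded random fraction of the remainder.

    "Largest" means most member fixes, ties broken by longer duration, then
    larger GLR — the clusters most likely to reward a site visit.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    groups: dict[tuple[str, tuple[int, int]], list[SpaceTimeCluster]] = {}
    for cl in clusters:
        iso = pd.Timestamp(cl.start_time).isocalendar()
        groups.setdefault((cl.animal_id, (iso.year, iso.week)), []).append(cl)
    chosen: list[SpaceTimeCluster] = []
    leftovers: list[SpaceTimeCluster] = []
    for key in sorted(groups):
        grp = sorted(
            groups[key],
            key=lambda cl: (-cl.n_fixes, -cl.duration_hours, -cl.cylinder.log_glr,
                            cl.cluster_id),
        )
        chosen.extend(grp[:per_bear_per_week])
        leftovers.extend(grp[per_bear_per_week:])
    if extra_fraction > 0 and leftovers:
        k = int(round(extra_fraction * len(leftovers)))
        if k > 0:
            idx = rng.choice(len(leftovers), size=min(k, len(leftovers)), replace=False)
            chosen.extend(leftovers[i] for i in sorted(idx))
    chosen.sort(key=lambda cl: (cl.animal_id, cl.start_time.astype("int64")))
    return chosen


def label_points(
    points: pd.DataFrame,
    clusters: list[SpaceTimeCluster],
    max_radius: float = 50.0,
) -> list[str]:
    """Label each point (columns ``timestamp``, ``x``, ``y``) as ``within``
    or ``outside`` the detected clusters.

    A point is *within* iff some cluster has t_start <= t <= t_end and the
    point lies within *max_radius* of the cluster's cylinder center — the
    same 50 m spatial constraint the scan used.
    """
    ts = pd.to_datetime(points["timestamp"])
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    t = ts.to_numpy().astype("datetime64[s]")
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    within = np.zeros(len(points), dtype=bool)
    for cl in clusters:
        cx, cy = cl.cylinder.center
        m = (
            (t >= cl.start_time)
            & (t <= cl.end_time)
            & (np.hypot(x - cx, y - cy) <= max_radius)
        )
        within |= m
    return ["within" if w else "outside" for w in within]


def detection_probability(n_events: int, n_visits: int) -> float:
    """Probability of finding a predation event per visited site, with its
    binomial standard error available via :func:`scipy.stats` if needed."""
    if n_visits <= 0:
        raise ValueError("n_visits must be positive")
    return n_events / n_visits


# ---------------------------------------------------------------------------
# export helpers

def clusters_to_frame(clusters: list[SpaceTimeCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        cy = cl.cylinder
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "animal_id": cl.animal_id,
                "window_index": cl.window_index,
                "center_x": cy.center[0],
                "center_y": cy.center[1],
                "radius_m": cy.radius,
                "t_start": pd.Timestamp(cy.t_start_time).isoformat() if cy.t_start_time is not None else "",
                "t_end": pd.Timestamp(cy.t_end_time).isoformat() if cy.t_end_time is not None else "",
                "n_fixes": cy.c,
                "expected": cy.mu,
                "glr": cy.glr,
                "p": cy.p,
                "member_fix_ids": ";".join(sorted(cy.member_fix_ids)),
            }
        )
    return pd.DataFrame(rows)


def clusters_to_geojson(clusters: list[SpaceTimeCluster]) -> dict:
    """Cluster centers as GeoJSON points (planar coordinates) with radius,
    time span, counts, GLR and p as properties."""
    feats = []
    for cl in clusters:
        cy = cl.cylinder
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [cy.center[0], cy.center[1]]},
                "properties": {
                    "cluster_id": cl.cluster_id,
                    "animal_id": cl.animal_id,
                    "radius_m": cy.radius,
                    "t_start": pd.Timestamp(cy.t_start_time).isoformat() if cy.t_start_time is not None else None,
                    "t_end": pd.Timestamp(cy.t_end_time).isoformat() if cy.t_end_time is not None else None,
                    "n_fixes": cy.c,
                    "expected": cy.mu,
                    "glr": cy.glr,
                    "p": cy.p,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def export_satscan(traj: Trajectory, cas_path, geo_path) -> None:
    """Write one animal-window as SaTScan-compatible case (.cas) and
    coordinate (.geo) files for cross-checking against the reference scan
    software.  Each fix is one location with one case at its fix time."""
    with open(geo_path, "w", newline="") as geo, open(cas_path, "w", newline="") as cas:
        for i in range(len(traj)):
            loc = f"loc{i}"
            geo.write(f"{loc} {traj.y[i]:.3f} {traj.x[i]:.3f}\n")
            stamp = pd.Timestamp(traj.t[i]).strftime("%Y/%m/%d/%H")
            cas.write(f"{loc} 1 {stamp}\n")
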