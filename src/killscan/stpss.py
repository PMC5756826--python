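"""Retrospective space–time permutation scan statistic (STPSS) over GPS fixes.

The scan centers space–time cylinders on every observed fix: the base is a
circle through an observed fix location (radius capped, default 50 m), the
height a closed time interval between observed fix times (span capped,
default 7 days).  Conditioning on the spatial and temporal marginals, the
expected count in a cylinder is mu = n_s * n_t / N, and each cylinder is
scored with the Poisson generalized likelihood ratio

    GLR = (c/mu)^c * ((N-c)/(N-mu))^(N-c)   for c > mu, else 1.

Inference is by Monte Carlo: times are uniformly re-permuted over locations,
the maximum GLR over all candidate cylinders is recorded per replicate, and
each observed cylinder gets p = (1 + #{replicate maxima >= GLR}) / (R + 1).
Because the null conditions on both marginals, only genuine space–time
interaction (an animal lingering somewhere for a stretch of time) scores.

Candidate geometry is a finite sufficient set: radii are enumerated only at
observed center-to-fix distances and interval endpoints only at member fix
times — any other cylinder has identical membership to an enumerated one.
Cylinders with identical member sets are collapsed to the tightest
representative (smallest mu, then radius, then center index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .telemetry import Trajectory

__all__ = [
    "ScanConfig",
    "Cylinder",
    "ScanResult",
    "candidate_cylinders",
    "expected_count",
    "poisson_glr",
    "permute_times",
    "scan_window",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    Defaults follow grizzly-bear kill-site biology: a 50 m maximum radius
    (carcasses are handled within tens of meters) and a 168 h (7 day) maximum
    cylinder height from maximum kill handling time.
    """

    max_radius: float = 50.0  # meters
    max_span: float = 168.0  # hours
    n_replicates: int = 999
    alpha: float = 0.05
    min_observed: int = 2
    rng_seed: int | None = None

    def __post_init__(self):
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_observed < 1:
            raise ValueError("min_observed must be >= 1")


@dataclass
class Cylinder:
    """A candidate space–time cluster.

    ``t_start``/``t_end`` are hours relative to the scanned window's first
    fix; when the scan input is a :class:`Trajectory`, ``t_start_time`` /
    ``t_end_time`` carry the absolute timestamps and ``member_fix_ids`` the
    fix tokens.
    """

    center_idx: int
    center: tuple[float, float]
    radius: float
    t_start: float
    t_end: float
    c: int
    n_s: int
    n_t: int
    mu: float
    log_glr: float
    member_idx: tuple[int, ...]
    p: float | None = None
    t_start_time: np.datetime64 | None = None
    t_end_time: np.datetime64 | None = None
    member_fix_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def glr(self) -> float:
        return float(np.exp(self.log_glr))

    @property
    def member_set(self) -> frozenset[int]:
        return frozenset(self.member_idx)


@dataclass
class ScanResult:
    """Ranked non-overlapping clusters from one animal-window scan."""

    clusters: list[Cylinder]
    null_max_glr: np.ndarray  # per-replicate maximum log-GLR (natural log)
    n_fixes: int
    config: ScanConfig

    @property
    def significant(self) -> list[Cylinder]:
        return [c for c in self.clusters if c.p is not None and c.p <= self.config.alpha]


def poisson_glr(c: float, mu: float, n_total: float) -> float:
    """Poisson generalized likelihood ratio for an observed count *c* against
    expectation *mu* out of *n_total* events.  Returns 1 when c <= mu."""
    return float(np.exp(_log_glr(c, mu, n_total)))


def _log_glr(c, mu, n_total):
    c = float(c)
    mu = float(mu)
    N = float(n_total)
    if not (0 <= c <= N and 0 <= mu <= N):
        raise ValueError("require 0 <= c <= N and 0 <= mu <= N")
    if c <= mu:
        return 0.0
    if mu == 0.0:
        # cannot arise for cylinders built from observed fixes (the center
        # fix itself contributes to both marginals)
        raise ValueError("mu = 0 with c > 0: invalid cylinder")
    out = c * np.log(c / mu)
    if N - c > 0:
        out += (N - c) * np.log((N - c) / (N - mu))
    return float(out)


def permute_times(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly reassign the multiset of times to locations (the STPSS
    null).  Input order corresponds to locations; output times are a random
    permutation of the input times."""
    t = np.asarray(t)
    if len(t) < 2:
        return t.copy()
    return t[rng.permutation(len(t))]


# ---------------------------------------------------------------------------
# candidate enumeration machinery

class _ScanGeometry:
    """Spatial candidate structure for one window; invariant under the
    time-permutation null, so it is built once and reused across replicates.

    For each center fix, neighbor distances within max_radius define the
    distinct candidate radii; each (center, radius) yields a spatial member
    set.  Sets are deduplicated (same index set from several center/radius
    combinations keeps the smallest radius, then center index).

    On top of the sets a flat pair structure is precomputed: every
    (set, a, b) with a <= b positional indices into the set's time-sorted
    member block.  Window fix times are distinct, so after sorting member
    times within each set the member count of interval (a, b) is simply
    b - a + 1, and a whole Monte Carlo replicate reduces to one lexsort plus
    vectorized arithmetic over all pairs.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, config: ScanConfig):
        self.config = config
        n = len(x)
        self.n = n
        dx = x[:, None] - x[None, :]
        dy = y[:, None] - y[None, :]
        d = np.hypot(dx, dy)
        sets: dict[tuple[int, ...], tuple[float, int, np.ndarray]] = {}
        min_sz = max(config.min_observed, 1)
        for i in range(n):
            di = d[i]
            within = np.flatnonzero(di <= config.max_radius)
            order = within[np.argsort(di[within], kind="stable")]
            radii = di[order]
            # distinct radii: the set grows only where the sorted distance
            # strictly increases
            for k in range(len(order)):
                if k + 1 < len(order) and radii[k + 1] == radii[k]:
                    continue
                members = np.sort(order[: k + 1])
                if len(members) < min_sz:
                    continue
                key = tuple(members.tolist())
                r = float(radii[k])
                prev = sets.get(key)
                if prev is None or (r, i) < (prev[0], prev[1]):
                    sets[key] = (r, i, members)
        # spatial sets sorted for determinism
        self.spatial = sorted(
            ((r, ci, m) for (r, ci, m) in sets.values()),
            key=lambda e: (len(e[2]), e[0], e[1], e[2].tolist()),
        )
        self._build_pairs()

    def _build_pairs(self) -> None:
        cfg = self.config
        sizes = [len(m) for _, _, m in self.spatial]
        self.member_concat = (
            np.concatenate([m for _, _, m in self.spatial])
            if self.spatial else np.zeros(0, dtype=int)
        )
        self.set_ids = np.repeat(np.arange(len(sizes)), sizes) if sizes else np.zeros(0, dtype=int)
        self.block_start = np.zeros(len(sizes), dtype=int)
        if sizes:
            self.block_start[1:] = np.cumsum(sizes)[:-1]
        self.set_ns = np.asarray(sizes, dtype=float)
        k0 = 0 if cfg.min_observed == 1 else 1
        pa_parts, pb_parts, ps_parts = [], [], []
        for s, m in enumerate(sizes):
            a, b = np.triu_indices(m, k=k0)
            pa_parts.append(a + self.block_start[s])
            pb_parts.append(b + self.block_start[s])
            ps_parts.append(np.full(len(a), s, dtype=int))
        if pa_parts:
            self.pa = np.concatenate(pa_parts)
            self.pb = np.concatenate(pb_parts)
            self.pair_set = np.concatenate(ps_parts)
            self.pair_ns = self.set_ns[self.pair_set]
            self.pair_c = (self.pb - self.pa + 1).astype(float)
        else:
            self.pa = self.pb = self.pair_set = np.zeros(0, dtype=int)
            self.pair_ns = self.pair_c = np.zeros(0)

    def _sorted_member_times(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Member times sorted within each set block; returns (times, order)."""
        u = t[self.member_concat]
        order = np.lexsort((u, self.set_ids))
        return u[order], order

    def _pair_stats(self, t: np.ndarray, t_sorted: np.ndarray):
        """Span-valid pair statistics for time vector *t*.

        Returns (pair_index, ta, tb, c, n_t, mu, order) where pair_index
        indexes into the precomputed pair arrays and order is the
        time-sorting permutation of member_concat.  Requires distinct times
        (guaranteed for hourly windows and their permutations)."""
        us, order = self._sorted_member_times(t)
        ta = us[self.pa]
        tb = us[self.pb]
        idx = np.flatnonzero((tb - ta) <= self.config.max_span)
        ta = ta[idx]
        tb = tb[idx]
        n_t = (
            np.searchsorted(t_sorted, tb, side="right")
            - np.searchsorted(t_sorted, ta, side="left")
        )
        mu = self.pair_ns[idx] * n_t / self.n
        return idx, ta, tb, self.pair_c[idx], n_t, mu, order

    @staticmethod
    def _vector_log_glr(c: np.ndarray, mu: np.ndarray, N: float) -> np.ndarray:
        """log GLR per pair; 0 where c <= mu."""
        out = np.zeros(len(c))
        m = c > mu
        cm = c[m]
        mm = mu[m]
        ll = cm * np.log(cm / mm)
        rest = N - cm
        pos = rest > 0
        ll[pos] += rest[pos] * np.log(rest[pos] / (N - mm[pos]))
        out[m] = ll
        return out

    def max_log_glr(self, t: np.ndarray, t_sorted: np.ndarray) -> float:
        """Maximum log-GLR over all candidate cylinders for time vector *t*
        (aligned with locations).  Used for the Monte Carlo null."""
        if len(self.pa) == 0:
            return 0.0
        _, _, _, c, _, mu, _ = self._pair_stats(t, t_sorted)
        mask = c > mu
        if not mask.any():
            return 0.0
        return float(self._vector_log_glr(c[mask], mu[mask], self.n).max())

    def _check_distinct(self, t: np.ndarray) -> None:
        if len(np.unique(t)) != len(t):
            raise ValueError("fix times within a window must be distinct "
                             "(regularize to hourly first)")

    def _pair_order(self, idx, ta, llr):
        """Deterministic processing order: decreasing GLR, then increasing
        mu is implied by GLR for a fixed member set; remaining ties broken
        by radius, start time, center index, pair index."""
        radius = np.array([self.spatial[s][0] for s in self.pair_set[idx]])
        center = np.array([self.spatial[s][1] for s in self.pair_set[idx]])
        return np.lexsort((idx, center, ta, radius, -llr))

    def enumerate_candidates(self, t: np.ndarray, x: np.ndarray, y: np.ndarray) -> list[Cylinder]:
        """All deduplicated candidate cylinders for the observed times."""
        if len(self.pa) == 0:
            return []
        cfg = self.config
        N = self.n
        self._check_distinct(t)
        t_sorted = np.sort(t)
        idx, ta, tb, c, n_t, mu, order = self._pair_stats(t, t_sorted)
        members_sorted = self.member_concat[order]
        keep = c >= cfg.min_observed
        idx, ta, tb, c, n_t, mu = (a[keep] for a in (idx, ta, tb, c, n_t, mu))
        llr = self._vector_log_glr(c, mu, N)
        best: dict[tuple[int, ...], Cylinder] = {}
        for j in range(len(idx)):
            pj = idx[j]
            s = self.pair_set[pj]
            # the slice is time-sorted, hence canonical for the member set
            key = tuple(members_sorted[self.pa[pj]:self.pb[pj] + 1].tolist())
            radius, center_idx, _ = self.spatial[s]
            cand_rank = (mu[j], radius, center_idx)
            prev = best.get(key)
            if prev is not None and (prev.mu, prev.radius, prev.center_idx) <= cand_rank:
                continue
            best[key] = Cylinder(
                center_idx=center_idx,
                center=(float(x[center_idx]), float(y[center_idx])),
                radius=radius,
                t_start=float(ta[j]),
                t_end=float(tb[j]),
                c=int(c[j]),
                n_s=int(self.set_ns[s]),
                n_t=int(n_t[j]),
                mu=float(mu[j]),
                log_glr=float(llr[j]),
                member_idx=key,
            )
        return sorted(
            best.values(),
            key=lambda cy: (-cy.log_glr, cy.radius, cy.t_start, cy.center_idx, cy.member_idx),
        )

    def greedy_clusters(self, t: np.ndarray, x: np.ndarray, y: np.ndarray) -> list[Cylinder]:
        """Most-likely cluster plus secondary clusters (GLR order, no shared
        member fixes), equivalent to a greedy sweep of
        :meth:`enumerate_candidates` but without materializing every
        duplicate member set."""
        if len(self.pa) == 0:
            return []
        cfg = self.config
        N = self.n
        self._check_distinct(t)
        t_sorted = np.sort(t)
        idx, ta, tb, c, n_t, mu, order = self._pair_stats(t, t_sorted)
        members_sorted = self.member_concat[order]
        # only cylinders with an observed excess (c > mu, GLR > 1) carry any
        # evidence and are worth reporting
        keep = (c >= cfg.min_observed) & (c > mu)
        idx, ta, tb, c, n_t, mu = (a[keep] for a in (idx, ta, tb, c, n_t, mu))
        llr = self._vector_log_glr(c, mu, N)
        used = np.zeros(N, dtype=bool)
        out: list[Cylinder] = []
        for j in self._pair_order(idx, ta, llr):
            pj = idx[j]
            mem = members_sorted[self.pa[pj]:self.pb[pj] + 1]
            if used[mem[0]] or used[mem[-1]] or used[mem].any():
                continue
            used[mem] = True
            s = self.pair_set[pj]
            radius, center_idx, _ = self.spatial[s]
            out.append(
                Cylinder(
                    center_idx=center_idx,
                    center=(float(x[center_idx]), float(y[center_idx])),
                    radius=radius,
                    t_start=float(ta[j]),
                    t_end=float(tb[j]),
                    c=int(c[j]),
                    n_s=int(self.set_ns[s]),
                    n_t=int(n_t[j]),
                    mu=float(mu[j]),
                    log_glr=float(llr[j]),
                    member_idx=tuple(mem.tolist()),
                )
            )
        return out


def _as_arrays(fixes):
    """Accept a Trajectory or (t_hours, x, y) arrays; times in hours."""
    if isinstance(fixes, Trajectory):
        if len(fixes) == 0:
            return np.array([]), np.array([]), np.array([]), fixes
        t0 = fixes.t[0]
        t_h = (fixes.t - t0).astype("timedelta64[s]").astype(float) / 3600.0
        return t_h, fixes.x.astype(float), fixes.y.astype(float), fixes
    t_h, x, y = fixes
    return (
        np.asarray(t_h, dtype=float),
        np.asarray(x, dtype=float),
        np.asarray(y, dtype=float),
        None,
    )


def candidate_cylinders(fixes, config: ScanConfig) -> list[Cylinder]:
    """Enumerate all deduplicated candidate cylinders for one window.

    *fixes* is a time-sorted :class:`Trajectory` or a ``(t_hours, x, y)``
    triple.  Returns cylinders sorted by decreasing GLR.
    """
    t, x, y, _ = _as_arrays(fixes)
    if len(t) == 0:
        return []
    geom = _ScanGeometry(x, y, config)
    return geom.enumerate_candidates(t, x, y)


def expected_count(cyl: Cylinder, fixes) -> float:
    """Permutation-model expectation mu = n_s * n_t / N for *cyl* computed by
    brute-force membership against *fixes* (self-consistency / oracle use)."""
    t, x, y, _ = _as_arrays(fixes)
    n = len(t)
    if n == 0:
        raise ValueError("no fixes")
    d = np.hypot(x - cyl.center[0], y - cyl.center[1])
    n_s = int((d <= cyl.radius).sum())
    n_t = int(((t >= cyl.t_start) & (t <= cyl.t_end)).sum())
    return n_s * n_t / n


def scan_window(fixes, config: ScanConfig) -> ScanResult:
    """Run the full scan on one animal-window.

    Computes the GLR for every candidate cylinder, builds the Monte Carlo
    null from ``config.n_replicates`` time permutations (replicate statistic:
    maximum GLR over all candidates), assigns each reported cluster
    p = (1 + #{replicate maxima >= GLR}) / (R + 1), and reports the
    most-likely cluster followed by secondary clusters in GLR order that
    share no member fix with a higher-ranked reported cluster.
    """
    t, x, y, traj = _as_arrays(fixes)
    n = len(t)
    if n < config.min_observed:
        return ScanResult([], np.zeros(config.n_replicates), n, config)
    geom = _ScanGeometry(x, y, config)
    reported = geom.greedy_clusters(t, x, y)

    rng = np.random.default_rng(config.rng_seed)
    t_sorted = np.sort(t)
    null = np.empty(config.n_replicates)
    for r in range(config.n_replicates):
        null[r] = geom.max_log_glr(permute_times(t, rng), t_sorted)

    for cy in reported:
        cy.p = float((1 + np.sum(null >= cy.log_glr - 1e-12)) / (config.n_replicates + 1))
        if traj is not None:
            t0 = traj.t[0]
            cy.t_start_time = t0 + np.timedelta64(int(round(cy.t_start * 3600)), "s")
            cy.t_end_time = t0 + np.timedelta64(int(round(cy.t_end * 3600)), "s")
            cy.member_fix_ids = frozenset(traj.fix_ids[list(cy.member_idx)])
    return ScanResult(reported, null, n, config)
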