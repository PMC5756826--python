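"""Independent brute-force oracle for the space-time scan.

Enumerates every cylinder literally from the definition: each observed fix
as center, every center-to-fix distance within the radius cap as a radius,
every ordered pair of observed fix times within the span cap as an
interval; membership by direct point-in-cylinder test.  Duplicate member
sets collapse to the minimum-(mu, radius, center) representative, mirroring
the documented canonical rule, but through none of the package's scan code.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_candidates(t, x, y, max_radius, max_span, min_observed):
    """dict: member frozenset -> (c, n_s, n_t, mu, glr, radius, center_idx,
    t_start, t_end)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    best = {}
    times = np.unique(t)
    for i in range(n):
        d = np.hypot(x - x[i], y - y[i])
        radii = sorted(set(d[d <= max_radius]))
        for r in radii:
            smask = d <= r
            n_s = int(smask.sum())
            for ai in range(len(times)):
                for bi in range(ai, len(times)):
                    ta, tb = times[ai], times[bi]
                    if tb - ta > max_span:
                        break
                    tmask = (t >= ta) & (t <= tb)
                    members = frozenset(np.flatnonzero(smask & tmask).tolist())
                    c = len(members)
                    if c < min_observed:
                        continue
                    n_t = int(tmask.sum())
                    mu = n_s * n_t / n
                    rank = (mu, r, i)
                    prev = best.get(members)
                    if prev is not None and (prev[3], prev[5], prev[6]) <= rank:
                        continue
                    mt = t[list(members)]
                    best[members] = (
                        c, n_s, n_t, mu, oracle_glr(c, mu, n), r, i,
                        float(mt.min()), float(mt.max()),
                    )
    return best


def oracle_glr(c, mu, n):
    if c <= mu:
        return 1.0
    val = (c / mu) ** c
    if n - c > 0:
        val *= ((n - c) / (n - mu)) ** (n - c)
    return val


def oracle_greedy(cands):
    """Non-overlapping clusters in decreasing GLR order (ties: smaller
    radius, earlier start, smaller center), GLR > 1 only."""
    # entry = (members, c, n_s, n_t, mu, glr, radius, center, t_start, t_end)
    entries = [
        (members, *vals) for members, vals in cands.items() if vals[4] > 1.0
    ]
    entries.sort(key=lambda e: (-e[5], e[6], e[8], e[7]))
    out = []
    used = set()
    for e in entries:
        if used & e[0]:
            continue
        used |= e[0]
        out.append(e)
    return out
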