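"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive expected results from first principles
(exhaustive enumeration, closed-form combinatorics, O(n^2) geometry) and
share no code with the package implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_call_peaks(probes, params):
    """Enumerate every candidate probe run at every threshold level.

    ``probes``: DataFrame with chrom/start/end/intensity/masked.  Returns a
    list of dicts (chrom, start, end, rank_threshold, n_probes,
    max_intensity) sorted like the implementation's output.

    A candidate run at level p is any (i, j) index pair over the unmasked
    probes of one chromosome such that every probe's intensity exceeds the
    floor, consecutive start coordinates are within the window, the run is
    maximal under those two constraints, and at least ``min_probes_above``
    probes exceed the p-th percentile of all unmasked intensities.
    Candidates are collected level by level from the highest; a candidate
    overlapping an already-recorded call merges into it (coordinates
    extended, rank kept).
    """
    um = probes.loc[~probes["masked"].astype(bool)]
    if len(um) < params.min_probes_above:
        return []
    all_vals = um["intensity"].to_numpy(dtype=float)
    levels = [params.p_start - i * params.p_step for i in range(params.n_steps + 1)]

    calls = []  # dicts, mutated in place on merge
    for p in levels:
        threshold = np.percentile(all_vals, p)
        for chrom in sorted(um["chrom"].unique()):
            sub = um[um["chrom"] == chrom]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            v = sub["intensity"].to_numpy(dtype=float)
            n = len(sub)
            for i in range(n):
                for j in range(i, n):
                    seg = v[i : j + 1]
                    if not (seg > params.floor_value).all():
                        continue
                    gaps_ok = all(
                        s[t + 1] - s[t] <= params.window_bp for t in range(i, j)
                    )
                    if not gaps_ok:
                        continue
                    # maximality
                    if i > 0 and v[i - 1] > params.floor_value and (
                        s[i] - s[i - 1] <= params.window_bp
                    ):
                        continue
                    if j < n - 1 and v[j + 1] > params.floor_value and (
                        s[j + 1] - s[j] <= params.window_bp
                    ):
                        continue
                    if int((seg > threshold).sum()) < params.min_probes_above:
                        continue
                    cand = dict(
                        chrom=chrom, start=int(s[i]), end=int(e[j]),
                        rank_threshold=float(p), n_probes=j - i + 1,
                        max_intensity=float(seg.max()),
                    )
                    merged = False
                    for call in calls:
                        if (
                            call["chrom"] == chrom
                            and call["start"] < cand["end"]
                            and cand["start"] < call["end"]
                        ):
                            call["start"] = min(call["start"], cand["start"])
                            call["end"] = max(call["end"], cand["end"])
                            call["n_probes"] = max(call["n_probes"], cand["n_probes"])
                            call["max_intensity"] = max(
                                call["max_intensity"], cand["max_intensity"]
                            )
                            merged = True
                            break
                    if not merged:
                        calls.append(cand)
    calls.sort(
        key=lambda c: (
            -c["rank_threshold"], -c["max_intensity"], c["chrom"], c["start"]
        )
    )
    return calls[: params.max_peaks]


def brute_force_knee(ranks, cumulative):
    """Knee rank by explicit point-to-chord geometry, or None if no point
    lies above the chord."""
    x = np.asarray(ranks, dtype=float)
    y = np.asarray(cumulative, dtype=float)
    x1, y1, x2, y2 = x[0], y[0], x[-1], y[-1]
    length = ((x2 - x1) ** 2 + (y2 - y1) ** 2) ** 0.5
    if length == 0:
        return None
    best_rank, best_dev = None, 0.0
    for xi, yi in zip(x, y):
        # signed area of the triangle (chord start, chord end, point);
        # positive when the point is left of the chord direction = above it
        area2 = (x2 - x1) * (yi - y1) - (y2 - y1) * (xi - x1)
        dev = area2 / length
        if dev > best_dev + 1e-12:
            best_dev = dev
            best_rank = int(xi)
    return best_rank


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) as a Fraction by counting favourable draws."""
    total = comb(N, n)
    favourable = sum(
        comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    )
    return Fraction(favourable, total)


def union_find_clusters(intervals, margin):
    """Transitive clusters of margin-expanded overlapping intervals via
    explicit union-find.  ``intervals``: list of (chrom, start, end).
    Returns a list of frozensets of input indices."""
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and si - margin < ej + margin and sj - margin < ei + margin:
                union(i, j)
    clusters: dict[int, set[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in clusters.values()]


def pearson_t_pvalue(x, y):
    """Pearson r and two-sided p via the t transform, computed from the
    definition (no scipy.pearsonr)."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * tdist.sf(abs(t), n - 2))
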