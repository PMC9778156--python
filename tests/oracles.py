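"""Independent brute-force oracles used by the test suite and the
acceptance script.  Everything here is deliberately naive (grid search,
explicit enumeration, O(n^2) loops) and shares no code with the package's
implementations."""

from __future__ import annotations

import numpy as np


def grid_segment_distance(p1, p2, q1, q2, zooms: int = 6) -> float:
    """Minimum segment-segment distance by 512x512 parameter-grid search
    with nested 1D zooming.  Pure evaluation of the squared distance on
    grid points; no closest-point algebra.

    The squared distance is jointly convex in (s, t), so its partial
    minimum over t is convex in s, and in one dimension a convex
    function's best grid point lies within one grid step of the true
    minimiser — which makes zooming each axis separately provably
    convergent even when the 2D landscape is a narrow diagonal valley."""
    p1, p2, q1, q2 = (np.asarray(x, float) for x in (p1, p2, q1, q2))
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    uu, vv, uv = u @ u, v @ v, u @ v
    wu, wv, ww = w @ u, w @ v, w @ w

    def d2(s, t):
        return ww + s * s * uu + t * t * vv + 2 * s * wu - 2 * t * wv - 2 * s * t * uv

    def min_over_t(s_arr):
        """min_t d2(s, t) per s, by 1D grid zoom on t (vectorised over s)."""
        t = np.linspace(0.0, 1.0, 512)
        D = d2(s_arr[:, None], t[None, :])
        k = np.argmin(D, axis=1)
        h = 1.0 / 511.0
        t_lo = np.clip(t[k] - h, 0.0, 1.0)
        t_hi = np.clip(t[k] + h, 0.0, 1.0)
        best = D[np.arange(len(s_arr)), k]
        for _ in range(zooms):
            frac = np.linspace(0.0, 1.0, 33)
            tt = t_lo[:, None] + frac[None, :] * (t_hi - t_lo)[:, None]
            D = d2(s_arr[:, None], tt)
            k = np.argmin(D, axis=1)
            best = D[np.arange(len(s_arr)), k]
            tb = np.take_along_axis(tt, k[:, None], axis=1)[:, 0]
            ht = (t_hi - t_lo) / 32.0
            t_lo = np.maximum(0.0, tb - ht)
            t_hi = np.minimum(1.0, tb + ht)
        return best

    s = np.linspace(0.0, 1.0, 512)
    g = min_over_t(s)
    k = int(np.argmin(g))
    best = g[k]
    h = 1.0 / 511.0
    s_lo, s_hi = max(0.0, s[k] - h), min(1.0, s[k] + h)
    for _ in range(zooms):
        ss = np.linspace(s_lo, s_hi, 33)
        g = min_over_t(ss)
        k = int(np.argmin(g))
        best = g[k]
        hs = (s_hi - s_lo) / 32.0
        s_lo, s_hi = max(0.0, ss[k] - hs), min(1.0, ss[k] + hs)
    return float(np.sqrt(max(best, 0.0)))


def brute_filter_strong(records, totals, threshold):
    """Keep (i, j, c) records whose endpoints both have total >= threshold."""
    return [
        (i, j, c)
        for i, j, c in records
        if totals.get(i, 0) >= threshold and totals.get(j, 0) >= threshold
    ]


def brute_bin_totals(records):
    totals: dict = {}
    for i, j, c in records:
        totals[i] = totals.get(i, 0) + c
        totals[j] = totals.get(j, 0) + c
    return totals


def brute_degree_filter(nodes, edges, min_degree):
    """Induced subgraph on nodes of degree >= min_degree; returns (nodes, edges)."""
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    keep = {v for v in nodes if deg[v] >= min_degree}
    kept_edges = {tuple(sorted((a, b))) for a, b in edges if a in keep and b in keep}
    return keep, kept_edges


def brute_largest_component(nodes, edges):
    """Largest connected component by exhaustive flood fill; ties broken by
    the component containing the smallest node."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for v in sorted(nodes):
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    return max(comps, key=lambda c: (len(c), -min(c))) if comps else set()


def brute_territory_matrix(positions, labels):
    """Chromosome-level mean-distance matrix by explicit double loop."""
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    M = np.zeros((len(uniq), len(uniq)))
    for a, la in enumerate(uniq):
        for b, lb in enumerate(uniq):
            pa = positions[labels == la]
            pb = positions[labels == lb]
            ds = [
                float(np.linalg.norm(x - y))
                for ii, x in enumerate(pa)
                for jj, y in enumerate(pb)
                if not (a == b and ii == jj)
            ]
            M[a, b] = np.mean(ds) if ds else np.nan
    return M
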