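"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: nearest-neighbour
distances by an O(n^2) scan, synapse detection by explicit all-pairs
distance evaluation with a textbook point-to-segment formula, the
Mann-Whitney null by full enumeration of group assignments, and the
intensity-response fit by an exhaustive parameter grid.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def nnd_bruteforce(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, float)
    out = np.empty(len(pts))
    for i in range(len(pts)):
        best = math.inf
        for j in range(len(pts)):
            if i == j:
                continue
            d = float(np.sqrt(np.sum((pts[i] - pts[j]) ** 2)))
            if d < best:
                best = d
        out[i] = best
    return out


def point_segment_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + t * ab)))


def detect_synapses_bruteforce(scene, radius: float = 1.5):
    """All-pairs re-derivation of the triple-proximity rule.

    Returns a set of (ctbp2_id, mglur6_id, rbc_id) triples.
    """
    c = scene.ctbp2[["x_um", "y_um", "z_um"]].to_numpy()
    cids = list(scene.ctbp2["id"])
    m = scene.mglur6[["x_um", "y_um", "z_um"]].to_numpy()
    mids = list(scene.mglur6["id"])
    cells = sorted(scene.dendrites, key=lambda s: str(s.cell_id))
    out = set()
    for i in range(len(c)):
        dm = [math.dist(c[i], m[j]) for j in range(len(m))]
        jbest = int(np.argmin(dm))
        best_dd, best_cell = math.inf, None
        for skel in cells:
            for poly in skel.polylines:
                for a, b in zip(poly[:-1], poly[1:]):
                    d = point_segment_distance(c[i], a, b)
                    if d < best_dd:
                        best_dd, best_cell = d, str(skel.cell_id)
        if dm[jbest] <= radius and best_dd <= radius:
            out.add((cids[i], mids[jbest], best_cell))
    return out


def mannwhitney_exact_p(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_stat(group1, group2) -> float:
        return float(sum(1.0 if x > y else 0.5 if x == y else 0.0
                         for x in group1 for y in group2))

    u_obs = u_stat(a, b)
    idx = range(len(pooled))
    n_le = n_ge = total = 0
    for comb in itertools.combinations(idx, n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in idx if i not in comb]
        u = u_stat(g1, g2)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def naka_rushton_grid_sse(intensities, peaks, rmin, rmax,
                          i50_bounds, n_bounds, shape=(500, 500)) -> float:
    """Minimum SSE over an exhaustive log-spaced (I50, n) grid."""
    intens = np.asarray(intensities, float)
    peaks = np.asarray(peaks, float)
    i50s = np.geomspace(i50_bounds[0], i50_bounds[1], shape[0])
    ns = np.geomspace(n_bounds[0], n_bounds[1], shape[1])
    best = math.inf
    for n in ns:
        ipow = intens**n
        pred = rmin + (rmax - rmin) * ipow[None, :] / (ipow[None, :] + i50s[:, None] ** n)
        sse = np.sum((pred - peaks[None, :]) ** 2, axis=1)
        best = min(best, float(sse.min()))
    return best
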