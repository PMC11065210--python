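"""Independent brute-force oracles used to cross-check the package.

Every function here recomputes a quantity by a route deliberately
different from the implementation: Gauss-quadrature Fourier integrals
instead of the closed-form chain sums, unit-mass assignment instead of
the transportation LP, per-cell loops instead of vectorized Gower,
edge-by-edge sidedness instead of Qhull, exhaustive threshold search
instead of the histogram-based Otsu.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def fourier_coefficients(points: np.ndarray, n_harmonics: int, nodes: int = 12):
    """Fourier coefficients of the piecewise-linear closed curve through
    ``points``, by per-segment Gauss-Legendre quadrature over arc length.

    Returns ``(coeffs (H, 4), (A0, C0))`` in the same layout as
    ``morphometrics.efa``.
    """
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    keep = dt > 1e-12
    closed = np.vstack([closed[:-1][keep], closed[:1]])
    seg = np.diff(closed, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    t = np.concatenate(([0.0], np.cumsum(dt)))
    big_t = t[-1]

    xg, wg = np.polynomial.legendre.leggauss(nodes)
    t0, t1 = t[:-1][:, None], t[1:][:, None]
    tm = (t0 + t1) / 2 + (t1 - t0) / 2 * xg          # (N, nodes)
    w = ((t1 - t0) / 2 * wg).ravel()
    x = np.interp(tm.ravel(), t, closed[:, 0])
    y = np.interp(tm.ravel(), t, closed[:, 1])
    tt = tm.ravel()

    coeffs = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        om = 2.0 * np.pi * n / big_t
        cos, sin = np.cos(om * tt), np.sin(om * tt)
        coeffs[n - 1] = [
            (2.0 / big_t) * np.sum(w * x * cos),
            (2.0 / big_t) * np.sum(w * x * sin),
            (2.0 / big_t) * np.sum(w * y * cos),
            (2.0 / big_t) * np.sum(w * y * sin),
        ]
    a0 = np.sum(w * x) / big_t
    c0 = np.sum(w * y) / big_t
    return coeffs, (a0, c0)


def emd_by_assignment(centers1, props1, centers2, props2, scale: int):
    """EMD via unit-mass assignment: proportions must be multiples of
    1/scale; each side is expanded into ``scale`` unit masses and solved
    with the Hungarian algorithm."""
    c1 = np.repeat(np.arange(len(props1)), np.round(np.asarray(props1) * scale).astype(int))
    c2 = np.repeat(np.arange(len(props2)), np.round(np.asarray(props2) * scale).astype(int))
    assert len(c1) == len(c2) == scale
    cost = np.linalg.norm(
        np.asarray(centers1)[c1][:, None, :] - np.asarray(centers2)[c2][None, :, :],
        axis=-1,
    )
    r, c = linear_sum_assignment(cost)
    return cost[r, c].sum() / scale


def gower_cell(row_i, row_j, meta, ranks=None, tie_counts=None, ranges=None):
    """Gower distance between two rows by an explicit per-descriptor loop."""
    num, den = 0.0, 0.0
    for name, m in meta.items():
        vi, vj = row_i[name], row_j[name]
        if vi is None or vj is None or (
            isinstance(vi, float) and np.isnan(vi)
        ) or (isinstance(vj, float) and np.isnan(vj)):
            continue
        if m.dclass == "numeric":
            rng = ranges[name]
            if rng <= 0:
                continue
            num += abs(vi - vj) / rng
        elif m.dclass == "ordinal":
            r = ranks[name]
            tc = tie_counts[name]
            r_vals = list(r.values())
            r_max, r_min = max(r_vals), min(r_vals)
            t_max, t_min = tc[r_max], tc[r_min]
            denom = (r_max - r_min) - (t_max - 1) / 2 - (t_min - 1) / 2
            if denom <= 0:
                continue
            d = (abs(r[vi] - r[vj]) - (tc[r[vi]] - 1) / 2 - (tc[r[vj]] - 1) / 2)
            num += min(max(d / denom, 0.0), 1.0)
        else:
            num += float(vi != vj)
        den += 1.0
    return num / den


def hull_vertices_bruteforce(points: np.ndarray):
    """Convex-hull vertex indices by O(n^3) edge sidedness: (i, j) is a
    hull edge iff every other point lies on one side (collinear points
    on the edge segment allowed)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    vertices = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e = pts[j] - pts[i]
            rel = pts - pts[i]
            side = e[0] * rel[:, 1] - e[1] * rel[:, 0]
            others = np.delete(side, [i, j])
            if np.all(others > 1e-12) or np.all(others < -1e-12):
                vertices.add(i)
                vertices.add(j)
    return vertices


def otsu_threshold_exhaustive(values: np.ndarray, nbins: int = 256):
    """Otsu's threshold by explicit search over all candidate bin edges:
    maximize the between-class variance of the two-class split."""
    hist, edges = np.histogram(values, bins=nbins)
    mids = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best, best_t = -1.0, mids[0]
    for k in range(1, nbins):
        w0 = hist[:k].sum() / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * mids[:k]).sum() / hist[:k].sum()
        mu1 = (hist[k:] * mids[k:]).sum() / hist[k:].sum()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best:
            best, best_t = var, (mids[k - 1] + mids[k]) / 2
    return best_t


def random_smooth_outline(rng: np.random.Generator, n_points: int = 256):
    """A random simple smooth closed shape: radial perturbation of a
    circle by a few low-order sinusoids."""
    t = 2 * np.pi * np.arange(n_points) / n_points
    r = np.ones_like(t)
    for k in range(1, 5):
        r += rng.uniform(-0.12, 0.12) * np.cos(k * t + rng.uniform(0, 2 * np.pi))
    x = r * np.cos(t) + rng.uniform(-1, 1)
    y = r * np.sin(t) + rng.uniform(-1, 1)
    return np.column_stack([x, y])
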