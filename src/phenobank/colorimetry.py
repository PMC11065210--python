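"""Colorimetric descriptors: RGB histograms, earth mover's distance and
k-means color clusters.

Foreground pixels of an organ are summarized two ways:

* a fixed-grid RGB histogram, compared between accessions with the
  earth mover's distance (optimal transport with Euclidean RGB ground
  distance) — used for QC and dendrograms;
* k-means clustering (k = 10 by default) of the pooled pixels of an
  accession, whose centroids and cluster shares become the phenomic
  color descriptors ``R_1..R_k, G_1..G_k, B_1..B_k, prop_1..k`` with an
  organ suffix (``R_10S`` = red of cluster 10, seeds).

Clusters are ordered by decreasing luminance before naming so that
"cluster i" is comparable across accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .exceptions import GridMismatchError

__all__ = [
    "ColorHistogram",
    "ColorClusterSet",
    "histogram",
    "emd",
    "kmeans_colors",
    "cluster_descriptors",
    "ORGAN_SUFFIXES",
]

#: conventional one-letter organ suffixes used in descriptor names
ORGAN_SUFFIXES = {"seed": "S", "flower": "F", "pod": "P", "leaf": "L", "leaflet": "L"}


@dataclass(frozen=True)
class ColorHistogram:
    """Proportions of pixels over a regular RGB grid.

    ``centers`` is (B, 3) with B = bins_per_channel**3; empty bins are
    kept with proportion 0 so any two histograms on the same grid are
    directly comparable.
    """

    centers: np.ndarray
    proportions: np.ndarray
    bins_per_channel: int

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("proportions must be nonnegative and sum to 1")


@dataclass(frozen=True)
class ColorClusterSet:
    """k RGB centroids with their pixel shares, luminance-ordered."""

    centroids: np.ndarray     # (k, 3) in [0, 1]
    proportions: np.ndarray   # (k,), sums to 1

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("proportions must be nonnegative and sum to 1")

    @property
    def k(self) -> int:
        return len(self.proportions)


def histogram(pixels: np.ndarray, bins_per_channel: int = 4) -> ColorHistogram:
    """Multidimensional RGB histogram over a regular grid in [0, 1]^3."""
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if len(pixels) < 1:
        raise ValueError("need at least one pixel")
    b = int(bins_per_channel)
    if b < 1:
        raise ValueError("bins_per_channel must be >= 1")
    idx = np.clip((pixels * b).astype(int), 0, b - 1)
    flat = (idx[:, 0] * b + idx[:, 1]) * b + idx[:, 2]
    counts = np.bincount(flat, minlength=b**3).astype(float)
    mids = (np.arange(b) + 0.5) / b
    rr, gg, bb = np.meshgrid(mids, mids, mids, indexing="ij")
    centers = np.column_stack([rr.ravel(), gg.ravel(), bb.ravel()])
    return ColorHistogram(centers, counts / counts.sum(), b)


def emd(h1: ColorHistogram, h2: ColorHistogram) -> float:
    """Earth mover's distance between two histograms on the same grid.

    Solves the transportation linear program with Euclidean RGB ground
    distance between bin centers.  Symmetric; zero iff the proportion
    vectors coincide.
    """
    if h1.bins_per_channel != h2.bins_per_channel or not np.allclose(
        h1.centers, h2.centers
    ):
        raise GridMismatchError("histograms were built on different bin grids")
    i = h1.proportions > 0
    j = h2.proportions > 0
    a = h1.proportions[i] / h1.proportions[i].sum()
    b = h2.proportions[j] / h2.proportions[j].sum()
    cost = cdist(h1.centers[i], h2.centers[j])
    ni, nj = len(a), len(b)
    if ni == 1:
        return float(cost[0] @ b)
    if nj == 1:
        return float(a @ cost[:, 0])

    rows, cols, vals = [], [], []
    for r in range(ni):                       # supply constraints
        rows.extend([r] * nj)
        cols.extend(range(r * nj, (r + 1) * nj))
        vals.extend([1.0] * nj)
    for s in range(nj):                       # demand constraints
        rows.extend([ni + s] * ni)
        cols.extend(range(s, ni * nj, nj))
        vals.extend([1.0] * ni)
    a_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(ni + nj, ni * nj))
    res = linprog(
        cost.ravel(),
        A_eq=a_eq,
        b_eq=np.concatenate([a, b]),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:                        # pragma: no cover
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def kmeans_colors(
    pixels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
) -> ColorClusterSet:
    """Best-of-restarts k-means clustering of RGB pixels.

    Centroids are sorted by decreasing luminance before naming so that
    descriptor ``i`` refers to a comparable brightness rank across
    accessions.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if len(pixels) < k:
        raise ValueError(f"need at least k={k} pixels, got {len(pixels)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(pixels)
    centroids = km.cluster_centers_
    props = np.bincount(labels, minlength=k) / len(pixels)
    order = np.argsort(-centroids.mean(axis=1), kind="stable")
    return ColorClusterSet(np.clip(centroids[order], 0.0, 1.0), props[order])


def cluster_descriptors(clusters: ColorClusterSet, organ: str) -> pd.Series:
    """Flatten a cluster set into a named descriptor row.

    Produces ``4k`` values ``R_i<o>, G_i<o>, B_i<o>, prop_i<o>`` for
    i = 1..k where ``<o>`` is the one-letter organ suffix.
    """
    suffix = ORGAN_SUFFIXES.get(organ, organ[:1].upper())
    values, names = [], []
    for i in range(clusters.k):
        r, g, b = clusters.centroids[i]
        names += [f"R_{i+1}{suffix}", f"G_{i+1}{suffix}", f"B_{i+1}{suffix}",
                  f"prop_{i+1}{suffix}"]
        values += [r, g, b, clusters.proportions[i]]
    return pd.Series(values, index=names, dtype=float)


def pool_pixels(
    pixel_arrays: "list[np.ndarray]",
    max_pixels: int = 50_000,
    seed: int = 0,
) -> np.ndarray:
    """Pool foreground pixels of several images, subsampling to at most
    ``max_pixels`` with a seeded generator for tractable clustering."""
    pool = np.concatenate([np.asarray(p, float).reshape(-1, 3) for p in pixel_arrays])
    if len(pool) > max_pixels:
        rng = np.random.default_rng(seed)
        pool = pool[rng.choice(len(pool), max_pixels, replace=False)]
    return pool
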