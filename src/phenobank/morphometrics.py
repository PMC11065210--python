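"""Elliptical Fourier analysis (EFA) of closed organ outlines.

A closed outline (seed, leaflet, pod silhouette) is decomposed into
harmonic coefficients ``(a_n, b_n, c_n, d_n)`` following the classical
piecewise-linear chain formulation of Kuhl & Giardina: the outline is
traversed once, each segment contributes analytically to the Fourier
integrals of ``x(t)`` and ``y(t)`` over arc length ``t``.  Harmonic 1
describes the best-fitting ellipse; higher harmonics add detail.

Coefficient sets can be normalized for size, rotation and starting
point (reflection is deliberately kept, since organ chirality can be a
real trait), reconstructed back into outlines, and projected into a
PCA "morphospace" whose axes act as quantitative shape descriptors
(PC1S, PC2S, ... for seeds; PC1L... leaves; PC1P... pods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import DegenerateOutlineError

__all__ = [
    "EFDSet",
    "MorphoMeasures",
    "Morphospace",
    "efa",
    "normalize_efd",
    "reconstruct",
    "measures",
    "morphospace",
    "shoelace_area",
    "clean_outline",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EFDSet:
    """Elliptical Fourier coefficients of one closed outline.

    Parameters
    ----------
    coefficients
        Array of shape ``(n_harmonics, 4)`` holding ``(a_n, b_n, c_n, d_n)``
        per harmonic, ``n = 1..n_harmonics``.
    offset
        The DC terms ``(A0, C0)`` — the outline centroid along the arc-length
        parameterization.  Dropped (set to 0) by normalization.
    normalized
        True once size/rotation/starting-point have been standardized.
    """

    coefficients: np.ndarray
    offset: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.ndim != 2 or coeffs.shape[1] != 4 or coeffs.shape[0] < 1:
            raise ValueError("coefficients must have shape (n_harmonics, 4)")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def n_harmonics(self) -> int:
        return self.coefficients.shape[0]

    def flatten(self) -> np.ndarray:
        """Coefficients as a flat vector (a1,b1,c1,d1,a2,...)."""
        return self.coefficients.ravel().copy()


@dataclass(frozen=True)
class MorphoMeasures:
    """Classical size descriptors of one outline, in pixel units.

    ``length``/``width`` are extents along/across the first principal axis
    of the outline points, so they do not depend on image orientation.
    """

    length: float
    width: float
    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("expected length >= width > 0")
        if self.area <= 0:
            raise ValueError("area must be positive")
        # isoperimetric inequality, with a tiny slack for pixel quantization
        if self.perimeter**2 < 4.0 * np.pi * self.area * (1 - 1e-9):
            raise ValueError("perimeter^2 < 4*pi*area violates isoperimetry")


@dataclass
class Morphospace:
    """PCA of normalized EFD coefficient vectors.

    ``scores`` columns are named ``PC1..PCk`` plus an optional organ suffix
    (``PC1S`` for seeds, ``PC1L`` for leaves/leaflets, ``PC1P`` for pods).
    """

    scores: pd.DataFrame
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def transform(self, efds: "list[EFDSet]") -> pd.DataFrame:
        """Project additional normalized coefficient sets onto the axes."""
        x = np.array([e.flatten() for e in efds]) - self.mean_
        return pd.DataFrame(x @ self.loadings.T, columns=self.scores.columns)


# --------------------------------------------------------------------------
# outline helpers
# --------------------------------------------------------------------------

def clean_outline(outline: np.ndarray, min_points: int = 8) -> np.ndarray:
    """Return outline as an (N, 2) array without the closing duplicate
    point or zero-length segments.

    Raises :class:`DegenerateOutlineError` if fewer than ``min_points``
    distinct points remain.
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateOutlineError("outline must be an (N, 2) point list")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) >= 2:
        seg = np.linalg.norm(pts - np.roll(pts, 1, axis=0), axis=1)
        pts = pts[seg > 1e-12]
    if len(pts) < min_points:
        raise DegenerateOutlineError(
            f"outline has {len(pts)} distinct points; need >= {min_points}"
        )
    return pts


def shoelace_area(outline: np.ndarray, signed: bool = False) -> float:
    """Polygon area by the shoelace formula (positive = counterclockwise)."""
    pts = np.asarray(outline, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    a = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(a) if signed else float(abs(a))


# --------------------------------------------------------------------------
# EFA core
# --------------------------------------------------------------------------

def efa(outline: np.ndarray, n_harmonics: int = 20) -> EFDSet:
    """Elliptical Fourier decomposition of a closed outline.

    The outline is treated as a closed polygon parameterized by arc
    length; each segment's contribution to the Fourier integrals has a
    closed form, so no numerical quadrature is involved.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = clean_outline(outline)

    d = np.roll(pts, -1, axis=0) - pts            # segment vectors, wraps
    dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate(([0.0], np.cumsum(dt)))
    big_t = t[-1]
    phi = (2.0 * np.pi / big_t) * t

    n = np.arange(1, n_harmonics + 1)
    # (H, N) phase-difference tables
    cos_d = np.cos(np.outer(n, phi[1:])) - np.cos(np.outer(n, phi[:-1]))
    sin_d = np.sin(np.outer(n, phi[1:])) - np.sin(np.outer(n, phi[:-1]))
    const = big_t / (2.0 * (n * np.pi) ** 2)

    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (cos_d @ vx)
    b = const * (sin_d @ vx)
    c = const * (cos_d @ vy)
    dd = const * (sin_d @ vy)

    # DC components: centroid of the arc-length parameterized curve
    dt2 = np.diff(t**2)
    xi = np.cumsum(d[:, 0]) - d[:, 0] - vx * t[:-1]
    delta = np.cumsum(d[:, 1]) - d[:, 1] - vy * t[:-1]
    a0 = pts[0, 0] + np.sum(d[:, 0] / (2 * dt) * dt2 + xi * dt) / big_t
    c0 = pts[0, 1] + np.sum(d[:, 1] / (2 * dt) * dt2 + delta * dt) / big_t

    return EFDSet(np.column_stack([a, b, c, dd]), offset=(float(a0), float(c0)))


def reconstruct(efd: EFDSet, n_points: int = 256) -> np.ndarray:
    """Evaluate the finite-harmonic outline at uniform parameter steps.

    Returns an open (N, 2) polygon (the closing edge is implicit).
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    phi = 2.0 * np.pi * np.arange(n_points) / n_points
    n = np.arange(1, efd.n_harmonics + 1)
    cos = np.cos(np.outer(phi, n))
    sin = np.sin(np.outer(phi, n))
    a, b, c, d = efd.coefficients.T
    x = efd.offset[0] + cos @ a + sin @ b
    y = efd.offset[1] + cos @ c + sin @ d
    return np.column_stack([x, y])


def _rotate_harmonics(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point: harmonic n gets a parameter rotation n*theta."""
    h = coeffs.shape[0]
    out = np.empty_like(coeffs)
    for i in range(h):
        nth = (i + 1) * theta
        rot = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        out[i] = (coeffs[i].reshape(2, 2) @ rot).ravel()
    return out


def _orient(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the coordinate frame by -psi (applied to every harmonic)."""
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    return np.einsum("ij,hjk->hik", rot, coeffs.reshape(-1, 2, 2)).reshape(-1, 4)


def normalize_efd(efd: EFDSet) -> EFDSet:
    """Standardize size, rotation and starting point of a coefficient set.

    The first-harmonic ellipse defines the standardization: the starting
    point is moved onto its semi-major axis, the frame is rotated so the
    semi-major axis lies along +x, and all coefficients are divided by
    the semi-major magnitude.  Reflection is *not* removed, so mirror
    shapes stay distinct.  The residual two-fold ambiguity (which end of
    the major axis) is resolved deterministically by requiring the
    largest even-harmonic coefficient to be positive.
    """
    if efd.normalized:
        return efd
    a1, b1, c1, d1 = efd.coefficients[0]
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )

    candidates = []
    for th in (theta, theta + np.pi):
        star = _rotate_harmonics(efd.coefficients, th)
        sa, _, sc, _ = star[0]
        scale = np.hypot(sa, sc)
        if scale < 1e-12:
            raise DegenerateOutlineError("degenerate first harmonic")
        psi = np.arctan2(sc, sa)
        candidates.append(_orient(star, psi) / scale)

    chosen = candidates[0]
    if efd.n_harmonics >= 2:
        even = chosen[1::2].ravel()           # harmonics 2, 4, ...
        pick = np.argmax(np.abs(even))
        if even[pick] < 0:
            chosen = candidates[1]
    return EFDSet(chosen, offset=(0.0, 0.0), normalized=True)


# --------------------------------------------------------------------------
# classical measures
# --------------------------------------------------------------------------

def measures(outline: np.ndarray) -> MorphoMeasures:
    """Length, width, area and perimeter of one outline.

    Area is the shoelace area, perimeter the closed segment sum;
    length/width are the point-cloud extents along/across the first
    principal axis, with length >= width by construction.
    """
    pts = clean_outline(outline)
    area = shoelace_area(pts)
    if area <= 0:
        raise DegenerateOutlineError("outline has zero area")
    seg = np.roll(pts, -1, axis=0) - pts
    perimeter = float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    _, vecs = np.linalg.eigh(cov)
    major, minor = vecs[:, 1], vecs[:, 0]     # eigh sorts ascending
    ext = lambda ax: float(np.ptp(centered @ ax))
    length, width = sorted((ext(major), ext(minor)), reverse=True)
    return MorphoMeasures(length=length, width=width, area=area, perimeter=perimeter)


# --------------------------------------------------------------------------
# morphospace (PCA of coefficient vectors)
# --------------------------------------------------------------------------

def morphospace(
    efds: "list[EFDSet]",
    k: int = 10,
    organ_suffix: str = "",
    index=None,
) -> Morphospace:
    """PCA morphospace of normalized coefficient sets.

    Keeps at most ``k`` components (fewer if the data have lower rank).
    Axis signs are fixed deterministically: the largest-magnitude loading
    of every component is made positive, so descriptor tables are
    reproducible across runs.
    """
    if len(efds) < 3:
        raise ValueError("need at least 3 outlines for a morphospace")
    n_harm = {e.n_harmonics for e in efds}
    if len(n_harm) != 1:
        raise ValueError("all EFDSets must share n_harmonics")
    if not all(e.normalized for e in efds):
        raise ValueError("all EFDSets must be normalized")

    x = np.array([e.flatten() for e in efds])
    n_max = min(len(efds) - 1, x.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    scores = pca.fit_transform(x)

    keep = min(k, int(np.sum(pca.explained_variance_ > 1e-12)))
    keep = max(keep, 1)
    scores = scores[:, :keep]
    loadings = pca.components_[:keep]

    # deterministic sign convention
    for j in range(keep):
        i = np.argmax(np.abs(loadings[j]))
        if loadings[j, i] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]

    names = [f"PC{j + 1}{organ_suffix}" for j in range(keep)]
    return Morphospace(
        scores=pd.DataFrame(scores, columns=names, index=index),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_[:keep].copy(),
        mean_=pca.mean_,
    )
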