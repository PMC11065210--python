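"""Functional diversity of accessions grouped into species.

Species are treated as functional entities (FEs) and their accessions
as equally weighted members.  Accession-level descriptor tables (mixed
numeric / ordinal / nominal) are turned into a Gower distance matrix,
embedded by principal coordinates analysis (PCoA), and summarized as:

* **FSpe** (functional specialization): the mean distance of an FE's
  accessions to the pooled centroid of all accessions, divided by the
  largest per-accession distance — so FSpe is in [0, 1] and the FE
  holding the single farthest accession scores exactly 1.00;
* **FOri** (functional originality): how isolated an FE's accessions
  are from accessions of *other* FEs.  The default ``nearest_entity``
  variant averages each accession's distance to its nearest
  different-FE accession, again max-normalized, and is defined for
  singleton FEs; the ``intra_mean`` variant (mean pairwise distance
  within the FE) is also provided but is undefined for singletons;
* **FIde** (functional identity): the FE centroid coordinates per axis;
* the convex hull of the first two axes, whose area measures occupied
  trait space and whose vertex accessions are natural candidates for a
  core (functional) collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .descriptors import DescriptorMatrix

__all__ = [
    "gower",
    "pcoa",
    "hull",
    "fspe",
    "fori",
    "fide",
    "fd_report",
    "FunctionalSpace",
    "FunctionalDiversityModel",
    "FunctionalDiversityResults",
]


# --------------------------------------------------------------------------
# Gower distance on mixed descriptor types
# --------------------------------------------------------------------------

def _podani_ordinal(col: pd.Series, levels) -> np.ndarray:
    """Podani's tie-corrected rank dissimilarity for one ordinal column."""
    rank_of = {lvl: i + 1.0 for i, lvl in enumerate(levels)}
    raw = col.map(rank_of).to_numpy(dtype=float)
    # average ranks over the observations, respecting ties
    order = pd.Series(raw).rank(method="average").to_numpy()
    ties = pd.Series(order).map(pd.Series(order).value_counts()).to_numpy()

    r_i = order[:, None]
    r_j = order[None, :]
    t_i = ties[:, None]
    t_j = ties[None, :]
    r_max, r_min = order.max(), order.min()
    t_max = ties[np.argmax(order)]
    t_min = ties[np.argmin(order)]
    denom = (r_max - r_min) - (t_max - 1) / 2.0 - (t_min - 1) / 2.0
    if denom <= 0:
        return None                      # effectively constant -> drop
    num = np.abs(r_i - r_j) - (t_i - 1) / 2.0 - (t_j - 1) / 2.0
    d = np.clip(num / denom, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def gower(matrix: DescriptorMatrix) -> pd.DataFrame:
    """Accession x accession Gower distance in [0, 1].

    Per descriptor: numeric -> |difference| / range; ordinal -> Podani
    tie-corrected rank dissimilarity; nominal -> 0/1 mismatch; the
    distance is the average over descriptors non-missing in both rows.
    Zero-range (constant) descriptors are dropped with a warning.
    """
    n = matrix.n_rows
    if n < 2:
        raise ValueError("need at least 2 accessions")
    total = np.zeros((n, n))
    weight = np.zeros((n, n))
    for name, m in matrix.meta.items():
        col = matrix.data[name]
        present = ~col.isna().to_numpy()
        both = np.outer(present, present)
        if m.dclass == "numeric":
            x = col.to_numpy(dtype=float)
            rng = np.nanmax(x) - np.nanmin(x)
            if not rng > 0:
                warnings.warn(f"dropping zero-range descriptor {name!r}")
                continue
            d = np.abs(x[:, None] - x[None, :]) / rng
        elif m.dclass == "ordinal":
            d = _podani_ordinal(col, m.levels)
            if d is None:
                warnings.warn(f"dropping constant ordinal descriptor {name!r}")
                continue
        else:
            v = col.to_numpy()
            d = (v[:, None] != v[None, :]).astype(float)
        d = np.where(both, np.nan_to_num(d), 0.0)
        total += d
        weight += both
    if not weight.any():
        raise ValueError("no usable descriptors")
    with np.errstate(invalid="ignore"):
        dist = np.where(weight > 0, total / weight, np.nan)
    np.fill_diagonal(dist, 0.0)
    index = matrix.data.index
    return pd.DataFrame(dist, index=index, columns=index)


# --------------------------------------------------------------------------
# PCoA (classical scaling)
# --------------------------------------------------------------------------

def pcoa(dist: pd.DataFrame, n_axes: int = 4) -> tuple:
    """Principal coordinates of a distance matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and keeps axes with
    eigenvalue > 1e-10 up to ``n_axes`` (negative eigenvalues — possible
    for non-Euclidean distances such as Gower — are dropped; no
    correction is applied).  Axis signs are fixed by making the
    largest-magnitude coordinate of each axis positive.

    Returns ``(coordinates, eigenvalues)``; eigenvalues are the full
    nonincreasing spectrum, coordinates only the retained axes.
    """
    if n_axes < 2:
        raise ValueError("n_axes must be >= 2")
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) > 1e-9) or np.any(d < -1e-12):
        raise ValueError("distances must be nonnegative with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    keep = np.where(vals > 1e-10)[0][:n_axes]
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    for jx in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, jx]))
        if coords[i, jx] < 0:
            coords[:, jx] = -coords[:, jx]
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(
        coords, index=index, columns=[f"PCo{k + 1}" for k in range(coords.shape[1])]
    )
    return frame, vals


# --------------------------------------------------------------------------
# convex hull of the trait space
# --------------------------------------------------------------------------

def hull(coords: pd.DataFrame, axes: tuple = (0, 1)) -> tuple:
    """2-D convex hull on a pair of ordination axes.

    Returns ``(area, vertex_ids)`` with vertices in hull order.  An
    all-collinear configuration degenerates to area 0 with the two
    extreme points as vertices (and a warning).
    """
    avail = [a for a in axes if a < coords.shape[1]]
    pts = np.asarray(coords.iloc[:, avail], dtype=float)
    if pts.shape[1] < 2:                     # degenerate 1-axis space
        pts = np.column_stack([pts, np.zeros(len(pts))])
    ids = list(coords.index)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    try:
        h = ConvexHull(pts)
    except QhullError:
        warnings.warn("points are collinear; hull degenerates to a segment")
        proj = pts @ (pts.std(axis=0) + 1e-12)
        lo, hi = int(np.argmin(proj)), int(np.argmax(proj))
        return 0.0, [ids[lo], ids[hi]]
    return float(h.volume), [ids[v] for v in h.vertices]


# --------------------------------------------------------------------------
# indices
# --------------------------------------------------------------------------

def _fe_groups(fe_map: pd.Series) -> dict:
    groups: dict = {}
    for acc, fe in fe_map.items():
        groups.setdefault(fe, []).append(acc)
    return groups


def fspe(coords: pd.DataFrame, fe_map: pd.Series) -> pd.Series:
    """Functional specialization per FE: mean accession distance to the
    pooled centroid, divided by the maximum per-accession distance."""
    if len(coords) < 2:
        raise ValueError("FSpe undefined for a single accession")
    x = coords.to_numpy(dtype=float)
    centroid = x.mean(axis=0)
    dist = pd.Series(np.linalg.norm(x - centroid, axis=1), index=coords.index)
    dmax = dist.max()
    if dmax <= 0:
        return pd.Series(
            0.0, index=sorted(set(fe_map)), name="FSpe", dtype=float
        )
    out = {
        fe: dist.loc[accs].mean() / dmax for fe, accs in _fe_groups(fe_map).items()
    }
    return pd.Series(out, name="FSpe").sort_index()


def nearest_neighbor_distances(coords: pd.DataFrame) -> pd.Series:
    """Distance of each accession to its nearest other accession (any
    FE) — a redundancy diagnostic: near-duplicates score near 0."""
    x = coords.to_numpy(dtype=float)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return pd.Series(d.min(axis=1), index=coords.index, name="nn_distance")


def fori(
    coords: pd.DataFrame,
    fe_map: pd.Series,
    variant: str = "nearest_entity",
) -> pd.Series:
    """Functional originality per FE.

    ``nearest_entity`` (default): each accession's distance to the
    nearest accession of a *different* FE, averaged within the FE and
    divided by the maximum per-accession value; well defined for
    singleton FEs.  ``intra_mean``: mean pairwise within-FE distance
    normalized by the maximum FE value; singletons get NaN.
    """
    groups = _fe_groups(fe_map)
    if len(groups) < 2:
        raise ValueError("FOri needs at least 2 functional entities")
    x = coords.to_numpy(dtype=float)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    fe_arr = fe_map.loc[coords.index].to_numpy()

    if variant == "nearest_entity":
        other = fe_arr[:, None] != fe_arr[None, :]
        masked = np.where(other, d, np.inf)
        nearest = pd.Series(masked.min(axis=1), index=coords.index)
        nmax = nearest.max()
        if nmax <= 0:
            return pd.Series(0.0, index=sorted(groups), name="FOri")
        out = {fe: nearest.loc[accs].mean() / nmax for fe, accs in groups.items()}
        return pd.Series(out, name="FOri").sort_index()

    if variant == "intra_mean":
        out = {}
        pos = {a: i for i, a in enumerate(coords.index)}
        for fe, accs in groups.items():
            if len(accs) < 2:
                out[fe] = np.nan
                continue
            idx = [pos[a] for a in accs]
            sub = d[np.ix_(idx, idx)]
            out[fe] = sub[np.triu_indices(len(idx), k=1)].mean()
        series = pd.Series(out, name="FOri").sort_index()
        vmax = series.max(skipna=True)
        return series / vmax if vmax and vmax > 0 else series

    raise ValueError(f"unknown FOri variant {variant!r}")


def fide(coords: pd.DataFrame, fe_map: pd.Series) -> pd.DataFrame:
    """Functional identity: per-axis unweighted mean coordinates of each
    FE's accessions (every accession has weight 1)."""
    groups = _fe_groups(fe_map)
    rows = {fe: coords.loc[accs].mean(axis=0) for fe, accs in groups.items()}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------

@dataclass
class FunctionalSpace:
    """PCoA embedding with its convex hull on the first two axes."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    hull_area: float
    hull_vertices: list

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be nonincreasing")


@dataclass
class FunctionalDiversityResults:
    """Per-FE indices plus the trait space they were computed in."""

    space: FunctionalSpace
    distances: pd.DataFrame
    fspe: pd.Series
    fori: pd.Series
    fide: pd.DataFrame
    nn_distance: pd.Series
    fe_map: pd.Series
    fori_variant: str

    @property
    def index_table(self) -> pd.DataFrame:
        sizes = self.fe_map.value_counts().sort_index()
        table = pd.DataFrame(
            {"n": sizes, "FSpe": self.fspe, "FOri": self.fori}
        )
        return table.join(self.fide.add_prefix("FIde_"))

    def summary(self) -> str:
        lines = [
            "Functional diversity of accessions by species (FE)",
            "==================================================",
            f"accessions: {len(self.fe_map)}   FEs: {self.fe_map.nunique()}   "
            f"axes: {self.space.coordinates.shape[1]}",
            f"hull area (axes 1-2): {self.space.hull_area:.4f}   "
            f"vertex accessions: {len(self.space.hull_vertices)}",
            "vertices: " + ", ".join(map(str, self.space.hull_vertices)),
            "",
            self.index_table.round(3).to_string(),
        ]
        return "\n".join(lines)

    def plot_space(self, ax=None, annotate: bool = True):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        xy = self.space.coordinates.iloc[:, :2].copy()
        if xy.shape[1] < 2:
            xy["PCo2"] = 0.0
        for fe in sorted(self.fe_map.unique()):
            pts = xy[self.fe_map.loc[xy.index] == fe]
            ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=fe, s=25)
        verts = xy.loc[self.space.hull_vertices]
        closed = pd.concat([verts, verts.iloc[:1]])
        ax.plot(closed.iloc[:, 0], closed.iloc[:, 1], "k--", lw=0.8)
        if annotate:
            for acc in self.space.hull_vertices:
                ax.annotate(str(acc), xy.loc[acc], fontsize=6)
        ax.set_xlabel(xy.columns[0])
        ax.set_ylabel(xy.columns[1])
        ax.legend(fontsize=7)
        return ax


class FunctionalDiversityModel:
    """Functional-diversity analysis of an accession-level descriptor
    matrix whose rows are grouped into species (functional entities).

    Parameters
    ----------
    matrix
        Accession-level :class:`DescriptorMatrix` (typically restricted
        to the RF-selected descriptors).
    n_axes
        Cap on retained positive-eigenvalue PCoA axes (default 4); the
        hull always uses axes 1-2.
    fori_variant
        ``"nearest_entity"`` (default) or ``"intra_mean"``.
    """

    def __init__(
        self,
        matrix: DescriptorMatrix,
        n_axes: int = 4,
        fori_variant: str = "nearest_entity",
    ):
        self.matrix = matrix
        self.n_axes = n_axes
        self.fori_variant = fori_variant

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, species_map: dict, meta: dict | None = None, **kw
    ) -> "FunctionalDiversityModel":
        """Build from a plain accession-indexed table and a species map."""
        from .descriptors import infer_meta

        meta = meta or infer_meta(data, dtype="classical")
        matrix = DescriptorMatrix(
            data=data,
            meta={n: meta[n] for n in data.columns},
            accession=pd.Series(data.index, index=data.index),
            species=pd.Series([species_map[a] for a in data.index], index=data.index),
        )
        return cls(matrix, **kw)

    def fit(self) -> FunctionalDiversityResults:
        dist = gower(self.matrix)
        coords, eigenvalues = pcoa(dist, n_axes=self.n_axes)
        area, vertices = hull(coords, axes=(0, 1))
        fe_map = pd.Series(
            self.matrix.species.values, index=self.matrix.data.index
        )
        return FunctionalDiversityResults(
            space=FunctionalSpace(coords, eigenvalues, area, vertices),
            distances=dist,
            fspe=fspe(coords, fe_map),
            fori=fori(coords, fe_map, self.fori_variant),
            fide=fide(coords, fe_map),
            nn_distance=nearest_neighbor_distances(coords),
            fe_map=fe_map,
            fori_variant=self.fori_variant,
        )


def fd_report(matrices: dict, n_axes: int = 4, fori_variant: str = "nearest_entity"):
    """Functional-diversity comparison across descriptor types.

    ``matrices`` maps type labels (``phenomic``/``classical``/
    ``combined``, abbreviated Phe/Cla/Com in the output) to
    accession-level :class:`DescriptorMatrix` objects.  Accession sets
    are intersected (with a warning when they differ).  Returns
    ``(index_table, results)``: a Table-1-shaped FE x {FSpe, FOri} x
    type table with FIde axes appended, and the per-type results.
    """
    abbrev = {"phenomic": "Phe", "classical": "Cla", "combined": "Com"}
    common = None
    for m in matrices.values():
        accs = set(m.data.index)
        common = accs if common is None else common & accs
    if any(set(m.data.index) != common for m in matrices.values()):
        warnings.warn("accession sets differ across descriptor types; intersecting")
    common = sorted(common)

    results = {}
    for dtype, matrix in matrices.items():
        sub = matrix.select(matrix.descriptor_names)
        sub.data = sub.data.loc[common]
        sub.accession = sub.accession.loc[common]
        sub.species = sub.species.loc[common]
        results[dtype] = FunctionalDiversityModel(
            sub, n_axes=n_axes, fori_variant=fori_variant
        ).fit()

    tag_of = {d: abbrev.get(d, d[:3].title()) for d in results}
    pieces = {}
    for which in ("FSpe", "FOri"):
        for dtype, res in results.items():
            pieces[(which, tag_of[dtype])] = getattr(res, which.lower())
    table = pd.DataFrame(pieces)
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    sizes = next(iter(results.values())).fe_map.value_counts().sort_index()
    table.insert(0, ("n", ""), sizes)
    for dtype, res in results.items():
        tag = abbrev.get(dtype, dtype[:3].title())
        for axis in res.fide.columns[:2]:
            table[("FIde_" + tag, axis)] = res.fide[axis]
    return table, results
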