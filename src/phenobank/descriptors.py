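"""Descriptor matrices: phenomic, classical and combined.

A :class:`DescriptorMatrix` couples a mixed-type table (rows =
observation units, columns = descriptors) with per-descriptor metadata:
measurement class (numeric / ordinal / nominal), provenance (phenomic =
image-derived, classical = scored by hand) and, for phenomic columns,
the organ.  Classification runs on plant-level replicate rows;
functional diversity runs on accession-level aggregates (numeric mean,
categorical mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["DescriptorMeta", "DescriptorMatrix", "assemble", "encode_for_rf"]

log = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.10


@dataclass(frozen=True)
class DescriptorMeta:
    """Metadata of one descriptor column."""

    name: str
    dclass: str                 # numeric | ordinal | nominal
    dtype: str                  # phenomic | classical
    organ: str | None = None
    levels: tuple = ()          # declared order, ordinal only

    def __post_init__(self):
        if self.dclass not in ("numeric", "ordinal", "nominal"):
            raise ValueError(f"unknown descriptor class {self.dclass!r}")
        if self.dtype not in ("phenomic", "classical"):
            raise ValueError(f"unknown descriptor type {self.dtype!r}")
        if self.dclass == "ordinal" and not self.levels:
            raise ValueError(f"ordinal descriptor {self.name!r} needs levels")


@dataclass
class DescriptorMatrix:
    """Observation units x descriptors with metadata and row labels."""

    data: pd.DataFrame
    meta: dict                    # name -> DescriptorMeta
    accession: pd.Series          # per row
    species: pd.Series            # per row

    def __post_init__(self):
        if list(self.data.columns) != list(self.meta):
            missing = set(self.data.columns) ^ set(self.meta)
            if missing:
                raise ValueError(f"metadata/columns mismatch: {sorted(missing)}")
            self.data = self.data[list(self.meta)]
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValueError("descriptor names must be unique")
        for name, m in self.meta.items():
            col = self.data[name]
            if col.isna().all():
                raise ValueError(f"descriptor {name!r} is fully missing")
            if m.dclass == "numeric" and not np.isfinite(
                col.dropna().astype(float)
            ).all():
                raise ValueError(f"numeric descriptor {name!r} has non-finite values")
            if m.dclass == "ordinal":
                bad = set(col.dropna()) - set(m.levels)
                if bad:
                    raise ValueError(f"undeclared ordinal level(s) {bad} in {name!r}")

    # -- convenience ------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def descriptor_names(self) -> list:
        return list(self.data.columns)

    def of_type(self, dtype: str) -> "DescriptorMatrix":
        names = [n for n, m in self.meta.items() if m.dtype == dtype]
        return self.select(names)

    def select(self, names) -> "DescriptorMatrix":
        names = [n for n in names if n in self.meta]
        return DescriptorMatrix(
            data=self.data[names].copy(),
            meta={n: self.meta[n] for n in names},
            accession=self.accession.copy(),
            species=self.species.copy(),
        )

    def to_accession_level(self) -> "DescriptorMatrix":
        """Aggregate plant rows to one row per accession: numeric mean,
        categorical mode (ties broken lexicographically)."""
        def agg(col: pd.Series, m: DescriptorMeta):
            if m.dclass == "numeric":
                return col.astype(float).mean()
            counts = col.value_counts()
            top = counts[counts == counts.max()]
            return sorted(top.index)[0]

        grouped = self.data.groupby(self.accession.values)
        rows = {
            acc: {n: agg(g[n], self.meta[n]) for n in self.data.columns}
            for acc, g in grouped
        }
        data = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        data = data[list(self.data.columns)]
        sp = (
            pd.Series(self.species.values, index=self.accession.values)
            .groupby(level=0)
            .first()
            .loc[data.index]
        )
        return DescriptorMatrix(
            data=data,
            meta=dict(self.meta),
            accession=pd.Series(data.index, index=data.index),
            species=sp,
        )


def assemble(
    phenomic: pd.DataFrame | None,
    classical: pd.DataFrame | None,
    species_map: dict,
    mode: str = "combined",
    phenomic_meta: dict | None = None,
    classical_meta: dict | None = None,
) -> DescriptorMatrix:
    """Build one of the three analysis matrices.

    ``phenomic`` rows are plant-level with an ``accession`` column;
    ``classical`` rows are accession-level (index = accession id).
    ``combined`` joins them on accession (classical values broadcast to
    plant rows); rows lacking either part are dropped with a logged
    count.  An accession absent from ``species_map`` is an error.
    """
    if mode not in ("phenomic", "classical", "combined"):
        raise ValueError(f"unknown mode {mode!r}")

    def check_species(accs):
        unknown = sorted(set(accs) - set(species_map))
        if unknown:
            raise KeyError(f"accession(s) not in species map: {unknown}")

    if mode == "classical" and phenomic is None:
        # accession-level rows (functional-diversity unit of analysis)
        if classical is None:
            raise ValueError("classical table required")
        table = classical.drop(columns=["species"], errors="ignore").sort_index()
        check_species(table.index)
        meta = classical_meta or infer_meta(table, dtype="classical")
        return DescriptorMatrix(
            data=table,
            meta={n: meta[n] for n in table.columns},
            accession=pd.Series(table.index, index=table.index),
            species=pd.Series([species_map[a] for a in table.index], index=table.index),
        )

    if phenomic is None:
        raise ValueError("phenomic table required")
    phen = phenomic.sort_index(kind="stable").sort_values("accession", kind="stable")
    accs = phen["accession"]
    check_species(accs)
    values = phen.drop(columns=["accession"])
    meta = dict(phenomic_meta or infer_meta(values, dtype="phenomic"))
    if mode == "classical":
        # plant-level replicate rows (classification unit of analysis)
        # with classical values broadcast and no phenomic columns
        values = values.iloc[:, :0]
        meta = {}

    if mode in ("combined", "classical"):
        if classical is None:
            raise ValueError("classical table required for combined mode")
        ctab = classical.drop(columns=["species"], errors="ignore")
        check_species(ctab.index)
        cmeta = classical_meta or infer_meta(ctab, dtype="classical")
        clash = set(values.columns) & set(ctab.columns)
        if clash:
            raise ValueError(f"descriptor name collision: {sorted(clash)}")
        keep = accs.isin(ctab.index)
        dropped = int((~keep).sum())
        extra = sorted(set(ctab.index) - set(accs))
        if dropped or extra:
            log.info(
                "combined assembly dropped %d plant row(s) without classical "
                "data and %d classical-only accession(s) %s",
                dropped, len(extra), extra,
            )
        values, accs = values[keep.values], accs[keep.values]
        broadcast = ctab.loc[accs].set_index(values.index)
        values = pd.concat([values, broadcast], axis=1)
        meta.update({n: cmeta[n] for n in ctab.columns})

    return DescriptorMatrix(
        data=values,
        meta={n: meta[n] for n in values.columns},
        accession=accs,
        species=pd.Series([species_map[a] for a in accs], index=accs.index),
    )


def infer_meta(
    table: pd.DataFrame,
    dtype: str,
    ordinal_levels: dict | None = None,
    organ_of: dict | None = None,
) -> dict:
    """Metadata from column dtypes: float/int columns are numeric, object
    columns nominal unless their ordered levels are declared."""
    ordinal_levels = ordinal_levels or {}
    organ_of = organ_of or {}
    meta = {}
    for name in table.columns:
        if name in ordinal_levels:
            meta[name] = DescriptorMeta(
                name, "ordinal", dtype, organ_of.get(name),
                tuple(ordinal_levels[name]),
            )
        elif pd.api.types.is_numeric_dtype(table[name]):
            meta[name] = DescriptorMeta(name, "numeric", dtype, organ_of.get(name))
        else:
            meta[name] = DescriptorMeta(name, "nominal", dtype, organ_of.get(name))
    return meta


def encode_for_rf(matrix: DescriptorMatrix):
    """Numeric encoding for tree ensembles.

    ordinal -> declared rank integers; nominal -> one-hot child columns;
    numeric -> passthrough.  Missing values (at most 10% per column) are
    imputed with the column mean (numeric) or mode (categorical).
    Returns ``(encoded, reverse_map)`` where ``reverse_map`` sends every
    encoded column back to its parent descriptor, so per-tree minimal
    depths can be collapsed to parent level.
    """
    encoded = {}
    reverse_map = {}
    for name, m in matrix.meta.items():
        col = matrix.data[name]
        frac_missing = col.isna().mean()
        if frac_missing > MAX_MISSING_FRACTION:
            raise ValueError(
                f"descriptor {name!r} is {frac_missing:.0%} missing (> 10%)"
            )
        if m.dclass == "numeric":
            col = col.astype(float)
            if frac_missing:
                col = col.fillna(col.mean())
            encoded[name] = col.to_numpy()
            reverse_map[name] = name
        else:
            if frac_missing:
                col = col.fillna(col.mode().sort_values().iloc[0])
            if m.dclass == "ordinal":
                rank = {lvl: i for i, lvl in enumerate(m.levels)}
                bad = set(col) - set(rank)
                if bad:
                    raise ValueError(f"undeclared ordinal level(s) {bad} in {name!r}")
                encoded[name] = col.map(rank).to_numpy(dtype=float)
                reverse_map[name] = name
            else:
                for lvl in sorted(set(col)):
                    child = f"{name}={lvl}"
                    encoded[child] = (col == lvl).to_numpy(dtype=float)
                    reverse_map[child] = name
    frame = pd.DataFrame(encoded, index=matrix.data.index)
    return frame, reverse_map
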