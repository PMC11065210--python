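"""End-to-end pipeline: simulate -> extract -> select -> funcdiv.

Ties the stages together on in-memory objects; the command-line
interface in :mod:`phenobank.cli` adds file layout, manifests and
logging on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import colorimetry, imageprep, morphometrics
from .colorimetry import ORGAN_SUFFIXES
from .descriptors import DescriptorMatrix, DescriptorMeta, assemble, infer_meta
from .funcdiv import fd_report
from .rfselect import DescriptorSelector, RFConfig
from .synthdata import SimulationConfig, SyntheticDataset, generate_dataset, stream_seed

log = logging.getLogger(__name__)

__all__ = ["ExtractionResult", "extract_dataset", "load_dataset_images",
           "run_selection", "run_functional_diversity", "run_all"]


@dataclass
class ExtractionResult:
    """Phenomic descriptors extracted from one image campaign."""

    plant_table: pd.DataFrame          # plant rows; 'accession' + numeric cols
    meta: dict                         # descriptor name -> DescriptorMeta
    color_table: pd.DataFrame          # accession-level color descriptors
    morphospaces: dict                 # organ -> Morphospace
    emd_matrices: dict = field(default_factory=dict)   # organ -> DataFrame


def _organ_suffix(organ: str) -> str:
    return ORGAN_SUFFIXES.get(organ, organ[:1].upper())


def extract_dataset(
    images: dict,
    n_harmonics: int = 20,
    k_components: int = 10,
    bins_per_channel: int = 4,
    k_colors: int = 10,
    color_restarts: int = 10,
    max_pixels: int = 50_000,
    seed: int = 0,
    compute_emd: bool = False,
    color_organs: tuple | None = None,
) -> ExtractionResult:
    """Run segmentation, morphometrics and colorimetry over a campaign.

    ``images`` maps ``(accession, organ, plant)`` to RGB arrays in
    [0, 1].  Masks are re-derived by Otsu segmentation rather than
    trusted from disk, so the extraction path is exercised end to end.

    Shape: per organ, every plant outline is decomposed (EFA at
    ``n_harmonics``), normalized, and projected into a k<=10 component
    morphospace; plant rows also carry length/width/area/perimeter.
    Color: per accession and organ, foreground pixels of all plants are
    pooled (subsampled to ``max_pixels``), clustered into ``k_colors``
    luminance-ordered clusters, and flattened into R/G/B/prop
    descriptors (accession-level, broadcast to plant rows).
    """
    organs = sorted({o for (_, o, _) in images})
    color_organs = organs if color_organs is None else [
        o for o in organs if o in color_organs
    ]
    plant_ids = sorted({(a, p) for (a, o, p) in images})
    uid = {ap: f"{ap[0]}.p{ap[1]:02d}" for ap in plant_ids}

    rows = {uid[ap]: {"accession": ap[0]} for ap in plant_ids}
    meta: dict = {}
    morphospaces = {}
    color_rows: dict = {}
    emd_matrices = {}

    for organ in organs:
        suf = _organ_suffix(organ)
        keys = sorted((a, p) for (a, o, p) in images if o == organ)
        efds, labels = [], []
        fg_by_acc: dict = {}
        for a, p in keys:
            img = images[(a, organ, p)]
            mask = imageprep.binarize(img)
            outline = imageprep.trace_outline(mask)
            mm = morphometrics.measures(outline)
            r = rows[uid[(a, p)]]
            r[f"length{suf}"] = mm.length
            r[f"width{suf}"] = mm.width
            r[f"area{suf}"] = mm.area
            r[f"perimeter{suf}"] = mm.perimeter
            efds.append(morphometrics.normalize_efd(
                morphometrics.efa(outline, n_harmonics)
            ))
            labels.append((a, p))
            if organ in color_organs:
                fg_by_acc.setdefault(a, []).append(
                    imageprep.foreground_pixels(img, mask)
                )
        for base in ("length", "width", "area", "perimeter"):
            name = f"{base}{suf}"
            meta[name] = DescriptorMeta(name, "numeric", "phenomic", organ)

        space = morphometrics.morphospace(
            efds, k=k_components, organ_suffix=suf,
            index=[uid[ap] for ap in labels],
        )
        morphospaces[organ] = space
        for name in space.scores.columns:
            meta[name] = DescriptorMeta(name, "numeric", "phenomic", organ)
        for u, row in space.scores.iterrows():
            rows[u].update(row.to_dict())

        if organ in color_organs:
            hists = {}
            for a, pixel_sets in sorted(fg_by_acc.items()):
                pool = colorimetry.pool_pixels(
                    pixel_sets, max_pixels=max_pixels,
                    seed=stream_seed(seed, a, organ, "pool"),
                )
                clusters = colorimetry.kmeans_colors(
                    pool, k=k_colors,
                    seed=stream_seed(seed, a, organ, "kmeans"),
                    n_restarts=color_restarts,
                )
                desc = colorimetry.cluster_descriptors(clusters, organ)
                color_rows.setdefault(a, {}).update(desc.to_dict())
                if compute_emd:
                    hists[a] = colorimetry.histogram(pool, bins_per_channel)
            for name in colorimetry.cluster_descriptors(clusters, organ).index:
                meta[name] = DescriptorMeta(name, "numeric", "phenomic", organ)
            if compute_emd:
                accs = sorted(hists)
                mat = pd.DataFrame(0.0, index=accs, columns=accs)
                for i, a in enumerate(accs):
                    for b in accs[i + 1:]:
                        mat.loc[a, b] = mat.loc[b, a] = colorimetry.emd(
                            hists[a], hists[b]
                        )
                emd_matrices[organ] = mat

    plant_table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    color_table = pd.DataFrame.from_dict(color_rows, orient="index").sort_index()
    # broadcast accession-level color descriptors onto plant rows
    if not color_table.empty:
        joined = color_table.loc[plant_table["accession"]].set_index(plant_table.index)
        plant_table = pd.concat([plant_table, joined], axis=1)
    ordered = ["accession"] + [n for n in meta if n in plant_table.columns]
    plant_table = plant_table[ordered]
    return ExtractionResult(plant_table, meta, color_table, morphospaces, emd_matrices)


def shape_descriptors_from_outlines(
    outline_sets: dict,
    n_harmonics: int = 12,
    k_components: int = 10,
) -> tuple:
    """Plant-level shape descriptors straight from sampled outlines.

    ``outline_sets`` maps ``(accession, organ)`` to a list of per-plant
    outlines (as produced by :func:`synthdata.accession_outline_sets`).
    Skips rendering/segmentation — useful for repeated simulation
    experiments where only the shape ground truth matters.  Returns
    ``(plant_table, meta)`` in the same layout as
    :class:`ExtractionResult`.
    """
    organs = sorted({o for (_, o) in outline_sets})
    rows: dict = {}
    meta: dict = {}
    for organ in organs:
        suf = _organ_suffix(organ)
        efds, labels = [], []
        for (acc, o), outlines in sorted(outline_sets.items()):
            if o != organ:
                continue
            for plant, outline in enumerate(outlines):
                u = f"{acc}.p{plant:02d}"
                rows.setdefault(u, {"accession": acc})
                mmres = morphometrics.measures(outline)
                rows[u][f"length{suf}"] = mmres.length
                rows[u][f"width{suf}"] = mmres.width
                efds.append(morphometrics.normalize_efd(
                    morphometrics.efa(outline, n_harmonics)
                ))
                labels.append(u)
        for base in ("length", "width"):
            name = f"{base}{suf}"
            meta[name] = DescriptorMeta(name, "numeric", "phenomic", organ)
        space = morphometrics.morphospace(
            efds, k=k_components, organ_suffix=suf, index=labels
        )
        for name in space.scores.columns:
            meta[name] = DescriptorMeta(name, "numeric", "phenomic", organ)
        for u, row in space.scores.iterrows():
            rows[u].update(row.to_dict())
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return table[["accession"] + list(meta)], meta


def load_dataset_images(dataset_dir: str | Path) -> dict:
    """Read a ``<species>/<accession>/<organ>/<plant>.png`` tree back
    into the in-memory mapping used by :func:`extract_dataset`."""
    dataset_dir = Path(dataset_dir)
    images = {}
    for png in sorted(dataset_dir.glob("*/*/*/*.png")):
        if png.stem.endswith("_mask"):
            continue
        organ = png.parent.name
        accession = png.parent.parent.name
        plant = int(png.stem)
        images[(accession, organ, plant)] = (
            iio.imread(png).astype(float) / 255.0
        )
    if not images:
        raise FileNotFoundError(f"no organ images found under {dataset_dir}")
    return images


def run_selection(
    extraction: ExtractionResult,
    classical: pd.DataFrame,
    species_map: dict,
    mode: str,
    rf_config: RFConfig,
    label_level: str = "accession",
    classical_ordinal_levels: dict | None = None,
):
    """Assemble one descriptor matrix and fit the selection forest."""
    ctab = classical.drop(columns=["species"], errors="ignore")
    cmeta = infer_meta(
        ctab, dtype="classical", ordinal_levels=classical_ordinal_levels
    )
    matrix = assemble(
        phenomic=extraction.plant_table,
        classical=ctab if mode != "phenomic" else None,
        species_map=species_map,
        mode=mode,
        phenomic_meta=extraction.meta,
        classical_meta=cmeta,
    )
    selector = DescriptorSelector(matrix, rf_config, label_level=label_level)
    result = selector.fit()
    return matrix, result


def run_functional_diversity(
    matrices: dict,
    selections: dict,
    n_axes: int = 4,
    fori_variant: str = "nearest_entity",
):
    """Restrict each matrix to its RF-selected descriptors, aggregate to
    accession level, and compare functional diversity across types."""
    accession_matrices = {}
    for mode, matrix in matrices.items():
        selected = selections[mode].selected
        accession_matrices[mode] = matrix.select(selected).to_accession_level()
    return fd_report(accession_matrices, n_axes=n_axes, fori_variant=fori_variant)


def run_all(
    sim_config: SimulationConfig,
    rf_config: RFConfig | None = None,
    seed: int | None = None,
    modes: tuple = ("phenomic", "classical", "combined"),
    label_level: str = "accession",
    n_axes: int = 4,
    extract_kwargs: dict | None = None,
) -> dict:
    """Simulate, extract, select and analyze in one call.

    Returns a dict with the dataset, extraction, per-mode matrices and
    selections, and the functional-diversity table and results.
    """
    seed = sim_config.seed if seed is None else seed
    rf_config = rf_config or RFConfig(seed=stream_seed(seed, "rf"))
    dataset = generate_dataset(sim_config)
    extraction = extract_dataset(
        dataset.images, seed=stream_seed(seed, "extract"),
        **(extract_kwargs or {}),
    )
    species_map = sim_config.species_map()
    ordinal_levels = _ordinal_levels(sim_config)
    matrices, selections = {}, {}
    for mode in modes:
        matrices[mode], selections[mode] = run_selection(
            extraction,
            dataset.classical,
            species_map,
            mode,
            rf_config,
            label_level=label_level,
            classical_ordinal_levels=ordinal_levels,
        )
    fd_table, fd_results = run_functional_diversity(
        matrices, selections, n_axes=n_axes
    )
    return {
        "dataset": dataset,
        "extraction": extraction,
        "matrices": matrices,
        "selections": selections,
        "fd_table": fd_table,
        "fd_results": fd_results,
    }


def _ordinal_levels(sim_config: SimulationConfig) -> dict:
    levels = {}
    for sp in sim_config.species:
        for name, spec in sp.classical_traits.items():
            if spec.dclass == "ordinal":
                levels[name] = tuple(spec.levels)
    return levels
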