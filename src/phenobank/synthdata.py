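"""Synthetic accession generator with known ground truth.

Real genebank image campaigns (multiple species, a handful of
accessions per species, ~10 replicate plants per accession, organ
photographs on white backgrounds plus a classical descriptor table)
are emulated from species *templates* defined directly in elliptical-
Fourier coefficient space.  Because shapes, palettes and traits are
parameterized, the morphospace structure, the discriminative
descriptors, a deliberately redundant accession pair and a deliberately
displaced outlier accession are all known by construction, which makes
every downstream stage testable without field data.

Hierarchy of variation: each species template holds mean EFD
coefficients per organ; each accession draws a coefficient offset
(sd ``shape_sd_accession``); each plant adds independent noise
(sd ``shape_sd_plant``).  Color palettes are species-level Gaussian
mixtures in RGB; classical traits are species-level distributions
sampled once per accession (classical scoring is accession-level).

Randomness: one stream per (accession, organ) derived from the master
seed by stable hashing, so adding accessions or organs never shifts
earlier draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .exceptions import DegenerateOutlineError, DegenerateTemplateError
from .morphometrics import EFDSet, reconstruct, shoelace_area

__all__ = [
    "PaletteComponent",
    "TraitSpec",
    "SpeciesTemplate",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "sample_outlines",
    "render_organ_image",
    "generate_dataset",
    "sample_classical_table",
    "make_species_templates",
    "default_config",
    "stream_seed",
]


# --------------------------------------------------------------------------
# templates and configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PaletteComponent:
    """One Gaussian component of a species color palette."""

    mean: tuple          # RGB in [0, 1]
    sd: float
    weight: float


@dataclass(frozen=True)
class TraitSpec:
    """Distribution of one classical trait within a species.

    numeric: N(mean, sd), optionally rounded to integers (e.g. days to
    flowering); ordinal/nominal: categorical over ``levels`` with
    probabilities ``probs`` (ordinal levels are rank-ordered).
    """

    dclass: str                       # numeric | ordinal | nominal
    mean: float | None = None
    sd: float | None = None
    integer: bool = False
    levels: tuple = ()
    probs: tuple = ()

    def __post_init__(self):
        if self.dclass not in ("numeric", "ordinal", "nominal"):
            raise ValueError(f"unknown trait class {self.dclass!r}")
        if self.dclass == "numeric":
            if self.sd is None or self.sd < 0:
                raise ValueError("numeric trait needs sd >= 0")
        else:
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("category probabilities must sum to 1")
            if len(self.levels) != len(self.probs):
                raise ValueError("levels/probs length mismatch")


@dataclass
class SpeciesTemplate:
    """Everything needed to simulate one species' accessions."""

    species_id: str
    organ_efd: dict                  # organ -> (H, 4) mean coefficients
    shape_sd_accession: float
    shape_sd_plant: float
    palette: tuple                   # tuple[PaletteComponent, ...]
    classical_traits: dict           # name -> TraitSpec

    def __post_init__(self):
        if self.shape_sd_accession < 0 or self.shape_sd_plant < 0:
            raise ValueError("shape sds must be >= 0")
        w = sum(c.weight for c in self.palette)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("palette weights must sum to 1")
        if any(c.sd < 0 for c in self.palette):
            raise ValueError("palette sds must be >= 0")
        self.organ_efd = {k: np.asarray(v, float) for k, v in self.organ_efd.items()}

    @property
    def organs(self) -> tuple:
        return tuple(self.organ_efd)


@dataclass
class SimulationConfig:
    """Layout of a synthetic campaign.

    ``plants_per_accession`` defaults to 10, the usual number of healthy
    adult plants sampled per plot in classical characterization.
    """

    species: list
    accessions_per_species: int = 3
    plants_per_accession: int = 10
    image_size: int = 128
    seed: int = 0
    accession_counts: dict = field(default_factory=dict)   # species_id -> n
    redundant_pair: tuple | None = None                    # (canonical, twin)
    outlier_accession: str | None = None
    discriminative_descriptors: tuple = ()

    def __post_init__(self):
        if self.accessions_per_species < 1 or self.plants_per_accession < 1:
            raise ValueError("counts must be >= 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.redundant_pair and self.outlier_accession in (self.redundant_pair or ()):
            raise ValueError("outlier accession must not be in the redundant set")

    def n_accessions(self, species_id: str) -> int:
        return self.accession_counts.get(species_id, self.accessions_per_species)

    def accession_ids(self, species_id: str) -> list:
        return [f"{species_id}-{i:02d}" for i in range(self.n_accessions(species_id))]

    def all_accessions(self) -> list:
        out = []
        for sp in self.species:
            out.extend(self.accession_ids(sp.species_id))
        return out

    def species_map(self) -> dict:
        return {
            acc: sp.species_id
            for sp in self.species
            for acc in self.accession_ids(sp.species_id)
        }

    def template_of(self, accession: str) -> SpeciesTemplate:
        sp_id = self.species_map()[accession]
        return next(s for s in self.species if s.species_id == sp_id)


@dataclass
class GroundTruth:
    """What the generator guarantees, for recovery tests."""

    species_of: dict
    discriminative_descriptors: list
    redundant_accessions: list
    outlier_accession: str | None

    def __post_init__(self):
        if self.outlier_accession in self.redundant_accessions:
            raise ValueError("outlier must not be in the redundant set")


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`generate_dataset`."""

    config: SimulationConfig
    images: dict        # (accession, organ, plant) -> (H, W, 3) float image
    masks: dict         # (accession, organ, plant) -> (H, W) bool mask
    classical: pd.DataFrame
    ground_truth: GroundTruth


# --------------------------------------------------------------------------
# seeding
# --------------------------------------------------------------------------

def stream_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed (< 2^31) for a named random stream."""
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# outline and image sampling
# --------------------------------------------------------------------------

def _is_simple(outline: np.ndarray) -> bool:
    poly = Polygon(outline)
    return poly.is_valid and poly.area > 1e-9


def sample_outlines(
    template: SpeciesTemplate,
    organ: str,
    n: int,
    accession_seed: int,
    offset_seed: int | None = None,
    n_points: int = 200,
    max_retries: int = 100,
) -> list:
    """Draw ``n`` per-plant outlines for one accession of a species.

    The accession-level coefficient offset comes from ``offset_seed``
    (defaults to ``accession_seed``); per-plant noise comes from
    ``accession_seed``.  Passing another accession's ``offset_seed``
    creates a phenotypically redundant twin with independent plants.
    Self-intersecting reconstructions are rejected and resampled.
    """
    if organ not in template.organ_efd:
        raise KeyError(f"template {template.species_id} has no organ {organ!r}")
    mean = template.organ_efd[organ]
    rng_off = np.random.default_rng(
        accession_seed if offset_seed is None else offset_seed
    )
    offset = rng_off.normal(0.0, template.shape_sd_accession, size=mean.shape)
    rng = np.random.default_rng(accession_seed)

    outlines = []
    for _ in range(n):
        for _attempt in range(max_retries):
            noise = rng.normal(0.0, template.shape_sd_plant, size=mean.shape)
            pts = reconstruct(EFDSet(mean + offset + noise), n_points)
            if _is_simple(pts):
                outlines.append(pts)
                break
        else:
            raise DegenerateTemplateError(
                f"{template.species_id}/{organ}: no simple outline in "
                f"{max_retries} tries"
            )
    return outlines


def render_organ_image(
    outline: np.ndarray,
    palette,
    image_size: int,
    seed: int,
    margin: float = 0.12,
):
    """Rasterize an outline on a white background and paint its interior
    from the palette mixture.  Returns ``(image, mask)``.

    The outline is centered and scaled so its larger extent fills
    ``1 - 2*margin`` of the frame.
    """
    pts = np.asarray(outline, float)
    if shoelace_area(pts) <= 1e-12:
        raise DegenerateOutlineError("outline has zero area; cannot render")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent = float(np.max(hi - lo))
    scale = (1.0 - 2.0 * margin) * image_size / extent
    centered = (pts - (lo + hi) / 2.0) * scale + image_size / 2.0

    rr, cc = draw_polygon(centered[:, 1], centered[:, 0], shape=(image_size, image_size))
    if len(rr) == 0:
        raise DegenerateOutlineError("outline rasterized to zero pixels")
    mask = np.zeros((image_size, image_size), dtype=bool)
    mask[rr, cc] = True

    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in palette])
    means = np.array([c.mean for c in palette], dtype=float)
    sds = np.array([c.sd for c in palette], dtype=float)
    comp = rng.choice(len(palette), size=len(rr), p=weights)
    colors = means[comp] + rng.standard_normal((len(rr), 3)) * sds[comp, None]

    image = np.ones((image_size, image_size, 3), dtype=float)
    image[rr, cc] = np.clip(colors, 0.0, 1.0)
    return image, mask


# --------------------------------------------------------------------------
# classical table and full dataset
# --------------------------------------------------------------------------

def _sample_trait(spec: TraitSpec, rng: np.random.Generator):
    if spec.dclass == "numeric":
        value = rng.normal(spec.mean, spec.sd)
        return int(round(value)) if spec.integer else float(value)
    return str(rng.choice(list(spec.levels), p=list(spec.probs)))


def sample_classical_table(config: SimulationConfig) -> pd.DataFrame:
    """Accession-level classical descriptor table (one row per accession).

    The designated redundant twin copies its canonical partner's row
    verbatim — redundant accessions are indistinguishable on paper.
    """
    rows = {}
    species_map = config.species_map()
    for acc in config.all_accessions():
        template = config.template_of(acc)
        rng = np.random.default_rng(stream_seed(config.seed, acc, "classical"))
        rows[acc] = {
            name: _sample_trait(spec, rng)
            for name, spec in template.classical_traits.items()
        }
    if config.redundant_pair:
        canonical, twin = config.redundant_pair
        rows[twin] = dict(rows[canonical])
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "accession"
    table.insert(0, "species", [species_map[a] for a in table.index])
    return table


def accession_outline_sets(config: SimulationConfig) -> dict:
    """All per-plant outlines, keyed ``(accession, organ)`` — the
    image-free path through the shape ground truth."""
    out = {}
    for acc in config.all_accessions():
        template = config.template_of(acc)
        offset_acc = acc
        if config.redundant_pair and acc == config.redundant_pair[1]:
            offset_acc = config.redundant_pair[0]
        for organ in template.organs:
            out[(acc, organ)] = sample_outlines(
                template,
                organ,
                config.plants_per_accession,
                accession_seed=stream_seed(config.seed, acc, organ),
                offset_seed=stream_seed(config.seed, offset_acc, organ, "offset"),
            )
    return out


def generate_dataset(config: SimulationConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Render the full synthetic campaign: one image + mask per organ per
    plant per accession, the classical table, and the ground truth.

    When ``outdir`` is given, images and masks are written as 8-bit PNG
    under ``<species>/<accession>/<organ>/<plant>.png``, the classical
    table as ``classical.csv`` and the ground truth as JSON.
    """
    outlines = accession_outline_sets(config)
    species_map = config.species_map()
    images, masks = {}, {}
    for (acc, organ), outline_list in outlines.items():
        template = config.template_of(acc)
        for plant, outline in enumerate(outline_list):
            img, mask = render_organ_image(
                outline,
                template.palette,
                config.image_size,
                seed=stream_seed(config.seed, acc, organ, plant, "render"),
            )
            images[(acc, organ, plant)] = img
            masks[(acc, organ, plant)] = mask

    classical = sample_classical_table(config)
    truth = GroundTruth(
        species_of=species_map,
        discriminative_descriptors=list(config.discriminative_descriptors),
        redundant_accessions=list(config.redundant_pair or ()),
        outlier_accession=config.outlier_accession,
    )
    dataset = SyntheticDataset(config, images, masks, classical, truth)
    if outdir is not None:
        write_dataset(dataset, Path(outdir))
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_map = dataset.config.species_map()
    for (acc, organ, plant), img in dataset.images.items():
        d = outdir / species_map[acc] / acc / organ
        d.mkdir(parents=True, exist_ok=True)
        iio.imwrite(d / f"{plant}.png", (img * 255).round().astype(np.uint8))
        iio.imwrite(
            d / f"{plant}_mask.png",
            (dataset.masks[(acc, organ, plant)] * 255).astype(np.uint8),
        )
    dataset.classical.to_csv(outdir / "classical.csv")
    truth = dataset.ground_truth
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "species_of": truth.species_of,
                "discriminative_descriptors": truth.discriminative_descriptors,
                "redundant_accessions": truth.redundant_accessions,
                "outlier_accession": truth.outlier_accession,
            },
            indent=2,
            sort_keys=True,
        )
    )
    (outdir / "config.json").write_text(config_to_json(dataset.config))


def config_to_json(config: SimulationConfig) -> str:
    payload = asdict(config)
    for sp in payload["species"]:
        sp["organ_efd"] = {k: np.asarray(v).tolist() for k, v in sp["organ_efd"].items()}
    return json.dumps(payload, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def make_species_templates(
    n_species: int = 5,
    organs: tuple = ("seed", "leaf"),
    n_harmonics: int = 8,
    separation: float = 3.0,
    shape_sd_accession: float = 0.02,
    shape_sd_plant: float = 0.01,
    seed: int = 0,
    displaced_species: int | None = None,
    displacement: float = 8.0,
) -> list:
    """Species templates whose means are separated by ``separation``
    pooled within-species standard deviations on every varying trait.

    One species can be displaced by ``displacement`` pooled sds instead,
    to act as a functional outlier.  Shape offsets decay as 1/n^2 with
    harmonic order so perturbed outlines stay simple.
    """
    rng = np.random.default_rng(seed)
    pooled = float(np.hypot(shape_sd_accession, shape_sd_plant))
    decay = 1.0 / np.arange(1, n_harmonics + 1) ** 2

    templates = []
    for s in range(n_species):
        displaced = s == displaced_species
        # shape displacement is capped so perturbed outlines stay simple;
        # trait displacement has no such geometric constraint
        sep = min(displacement, 8.0) if displaced else separation
        bump = displacement if displaced else 0.0   # extra sds on numeric traits
        hot = s + (3 if displaced else 0)           # distinct modal categories
        organ_efd = {}
        for organ in organs:
            base = np.zeros((n_harmonics, 4))
            base[0] = [1.0, 0.0, 0.0, 0.55 if organ == "seed" else 0.40]
            base[2, 0] = 0.04 if organ == "leaf" else 0.0   # lobing accent
            # aspect ladder; a displaced species is pushed well past the top
            # of the ladder (much rounder organs than any ordinary species)
            base[0, 3] += (s * separation + (2 * sep if displaced else 0.0)) * pooled
            direction = rng.standard_normal((n_harmonics, 4)) * decay[:, None]
            direction[0, :] *= 0.2                          # keep harmonic 1 tame
            base += direction * sep * pooled
            organ_efd[organ] = base

        hue = rng.uniform(0.15, 0.75, size=3)
        palette = (
            PaletteComponent(tuple(np.clip(hue, 0.05, 0.85)), 0.03, 0.7),
            PaletteComponent(tuple(np.clip(hue * 0.5 + 0.1, 0.05, 0.85)), 0.03, 0.3),
        )

        def biased(levels, which, hot_prob=0.6):
            p = np.full(len(levels), (1 - hot_prob) / (len(levels) - 1))
            p[which % len(levels)] = hot_prob
            return tuple(p / p.sum())

        traits = {
            # day counts are recorded as integers: accessions of the same
            # species often tie, so these separate species but rarely
            # accessions within a species
            "days_to_flowering": TraitSpec(
                "numeric", mean=45.0 + (s * separation + bump) * 0.6, sd=0.6,
                integer=True,
            ),
            "days_to_harvest": TraitSpec(
                "numeric", mean=95.0 + (s * separation + bump) * 0.8, sd=0.8,
                integer=True,
            ),
            # the engineered discriminative trait: continuous and
            # accession-unique, so it is informative at every split level
            # (species and within-species alike)
            "weight_100_seeds": TraitSpec(
                "numeric", mean=20.0 + (s * separation + bump) * 4.0, sd=4.0
            ),
            "growth_habit": TraitSpec(
                "nominal",
                levels=("erect", "semi-erect", "prostrate"),
                probs=biased(("erect", "semi-erect", "prostrate"), hot),
            ),
            # seed color is shared across species groups (related species
            # often share it), so it only partially separates species
            "seed_color_primary": TraitSpec(
                "nominal",
                levels=("cream", "brown", "red", "black"),
                probs=biased(("cream", "brown", "red", "black"), hot % 2),
            ),
            "vigor": TraitSpec(
                "ordinal",
                levels=("low", "medium", "high", "very_high"),
                probs=biased(("low", "medium", "high", "very_high"), hot),
            ),
        }
        templates.append(
            SpeciesTemplate(
                species_id=f"SP{s + 1}",
                organ_efd=organ_efd,
                shape_sd_accession=shape_sd_accession,
                shape_sd_plant=shape_sd_plant,
                palette=palette,
                classical_traits=traits,
            )
        )
    return templates


def default_config(
    n_species: int = 5,
    accessions_per_species: int = 3,
    plants_per_accession: int = 10,
    image_size: int = 128,
    seed: int = 0,
    separation: float = 3.0,
    organs: tuple = ("seed", "leaf"),
    redundant_pair: bool = True,
    outlier: bool = False,
) -> SimulationConfig:
    """Study conditions used throughout: ``n_species`` species with
    ``accessions_per_species`` accessions and 10 plants each, species
    means 3 pooled sds apart, a redundant accession pair within species
    1, and optionally an extra displaced singleton outlier species.

    ``weight_100_seeds`` (continuous, accession-unique) is the
    designated discriminative descriptor.
    """
    templates = make_species_templates(
        n_species=n_species,
        organs=organs,
        separation=separation,
        seed=stream_seed(seed, "templates"),
    )
    counts = {}
    outlier_acc = None
    if outlier:
        # the outlier sits far beyond the ladder of ordinary species on
        # every trait axis, so it is unambiguous in any descriptor space
        displaced = make_species_templates(
            n_species=1,
            organs=organs,
            separation=separation,
            seed=stream_seed(seed, "outlier-template"),
            displaced_species=0,
            displacement=max(8.0, (n_species + 4) * separation),
        )[0]
        displaced.species_id = "OUT"
        templates.append(displaced)
        counts["OUT"] = 1
        outlier_acc = "OUT-00"
    pair = ("SP1-00", "SP1-01") if redundant_pair and accessions_per_species >= 2 else None
    return SimulationConfig(
        species=templates,
        accessions_per_species=accessions_per_species,
        plants_per_accession=plants_per_accession,
        image_size=image_size,
        seed=seed,
        accession_counts=counts,
        redundant_pair=pair,
        outlier_accession=outlier_acc,
        discriminative_descriptors=("weight_100_seeds",),
    )
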