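# Methods

This note documents the models and procedures implemented in
`phenobank`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Image preparation

Images are float RGB rasters in [0, 1], coordinates x = column,
y = row, origin top-left. White balance is a per-channel linear gain
`g_c = target_c / observed_c` from a color-card patch, clipped to
[0, 1]; a patch channel mean ≤ 0.01 is rejected as unusable. The
correction is idempotent once applied (the corrected card reads at its
targets). Segmentation is Otsu's threshold on luminance (the plain
channel mean — no colorimetric weighting is assumed), foreground on the
dark side, holes filled, largest connected component kept. This
replaces interactive or service-based background removal with a
deterministic, testable operation that is adequate for the
high-contrast photobox/scanner imagery the pipeline targets; it assumes
one organ per image on a near-white background. Outlines come from
subpixel contour tracing on the padded mask, oriented counterclockwise
(positive shoelace area); a foreground touching the image border
produces a warning, not an error, since scanner crops can clip
leaflets.

## Elliptical Fourier analysis

Outlines are closed polygons parameterized by arc length. Coefficients
follow the Kuhl–Giardina chain formulation: each polygon segment
contributes analytically to the Fourier integrals of x(t), y(t), so no
quadrature error enters. Consequences worth knowing:

* the decomposition is exact for the piecewise-linear curve, and is
  cross-checked in the tests against an independent per-segment
  Gauss–Legendre quadrature oracle to 10⁻⁶ relative;
* because the parameter is arc length (not the ellipse angle), the
  first-harmonic coefficients of an eccentric ellipse are *not* exactly
  its semiaxes — for semiaxes 4 : 1.5 the deviation is ≈ 10%, with the
  energy reappearing in odd harmonics. Tests assert the semiaxis
  identity only for near-circular shapes and verify eccentric shapes
  through reconstruction.

Normalization standardizes size (first-harmonic semi-major magnitude),
rotation and starting point from the first-harmonic ellipse. The
residual two-fold ambiguity (which end of the major axis the start sits
on) flips the sign of even harmonics; it is resolved deterministically
by making the largest-magnitude even-harmonic coefficient positive.
Reflection is deliberately **not** removed: mirror shapes stay
distinct, since organ chirality can be a real trait. Default 20
harmonics for image extraction (typical seed/leaf practice;
configurable); the synthetic templates use 8, which already spans the
shape variation they encode.

Morphospaces are PCAs of the flattened normalized coefficient vectors,
at most 10 components retained per organ, axis signs fixed by making
each component's largest-magnitude loading positive. Per-plant outlines
enter the PCA individually (keeping its sample size large) and are
averaged to accession level afterwards, as mean scores.

## Colorimetry

Histograms use a fixed regular RGB grid, 4 bins per channel (64 bins)
by default; empty bins are kept so grids stay comparable. The earth
mover's distance solves the transportation linear program
(`scipy.optimize.linprog`, HiGHS) with Euclidean ground distance
between bin centers; tests verify it against a unit-mass assignment
oracle and the metric axioms. EMD matrices are a QC/dendrogram product,
not a classifier input.

Cluster descriptors come from k-means (scikit-learn, k-means++
seeding, 10 restarts, fixed seeds) on an accession's pooled foreground
pixels, subsampled to ≤ 50,000 for tractability. **Cluster
correspondence across accessions is by luminance rank**: centroids are
sorted by decreasing (R+G+B)/3 before naming, so descriptor `R_3S`
means "red channel of the third-brightest seed cluster". This is a
convention, not a fact of nature — two accessions' third-brightest
clusters need not be homologous colors — and it is the largest
interpretive gap in the colorimetric descriptor design; any analysis
that depends on cluster identity should inspect the centroids
themselves.

## Descriptor matrices

Descriptors carry a class (numeric / ordinal / nominal), a provenance
(phenomic / classical) and, for phenomic ones, an organ. Classification
uses plant-level replicate rows (10 per accession by default);
accession-level values (classical scores, color clusters) are broadcast
to the plants of their accession. Functional diversity uses
accession-level rows: numeric mean, categorical mode with ties broken
lexicographically. For tree models, ordinals map to their declared rank
integers and nominals to one-hot children tagged with their parent;
missing values up to 10% per column are imputed (mean/mode), more is an
error.

## Random-forest selection and minimal depth

100 CART trees on bootstrap samples with √p feature subsampling, Gini
impurity, no depth cap, minimum leaf 1; stratified 70/30
train/validation split. Two diagnostics are reported separately because
they answer different questions: the OOB error (bootstrap-excluded
votes on training rows) estimates generalization, and the row-
normalized confusion matrix on the held-out 30% localizes which
accessions are mistaken for which — mutual confusion between two
accessions is the operational signature of phenotypic redundancy.

Minimal depth of a descriptor in one tree is the depth of its
shallowest split (root = 0). Descriptors a tree never uses are assigned
that tree's leaf depth + 1 — a penalty convention (pluggable) chosen so
that rarely-used descriptors rank below consistently-used ones rather
than dropping out of the average. One-hot children collapse to their
parent by per-tree minimum *before* averaging. The ranking is ascending
mean minimal depth, ties broken by usage count then name; the top 15
descriptors feed the diversity analysis. Note one structural bias: a
k-level nominal parent owns k encoded columns and therefore appears in
candidate subsets roughly k times as often as a numeric descriptor,
which deflates its minimal depth; rankings across descriptor classes
should be read with that in mind.

## Functional diversity

Mixed-type dissimilarity is Gower: numeric |Δ|/range, ordinal by
Podani's tie-corrected rank formula, nominal 0/1, averaged over
descriptors non-missing in both rows; constant descriptors are dropped
with a warning. The trait space is classical PCoA (double-centering of
−D²/2); negative eigenvalues — expected for Gower distances — are
dropped with no Cailliez/Lingoes correction (simplest defensible
choice; a correction can be layered on the distance matrix before
`pcoa` if wanted), and at most 4 positive axes are retained by default.
Hulls and ordination figures always use axes 1–2.

Indices, per functional entity (species):

* FSpe: mean member distance to the pooled accession centroid, divided
  by the **maximum per-accession distance**. The normalization is what
  pins the top of the scale: the FE holding the single farthest
  accession scores exactly 1.00, and both reference quantities in
  `scripts/acceptance.py` are instances of this identity.
* FOri, default `nearest_entity` variant: mean over members of the
  distance to the nearest accession of a different FE, max-normalized.
  This variant is defined for singleton FEs, which is why it is the
  default; the literal reading "average distance between accessions of
  the same species" (`intra_mean` variant, also provided) is undefined
  for singletons and is reported as missing there. The two variants
  answer subtly different questions and should not be mixed in one
  table.
* FIde: unweighted per-axis mean of member coordinates (every accession
  has weight 1).

A per-accession nearest-neighbor distance (nearest other accession of
*any* FE) is exposed as a redundancy diagnostic: near-duplicate
accessions score near zero there even though they sit inside the same
FE.

Hull areas are in squared PCoA-coordinate units, which inherit the
Gower scale; areas are comparable between descriptor types computed on
the same accessions, but their absolute magnitude has no physical unit.

## Synthetic campaigns and what passing tests show

The generator defines species templates directly in EFD coefficient
space: mean coefficients per organ, an accession-level coefficient
offset (sd 0.02 per coefficient) and plant-level noise (sd 0.01), an
RGB Gaussian-mixture palette, and per-trait classical distributions.
Species means sit 3 pooled within-species sds apart by default — the
regime in which a characterization study expects descriptors to
discriminate. Self-intersecting outline draws are rejected and
resampled (≤ 100 tries), which is unbiased at these noise levels.
Random streams are derived per (accession, organ) by stable hashing of
the master seed, so enlarging a campaign never shifts existing draws.

Ground-truth constructions used by the recovery tests:

* the **engineered discriminative descriptor** (`weight_100_seeds`) is
  the only continuous, accession-unique classical trait; the day-count
  traits are integer-rounded with small within-species spread (ties
  between accessions are common, so they separate species but rarely
  accessions), and the categorical scores are noisy (hot-category
  probability 0.6) with seed color shared between species groups. That
  asymmetry — informative at every split level vs. informative only at
  species level — is what "engineered to be discriminative" means here;
* the **redundant pair** shares its accession-level shape offsets and
  its classical row, with independent plant noise: indistinguishable in
  expectation, as true duplicates would be;
* the **outlier** is a singleton species displaced far beyond the
  species ladder on every classical trait and pushed past the top of
  the shape ladder (the shape displacement is capped at 8 pooled sds so
  outlines stay simple).

The generator emulates the *structure* of a characterization campaign,
not its photometric reality: no lighting or lens effects, no color
card inside the synthetic frames (white balance is tested on separate
card fixtures), a single organ per image, palettes that are mixtures of
isotropic Gaussians. Passing recovery tests therefore show that the
pipeline's statistics recover structure that is genuinely present in
descriptor space; they do not certify segmentation or color constancy
on difficult field photographs.

## Problem sizes and determinism

Default experiment sizes were chosen as the smallest that exercise the
claims: the classification recovery uses 5 species × 3 accessions × 10
plants over 20 seeds (shape descriptors computed directly from sampled
outlines; rendering and re-segmentation are covered by the smaller
end-to-end fixtures), and the diversity recovery uses 3 ordinary
species plus the outlier with 5 plants over 20 seeds. The image-based
smoke fixture is 2 species × 2 accessions × 3 plants at 96 px. All
randomness flows from explicit integer seeds; rerunning any stage with
the same seed reproduces outputs byte-for-byte, and the CLI writes a
checksum manifest per stage to make that checkable.

## Known limitations

* One connected organ per image; multi-seed trays must be split
  upstream.
* Luminance-ranked color clusters are not guaranteed homologous across
  accessions (see above).
* Gower + PCoA discards negative-eigenvalue structure; with heavily
  nominal descriptor sets a sizable share of variance can live there.
* Minimal depth inherits the forest's candidate-sampling biases
  (one-hot multiplicity, correlated descriptors sharing credit).
* FSpe/FOri max-normalization makes indices relative to the most
  extreme accession in the dataset at hand; values are not comparable
  across datasets.
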