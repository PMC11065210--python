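"""Image standardization, segmentation and outline extraction.

Organ photographs (one organ on a near-white background, as produced by
a photobox or flatbed scanner) are white-balanced against a color card,
binarized by Otsu thresholding on luminance, cleaned (holes filled,
largest connected component kept) and traced into a closed outline for
downstream elliptical Fourier analysis.  Foreground pixels feed the
colorimetric descriptors.

Conventions: images are float arrays in [0, 1] with shape (H, W, 3);
outlines are (N, 2) arrays of (x=column, y=row) pixel coordinates with
counterclockwise orientation (positive shoelace area).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .exceptions import BorderClipWarning, NoForegroundError, UnusableCardError
from .morphometrics import shoelace_area

__all__ = [
    "white_balance",
    "binarize",
    "trace_outline",
    "foreground_pixels",
    "luminance",
]


def luminance(image: np.ndarray) -> np.ndarray:
    """Per-pixel luminance as the plain channel mean (R+G+B)/3."""
    return np.asarray(image, dtype=float).mean(axis=-1)


def white_balance(
    image: np.ndarray,
    card_patch_means,
    card_patch_targets,
) -> np.ndarray:
    """Linear per-channel white balance from a reference-card patch.

    Each channel is scaled by ``gain_c = target_c / observed_c`` where
    ``observed_c`` is the channel mean measured on the card patch and
    ``target_c`` its known reference value; the result is clipped to
    [0, 1].  Applying the correction twice with the corrected card is
    the identity (gains become 1).
    """
    observed = np.asarray(card_patch_means, dtype=float).ravel()
    targets = np.asarray(card_patch_targets, dtype=float).ravel()
    if observed.shape != (3,) or targets.shape != (3,):
        raise ValueError("card patch values must be 3-vectors (R, G, B)")
    if np.any(observed <= 0.01):
        raise UnusableCardError(
            f"card patch channel mean(s) {observed} too dark to be usable"
        )
    gains = targets / observed
    return np.clip(np.asarray(image, dtype=float) * gains, 0.0, 1.0)


def binarize(image: np.ndarray) -> np.ndarray:
    """Segment the organ from a light background.

    Otsu's threshold on luminance; the darker side is foreground
    (white-background convention).  Interior holes are filled and only
    the largest connected component is kept.
    """
    lum = luminance(image)
    if lum.size == 0:
        raise NoForegroundError("empty image")
    if np.ptp(lum) < 1e-9:
        raise NoForegroundError("uniform image: nothing to segment")
    thresh = threshold_otsu(lum, nbins=256)
    mask = lum < thresh
    if not mask.any():
        raise NoForegroundError("no pixels below the Otsu threshold")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == np.argmax(sizes)
    return mask


def trace_outline(mask: np.ndarray) -> np.ndarray:
    """Boundary of the mask's single foreground component as a closed,
    counterclockwise outline in (x, y) pixel coordinates.

    A foreground touching the image border yields a
    :class:`BorderClipWarning`; the (clipped) outline is still returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoForegroundError("mask has no foreground pixels")
    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
    ):
        warnings.warn(
            "foreground touches the image border; outline may be clipped",
            BorderClipWarning,
            stacklevel=2,
        )
    # pad so border-touching components still yield closed contours
    padded = np.pad(mask, 1)
    contours = skmeasure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise NoForegroundError("no contour found")
    contour = max(contours, key=len)          # outer boundary is longest
    # (row, col) in padded frame -> (x=col, y=row) in original frame
    outline = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
    if np.allclose(outline[0], outline[-1]):
        outline = outline[:-1]
    if shoelace_area(outline, signed=True) < 0:
        outline = outline[::-1]
    return outline


def foreground_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """RGB triples (N, 3) where ``mask`` is true, in row-major order."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise NoForegroundError("mask has no foreground pixels")
    return image[mask]
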