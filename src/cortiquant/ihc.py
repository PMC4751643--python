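"""Automated DAB+ cell quantification from brightfield RGB sections.

The quantification proceeds in four steps:

1. **Contrast enhancement.** DAB (3,3'-diaminobenzidine) deposits are brown,
   i.e. red-dominant, while the hematoxylin counterstain is blue-dominant and
   the background is near white.  The *excess-red* transform
   ``E = clamp(2R - B - G, 0, 255)`` vanishes on achromatic pixels (white
   background, gray) and on blue-dominant tissue, and is large on DAB.
2. **Cell segmentation.** The excess-red channel is binarised with the
   maximum-entropy (Kapur-Sahoo-Wong) threshold, then cleaned with a
   morphological opening and small-object removal to suppress staining
   specks and dust.
3. **Tissue segmentation.** The total section area is recovered from the
   blue channel with an Otsu threshold (white background vs stained tissue)
   followed by hole filling.
4. **Density.** Cell density is the area occupied by cells divided by the
   total tissue area of the section, a dimensionless fraction in [0, 1].

Scikit-learn style transformers (:class:`CellSegmenter`,
:class:`TissueSegmenter`) wrap the segmentation steps; the module-level
functions are the underlying primitives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening, remove_small_objects
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DataError, DegenerateHistogramError, NoTissueError

logger = logging.getLogger(__name__)

#: Blue level above which an Otsu class is considered white background.
WHITE_BLUE_MIN = 200

#: Default microns-per-pixel calibration (documented package default; not a
#: scanner-derived value).
DEFAULT_UM_PER_PX = 0.46


def _as_rgb(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataError(
            f"expected an H x W x 3 RGB image, got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise DataError("RGB intensities must lie in [0, 255]")
    return arr


def _as_gray(gray) -> np.ndarray:
    arr = np.asarray(gray)
    if arr.size == 0:
        raise DataError("empty gray image")
    if arr.min() < 0 or arr.max() > 255:
        raise DataError("gray intensities must lie in [0, 255]")
    return arr


def excess_red(img) -> np.ndarray:
    """Excess-red contrast enhancement ``clamp(2R - B - G, 0, 255)``.

    Computed in a signed integer range wide enough to avoid uint8
    wrap-around before clamping.  Returns a uint8 image of the input's
    spatial shape.
    """
    arr = _as_rgb(img).astype(np.int32)
    e = 2 * arr[..., 0] - arr[..., 2] - arr[..., 1]
    return np.clip(e, 0, 255).astype(np.uint8)


def _kapur_criterion(gray) -> np.ndarray:
    """Kapur entropy criterion phi(t) for every candidate level t in 0..255.

    phi(t) is the sum of Shannon entropies of the normalised sub-histograms
    at or below t and strictly above t; invalid splits (one empty class)
    are -inf.  Empty bins contribute zero entropy.
    """
    arr = _as_gray(gray)
    hist = np.bincount(arr.ravel().astype(np.intp), minlength=256)[:256]
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: image has < 2 distinct intensity values"
        )
    p = hist / hist.sum()
    cum_p = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_s = np.cumsum(plogp)
    s_tot = cum_s[-1]

    phi = np.full(256, -np.inf)
    valid = (cum_p > 0.0) & (cum_p < 1.0)
    idx = np.nonzero(valid)[0]
    p0 = cum_p[idx]
    p1 = 1.0 - p0
    # H_low = log P0 - S(t)/P0 ; H_high = log P1 - (S_tot - S(t))/P1
    phi[idx] = (
        np.log(p0) - cum_s[idx] / p0 + np.log(p1) - (s_tot - cum_s[idx]) / p1
    )
    return phi


def entropy_threshold(gray) -> int:
    """Maximum-entropy (Kapur) threshold of an 8-bit gray image.

    Builds a 256-bin histogram on the raw 8-bit range and returns the level
    ``t*`` maximising the sum of Shannon entropies of the normalised
    sub-histograms at or below ``t`` and strictly above ``t``.  Ties are
    broken toward the lowest maximising level so the result is
    deterministic.

    Raises
    ------
    DegenerateHistogramError
        If the image has fewer than two distinct intensity values.
    """
    phi = _kapur_criterion(gray)
    return int(np.argmax(phi))  # argmax takes the lowest index on ties


def _entropy_candidates(gray) -> list[int]:
    """Local maxima of the Kapur criterion, best first (ties: lowest t)."""
    phi = _kapur_criterion(gray)
    padded = np.concatenate(([-np.inf], phi, [-np.inf]))
    is_max = (phi >= padded[:-2]) & (phi >= padded[2:]) & np.isfinite(phi)
    cand = np.nonzero(is_max)[0]
    order = np.lexsort((cand, -phi[cand]))
    return [int(t) for t in cand[order]]


def segment_cells(
    img,
    min_object_area: int = 20,
    opening_radius: int = 1,
    return_threshold: bool = False,
):
    """Binary mask of DAB+ cells in an RGB section image.

    Thresholds the excess-red channel at the maximum-entropy level, then
    applies a morphological opening with a disc structuring element and
    removes 8-connected components smaller than ``min_object_area`` px^2.

    The excess-red transform maps every achromatic or blue-dominant pixel
    (white background, hematoxylin tissue) to exactly zero, so the zero
    bin is structural background rather than signal; the entropy threshold
    is therefore computed over the positive excess-red values.  When the
    positive support is too narrow to split (fewer than two distinct
    values), the full histogram is used instead.

    A section whose excess-red channel is constant zero carries no DAB
    signal at all; that is a valid observation (density 0), so an empty
    mask is returned with a logged warning instead of raising.  A constant
    *nonzero* excess-red channel is still a degenerate histogram error.
    """
    if min_object_area < 0:
        raise DataError("min_object_area must be >= 0")
    e = excess_red(img)
    threshold: int | None = None
    if e.min() == e.max():
        if e.flat[0] == 0:
            logger.warning(
                "blank input: excess-red channel is constant zero; "
                "returning an empty cell mask"
            )
            mask = np.zeros(e.shape, dtype=bool)
            return (mask, threshold) if return_threshold else mask
        raise DegenerateHistogramError(
            "degenerate histogram: constant nonzero excess-red channel"
        )
    threshold = entropy_threshold(e)
    mask = e > threshold
    if opening_radius > 0:
        # On a near-degenerate histogram (dominant zero spike plus one wide
        # stain mode) the global entropy maximum can fall inside the stain
        # mode, yielding spatially incoherent salt.  The opening detects
        # this: if it destroys more than half the thresholded pixels, fall
        # back to the best entropy-criterion local maximum whose mask
        # survives the opening.  On well-separated histograms the global
        # maximum is coherent and this safeguard never engages.
        selem = disk(opening_radius)
        opened = opening(mask, selem)
        if opened.sum() < 0.5 * mask.sum():
            for t in _entropy_candidates(e):
                m = e > t
                o = opening(m, selem)
                if o.sum() >= 0.5 * m.sum():
                    threshold, mask, opened = t, m, o
                    break
        mask = opened
    if min_object_area > 0:
        # remove_small_objects keeps components with area >= min_size,
        # i.e. removes those with area < min_object_area (8-connectivity).
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # "only one label" chatter
            mask = remove_small_objects(
                mask, min_size=min_object_area, connectivity=2
            )
    return (mask, threshold) if return_threshold else mask


def tissue_mask(img) -> np.ndarray:
    """Binary mask of the tissue section from the blue channel.

    The blue channel is thresholded with Otsu's method.  If the upper
    (blue-rich) class is near white (mean blue >= ``WHITE_BLUE_MIN``) it is
    taken as background and the lower class as tissue; otherwise no white
    background is present and the whole frame is tissue.  Holes (e.g.
    unstained lumina, DAB-only regions) are filled.

    Raises
    ------
    DegenerateHistogramError
        If the blue channel is constant (e.g. an all-white frame).
    """
    arr = _as_rgb(img)
    blue = arr[..., 2]
    if blue.min() == blue.max():
        raise DegenerateHistogramError(
            "degenerate histogram: constant blue channel"
        )
    t = threshold_otsu(np.asarray(blue, dtype=np.uint8))
    low = blue <= t
    high = ~low
    if high.any() and blue[high].mean() >= WHITE_BLUE_MIN:
        mask = low
    else:
        # No near-white class: the frame is fully covered by tissue.
        mask = np.ones(blue.shape, dtype=bool)
    return ndimage.binary_fill_holes(mask)


@dataclass(frozen=True)
class DensityResult:
    """Cell-density measurement for one section image.

    ``density = cell_area / tissue_area`` where ``cell_area`` counts only
    cell pixels inside the tissue mask.  ``threshold_used`` is the
    maximum-entropy level applied to the excess-red channel (``None`` for a
    blank section).
    """

    cell_area: int
    tissue_area: int
    density: float
    threshold_used: int | None = None


def cell_density(cells, tissue, threshold_used: int | None = None) -> DensityResult:
    """Cell density from a cell mask and a tissue mask of equal shape."""
    cells = np.asarray(cells).astype(bool)
    tissue = np.asarray(tissue).astype(bool)
    if cells.shape != tissue.shape:
        raise DataError(
            f"mask shapes differ: {cells.shape} vs {tissue.shape}"
        )
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        raise NoTissueError("no tissue detected: empty tissue mask")
    cell_area = int((cells & tissue).sum())
    return DensityResult(
        cell_area=cell_area,
        tissue_area=tissue_area,
        density=cell_area / tissue_area,
        threshold_used=threshold_used,
    )


def quantify_image(
    img,
    min_object_area: int = 20,
    opening_radius: int = 1,
    return_masks: bool = False,
):
    """Full per-image pipeline: tissue mask, cell mask, density."""
    tmask = tissue_mask(img)
    cmask, threshold = segment_cells(
        img,
        min_object_area=min_object_area,
        opening_radius=opening_radius,
        return_threshold=True,
    )
    result = cell_density(cmask, tmask, threshold_used=threshold)
    if return_masks:
        return result, cmask, tmask
    return result


class CellSegmenter(TransformerMixin, BaseEstimator):
    """Stateless transformer producing DAB+ cell masks from RGB images.

    Parameters
    ----------
    min_object_area : int
        Connected components (8-connectivity) smaller than this area in
        px^2 are removed after thresholding.
    opening_radius : int
        Radius of the disc structuring element for the morphological
        opening; 0 disables the opening.
    """

    def __init__(self, min_object_area: int = 20, opening_radius: int = 1):
        self.min_object_area = min_object_area
        self.opening_radius = opening_radius

    def fit(self, X=None, y=None):
        if self.min_object_area < 0:
            raise DataError("min_object_area must be >= 0")
        if self.opening_radius < 0:
            raise DataError("opening_radius must be >= 0")
        return self

    def transform(self, X):
        """Segment one image (H x W x 3) or a sequence of images."""
        self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 3:
            mask, t = segment_cells(
                X, self.min_object_area, self.opening_radius,
                return_threshold=True,
            )
            self.thresholds_ = [t]
            return mask
        masks, thresholds = [], []
        for img in X:
            mask, t = segment_cells(
                img, self.min_object_area, self.opening_radius,
                return_threshold=True,
            )
            masks.append(mask)
            thresholds.append(t)
        self.thresholds_ = thresholds
        return masks


class TissueSegmenter(TransformerMixin, BaseEstimator):
    """Stateless transformer producing tissue masks from RGB images."""

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return tissue_mask(X)
        return [tissue_mask(img) for img in X]
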