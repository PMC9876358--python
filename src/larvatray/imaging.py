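"""Image-processing chain: container photograph → per-region larval pixel counts.

The chain mirrors a standard manual workflow for photographs of dark larvae on
light water: crop to the water surface, invert so larvae are bright, quantise
to 8-bit, threshold, despeckle (3×3 median), delete small connected components
(food particles and debris), then count larval pixels inside each analysis
region.  Thresholding is automatic (Otsu's between-class-variance criterion)
with a manual override so that a human-chosen threshold can be reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, filters, morphology, util

from .geometry import REGION_LABELS, REGIONS


class ImagingError(ValueError):
    """Invalid input to an image-processing step."""


class DegenerateHistogramError(ImagingError):
    """Automatic thresholding on an image with a single grey level."""


def preprocess(image: np.ndarray, crop: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Crop, invert and quantise a photograph to 8-bit with bright larvae.

    Parameters
    ----------
    image :
        2-D grayscale or RGB array.  RGB is converted by luminance; 16-bit
        and float inputs are rescaled to 0–255 by their full dtype range.
    crop :
        ``(row0, col0, row1, col1)`` water-surface rectangle (half-open).

    Returns
    -------
    uint8 array in which larvae (dark in the original) are high-intensity.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = color.rgb2gray(img)  # float in [0, 1]
    elif img.ndim != 2:
        raise ImagingError("expected a 2-D grayscale or RGB image")
    if crop is not None:
        r0, c0, r1, c1 = crop
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ImagingError("empty or out-of-bounds crop rectangle")
        img = img[r0:r1, c0:c1]
    if img.dtype != np.uint8:
        img = util.img_as_ubyte(img)
    return (255 - img).astype(np.uint8)


def otsu_threshold(image: np.ndarray) -> float:
    """Between-class-variance-maximising threshold of an 8-bit image."""
    image = np.asarray(image)
    if image.min() == image.max():
        raise DegenerateHistogramError(
            "image has a single grey level; automatic thresholding is undefined"
        )
    return float(filters.threshold_otsu(image))


def threshold(
    image: np.ndarray,
    method: str = "otsu",
    manual_value: float | None = None,
) -> np.ndarray:
    """Binarise an 8-bit image: mask = pixels with value >= threshold.

    With ``manual_value`` given, that value is used verbatim (human parity
    with a hand-tuned threshold); otherwise Otsu's automatic threshold is
    computed from the histogram.
    """
    image = np.asarray(image)
    if manual_value is not None:
        t = float(manual_value)
    elif method == "otsu":
        # strictly-above keeps parity with skimage's img > t convention while
        # the mask contract is >=; Otsu's t lies between the modes so both
        # agree except exactly at t, which we put in the foreground.
        t = otsu_threshold(image)
    else:
        raise ImagingError(f"unknown threshold method {method!r}")
    return image >= t


def despeckle(grid: np.ndarray, passes: int = 1) -> np.ndarray:
    """3×3 median filter (the classic 'despeckle'), reflective padding.

    Accepts binary masks or grayscale images and preserves the input type.
    A single pass removes isolated pixels; it is idempotent on binary
    fixtures within at most one extra pass.
    """
    if grid.ndim != 2:
        raise ImagingError("despeckle expects a 2-D grid")
    out = grid
    for _ in range(passes):
        if out.dtype == bool:
            out = ndimage.median_filter(out.astype(np.uint8), size=3, mode="reflect") > 0
        else:
            out = ndimage.median_filter(out, size=3, mode="reflect")
    return out


def remove_small_objects(mask: np.ndarray, max_area_px: int) -> np.ndarray:
    """Delete 8-connected components with area <= ``max_area_px`` pixels.

    ``max_area_px = 0`` leaves the mask unchanged.  This is the automated
    surrogate for hand-painting food particles out of the image.
    """
    if mask.dtype != bool:
        raise ImagingError("remove_small_objects expects a boolean mask")
    if max_area_px < 0:
        raise ImagingError("max_area_px must be >= 0")
    if max_area_px == 0:
        return mask.copy()
    return morphology.remove_small_objects(mask, max_size=max_area_px, connectivity=2)


def area_fractions(mask: np.ndarray, region_label_mask: np.ndarray) -> pd.DataFrame:
    """Exact per-region larval and total pixel counts.

    Returns one row per region (edge, intermediate, central) plus a ``total``
    row summed over all region pixels (label > 0), with columns
    ``region, larval_px, total_px, coverage``.
    """
    mask = np.asarray(mask)
    labels = np.asarray(region_label_mask)
    if mask.shape != labels.shape:
        raise ImagingError("mask and region label mask shapes differ")
    rows = []
    for region in REGIONS:
        sel = labels == REGION_LABELS[region]
        total = int(sel.sum())
        larval = int(np.count_nonzero(mask & sel))
        rows.append((region, larval, total))
    in_any = labels > 0
    rows.append(("total", int(np.count_nonzero(mask & in_any)), int(in_any.sum())))
    df = pd.DataFrame(rows, columns=["region", "larval_px", "total_px"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df["coverage"] = df["larval_px"] / df["total_px"]
    return df


def process_image(
    image: np.ndarray,
    region_labels: np.ndarray,
    crop: tuple[int, int, int, int] | None = None,
    threshold_method: str = "otsu",
    manual_threshold: float | None = None,
    despeckle_passes: int = 1,
    max_particle_area_px: int = 12,
) -> tuple[pd.DataFrame, dict]:
    """Run the full chain on one photograph.

    Returns the per-region count table from :func:`area_fractions` and an
    info dict with the chosen threshold and the final mask (for QC output).
    """
    pre = preprocess(image, crop=crop)
    if manual_threshold is not None:
        t: float = float(manual_threshold)
    else:
        t = otsu_threshold(pre)
    mask = threshold(pre, method=threshold_method, manual_value=t)
    mask = despeckle(mask, passes=despeckle_passes)
    mask = remove_small_objects(mask, max_particle_area_px)
    counts = area_fractions(mask, region_labels)
    return counts, {"threshold": t, "mask": mask}
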