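"""Brightness thresholding, segment/soma separation, particle analysis.

The primary readout of the quantification chain is thresholded pixel
area.  Cone outer segments label at distinctly higher fluorescence
intensity than cell bodies, so the two compartments are separated by a
second, intensity-only split inside the all-cone mask; no attempt is
made to declump touching cells (area, not count, is the statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import regionprops_table

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class ConeMaskSet:
    """Disjoint compartment masks: segments + somata == all_cones."""

    all_cones: np.ndarray
    segments: np.ndarray
    somata: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        if self.segments.shape != self.all_cones.shape or (
            self.somata.shape != self.all_cones.shape
        ):
            raise ValueError("mask shapes differ")
        if np.any(self.segments & self.somata):
            raise ValueError("segments and somata masks overlap")
        if np.any((self.segments | self.somata) != self.all_cones):
            raise ValueError("segments + somata must partition all_cones")


def threshold_all_cones(
    raster: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Mask of pixels at or above the brightness threshold.

    ``method`` is ``"otsu"`` (automatic, reproducible stand-in for the
    operator-chosen brightness cut) or ``"fixed"`` with an explicit
    ``fixed_threshold``.  Returns (mask, metadata) with the threshold
    actually used recorded in the metadata.
    """
    img = np.asarray(raster)
    meta: dict = {"method": method}
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        t = float(fixed_threshold)
    elif method == "otsu":
        if img.max() == img.min():
            warnings.warn("blank raster; empty all-cone mask")
            meta["threshold"] = None
            meta["flag"] = "blank"
            return np.zeros(img.shape, dtype=bool), meta
        t = float(threshold_otsu(img))
        meta["threshold"] = t
        # skimage convention: foreground is strictly above the Otsu value
        # (matters for discrete images where the value itself is a level)
        return img > t, meta
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    meta["threshold"] = t
    return img >= t, meta


def split_segments_somata(
    raster: np.ndarray,
    all_cones: np.ndarray,
    min_mask_px: int = 64,
    min_separation: float = 1.6,
) -> ConeMaskSet:
    """Separate outer segments from somata by intensity inside the mask.

    A three-class Otsu split of the masked intensities assigns the top
    class (high-intensity, bundle-like outer segments) to ``segments``
    and the rest to ``somata`` — but only when the top class is a
    genuinely brighter population: segments label at a multiple of the
    soma intensity, so the median of the candidate segment tier must
    exceed ``min_separation`` times the median of the tier below it.
    Otherwise the field contains no segment tier (all segments have
    degenerated) and every cone pixel is a soma pixel.  Masks too small
    for a stable multi-level threshold are assigned entirely to somata
    and flagged.
    """
    img = np.asarray(raster)
    mask = np.asarray(all_cones, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape differs from raster")
    vals = img[mask].astype(float)
    meta: dict = {}
    empty = np.zeros(img.shape, dtype=bool)
    if vals.size < min_mask_px or np.unique(vals).size < 3:
        meta["flag"] = "mask too small or degenerate; all pixels -> somata"
        return ConeMaskSet(mask, empty, mask.copy(), meta)
    # log-domain split: fluorescence intensity tiers are roughly
    # log-normal, and the wide segment tier would otherwise dominate
    # the between-class variance and push the cut far above the valley
    t_low, t_high = np.exp(
        threshold_multiotsu(np.log(np.clip(vals, 1e-6, None)), classes=3)
    )
    meta["thresholds"] = (float(t_low), float(t_high))
    top = vals[vals >= t_high]
    middle = vals[(vals >= t_low) & (vals < t_high)]
    if top.size == 0 or middle.size == 0:
        meta["flag"] = "collapsed intensity class; all pixels -> somata"
        return ConeMaskSet(mask, empty, mask.copy(), meta)
    separation = float(np.median(top) / max(np.median(middle), 1e-12))
    meta["separation"] = separation
    if separation < min_separation:
        meta["flag"] = "no high-intensity segment tier; all pixels -> somata"
        return ConeMaskSet(mask, empty, mask.copy(), meta)
    segs = mask & (img >= t_high)
    return ConeMaskSet(mask, segs, mask & ~segs, meta)


def analyze_particles(
    mask: np.ndarray,
    min_area: float = 0.0,
    max_area: float = np.inf,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Connected-component particle measurement (8-connectivity).

    Returns one row per particle with area in px^2 and um^2, centroid in
    um, bounding box, eccentricity and perimeter, filtered to the
    ``[min_area, max_area]`` pixel-area window.
    """
    m = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(m, structure=_EIGHT_CONN)
    cols = ["label", "area", "centroid-0", "centroid-1", "bbox-0", "bbox-1",
            "bbox-2", "bbox-3", "eccentricity", "perimeter"]
    if n == 0:
        return pd.DataFrame(columns=[
            "label", "area_px2", "area_um2", "centroid_x_um", "centroid_y_um",
            "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
            "eccentricity", "perimeter_px",
        ])
    props = pd.DataFrame(regionprops_table(
        labels, properties=("label", "area", "centroid", "bbox",
                            "eccentricity", "perimeter")))
    props.columns = cols
    df = pd.DataFrame({
        "label": props["label"],
        "area_px2": props["area"].astype(float),
        "area_um2": props["area"].astype(float) * pixel_size_um**2,
        "centroid_x_um": props["centroid-1"] * pixel_size_um,
        "centroid_y_um": props["centroid-0"] * pixel_size_um,
        "bbox_min_row": props["bbox-0"],
        "bbox_min_col": props["bbox-1"],
        "bbox_max_row": props["bbox-2"],
        "bbox_max_col": props["bbox-3"],
        "eccentricity": props["eccentricity"],
        "perimeter_px": props["perimeter"],
    })
    keep = (df["area_px2"] >= min_area) & (df["area_px2"] <= max_area)
    return df[keep].reset_index(drop=True)


def mask_area(mask: np.ndarray, pixel_size_um: float = 1.0) -> tuple[int, float]:
    """Exact pixel count of a binary mask and its physical area in um^2."""
    px = int(np.count_nonzero(mask))
    return px, px * pixel_size_um**2


def labeled_mask(mask: np.ndarray) -> np.ndarray:
    """8-connected component labels of a binary mask (0 = background)."""
    labels, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=_EIGHT_CONN)
    return labels
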