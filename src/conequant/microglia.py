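"""Iba1/CD68 microglia quantification.

Counts Iba1+ cells by thresholding + particle analysis (the same
machinery as the cone masks), scores each cell CD68+ when a sufficient
fraction of its pixels exceed the CD68 threshold, and measures linear
density of Iba1+ cells along the ONL band of transverse sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from conequant.segmentation import analyze_particles, labeled_mask


@dataclass(frozen=True)
class MicrogliaConfig:
    """Counting parameters.

    cd68_colabel_fraction:
        A cell is CD68+ when at least this fraction of its pixels
        exceeds the CD68 threshold.
    min_area_px2 / max_area_px2:
        Particle size window for cell-scale objects.
    amoeboid_circularity:
        Circularity cutoff of the optional morphology flag.
    """

    cd68_colabel_fraction: float = 0.30
    min_area_px2: float = 20.0
    max_area_px2: float = 5000.0
    amoeboid_circularity: float = 0.6


@dataclass
class MicrogliaResult:
    """Counts and derived quantities for one scene."""

    n_iba1: int
    n_cd68: int
    geometry: str
    activated_fraction: Optional[float] = None
    linear_density_per_mm: Optional[float] = None
    metadata: dict | None = None

    def __post_init__(self) -> None:
        if self.n_cd68 > self.n_iba1:
            raise ValueError("n_cd68 cannot exceed n_iba1")


def robust_threshold(raster: np.ndarray, k_sigma: float = 6.0) -> float | None:
    """Otsu threshold floored at median + k * sigma (sigma via MAD).

    Returns ``None`` when the channel carries no signal above the robust
    background — a blank channel must yield zero detections rather than
    an Otsu cut through noise.
    """
    img = np.asarray(raster, dtype=float)
    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - med))
    floor = med + k_sigma * max(sigma, 1e-12)
    if img.max() <= floor:
        return None
    return max(float(threshold_otsu(img)), floor)


def count_microglia_wholemount(
    iba1: np.ndarray,
    cd68: np.ndarray,
    config: MicrogliaConfig | None = None,
    pixel_size_um: float = 1.0,
) -> MicrogliaResult:
    """Count Iba1+ cells and the CD68+ (activated) subset.

    Iba1 particles come from a robust threshold plus size-filtered
    connected components; each particle is scored against the CD68
    channel with the co-label fraction rule.
    """
    cfg = config or MicrogliaConfig()
    if iba1.shape != cd68.shape:
        raise ValueError("channel shapes differ")
    thr_iba1 = robust_threshold(iba1)
    meta: dict = {"iba1_threshold": thr_iba1}
    if thr_iba1 is None:
        warnings.warn("blank Iba1 channel; zero counts")
        meta["flag"] = "blank iba1 channel; activated fraction undefined"
        return MicrogliaResult(0, 0, "wholemount", None, None, meta)
    mask = iba1 >= thr_iba1
    particles = analyze_particles(mask, cfg.min_area_px2, cfg.max_area_px2,
                                  pixel_size_um)
    n_iba1 = len(particles)
    thr_cd68 = robust_threshold(cd68)
    meta["cd68_threshold"] = thr_cd68
    if n_iba1 == 0:
        meta["flag"] = "no iba1 particles; activated fraction undefined"
        return MicrogliaResult(0, 0, "wholemount", None, None, meta)
    n_cd68 = 0
    if thr_cd68 is not None:
        labels = labeled_mask(mask)
        cd68_hot = cd68 >= thr_cd68
        for lab in particles["label"]:
            cell = labels == lab
            frac = np.count_nonzero(cd68_hot & cell) / np.count_nonzero(cell)
            if frac >= cfg.cd68_colabel_fraction:
                n_cd68 += 1
    return MicrogliaResult(
        n_iba1, n_cd68, "wholemount", n_cd68 / n_iba1, None, meta
    )


def linear_density_transverse(
    iba1: np.ndarray,
    band_um: tuple[float, float],
    section_length_mm: float,
    config: MicrogliaConfig | None = None,
    pixel_size_um: float = 1.0,
) -> MicrogliaResult:
    """Iba1+ cells per mm whose centroid lies in the ONL band."""
    cfg = config or MicrogliaConfig()
    if section_length_mm <= 0:
        raise ValueError("section length must be positive")
    thr = robust_threshold(iba1)
    meta: dict = {"iba1_threshold": thr, "band_um": band_um}
    if thr is None:
        warnings.warn("blank Iba1 channel; zero counts")
        return MicrogliaResult(0, 0, "transverse", None, 0.0, meta)
    particles = analyze_particles(iba1 >= thr, cfg.min_area_px2,
                                  cfg.max_area_px2, pixel_size_um)
    y = particles["centroid_y_um"]
    in_band = (y >= band_um[0]) & (y < band_um[1])
    n = int(in_band.sum())
    return MicrogliaResult(
        n, 0, "transverse", None, n / section_length_mm, meta
    )


def morphology_index(particle: pd.Series | dict) -> float:
    """Circularity 4*pi*area / perimeter^2, clipped to [0, 1].

    ~1 for compact amoeboid cells, -> 0 for thin ramified shapes; a
    degenerate zero perimeter scores 1 (a single pixel is compact).
    """
    area = float(particle["area_px2"])
    perim = float(particle["perimeter_px"])
    if perim <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perim**2))
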