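"""Hue-window cone-type classification on merged two-channel images.

The S-opsin channel is mapped to red and the M/L-opsin channel to green;
in the merged RGB image genuine S-cones appear red, genuine M/L-cones
green and dual cones (expressing both opsins) yellow.  Every pixel of
the all-cone mask is assigned to exactly one hue window (on the 0-255
hue wheel, as in ImageJ colour thresholding) or left unclassified;
composition fractions are computed over the classified cone area, with
the unclassified remainder reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from conequant.preprocess import (
    PreprocessConfig,
    background_mode,
    clean_and_quantize,
    flatten_illumination,
    match_channel_intensity,
    stretch_bounds,
)
from conequant.render import FieldImage
from conequant.segmentation import split_segments_somata, threshold_all_cones

CLASSES = ("S", "dual", "ML")


@dataclass(frozen=True)
class HueWindows:
    """Hue intervals (inclusive, 0-255 wheel) for red / yellow / green.

    Defaults put the pure-red (hue 0), balanced-yellow (hue 42) and
    pure-green (hue 85) points mid-window.  Red wraps around the wheel.
    Saturation and brightness are kept at full range; brightness
    selection happens earlier, in the all-cone threshold.
    """

    red: tuple[tuple[int, int], ...] = ((0, 21), (234, 255))
    yellow: tuple[tuple[int, int], ...] = ((22, 63),)
    green: tuple[tuple[int, int], ...] = ((64, 160),)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name in ("red", "yellow", "green"):
            for lo, hi in getattr(self, name):
                if not (0 <= lo <= hi <= 255):
                    raise ValueError(f"{name} interval ({lo},{hi}) out of range")
                vals = set(range(lo, hi + 1))
                if vals & seen:
                    raise ValueError("hue windows overlap")
                seen |= vals

    def _contains(self, hue: np.ndarray, name: str) -> np.ndarray:
        out = np.zeros(hue.shape, dtype=bool)
        for lo, hi in getattr(self, name):
            out |= (hue >= lo) & (hue <= hi)
        return out


@dataclass
class CompositionResult:
    """Cone-type areas and fractions for one field.

    ``areas`` maps S / dual / ML / unclassified to pixel areas; the
    fractions are over the classified area only and sum to 1 (they are
    ``None`` when no pixel classified).
    """

    areas: dict[str, int]
    fractions: dict[str, float] | None
    metadata: dict = dc_field(default_factory=dict)

    @property
    def classified_area(self) -> int:
        return self.areas["S"] + self.areas["dual"] + self.areas["ML"]


def merge_channels(s_raster: np.ndarray, ml_raster: np.ndarray) -> np.ndarray:
    """Merge opsin channels into RGB: R = S-opsin, G = M/L-opsin, B = 0."""
    s = np.asarray(s_raster)
    ml = np.asarray(ml_raster)
    if s.shape != ml.shape:
        raise ValueError("channel shapes differ")
    if s.dtype != np.uint8 or ml.dtype != np.uint8:
        raise ValueError("merge expects 8-bit channels")
    rgb = np.zeros(s.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = s
    rgb[..., 1] = ml
    return rgb


def hue_wheel(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel hue on the 0-255 wheel (standard RGB->HSB conversion).

    Zero-intensity pixels (max channel 0) get hue 0.  The arithmetic
    mirrors the textbook piecewise formula so that scalar re-computation
    per pixel reproduces it exactly.
    """
    r = rgb[..., 0].astype(float)
    g = rgb[..., 1].astype(float)
    b = rgb[..., 2].astype(float)
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    safe = np.where(delta == 0, 1.0, delta)
    rc = (maxc - r) / safe
    gc = (maxc - g) / safe
    bc = (maxc - b) / safe
    h = np.where(
        r == maxc, bc - gc, np.where(g == maxc, 2.0 + rc - bc, 4.0 + gc - rc)
    )
    h = np.where(delta == 0, 0.0, (h / 6.0) % 1.0)
    return h * 255.0


def hue_partition(
    rgb: np.ndarray,
    all_cones: np.ndarray,
    windows: HueWindows | None = None,
    metadata: dict | None = None,
) -> tuple[dict[str, np.ndarray], CompositionResult]:
    """Assign each masked pixel to one hue window; report composition.

    Hue is rounded to the nearest integer on the 0-255 wheel before
    window membership is tested (windows are integer intervals).  Class
    masks are pairwise disjoint and together with the unclassified mask
    tile the all-cone mask exactly.
    """
    windows = windows or HueWindows()
    mask = np.asarray(all_cones, dtype=bool)
    hue = np.round(hue_wheel(rgb))
    masks = {
        "S": mask & windows._contains(hue, "red"),
        "dual": mask & windows._contains(hue, "yellow"),
        "ML": mask & windows._contains(hue, "green"),
    }
    masks["unclassified"] = (
        mask & ~(masks["S"] | masks["dual"] | masks["ML"])
    )
    areas = {k: int(np.count_nonzero(v)) for k, v in masks.items()}
    classified = areas["S"] + areas["dual"] + areas["ML"]
    meta = dict(metadata or {})
    meta["hue_windows"] = windows
    if classified == 0:
        warnings.warn("no classified cone pixels; fractions undefined")
        meta["flag"] = "empty classified area"
        fractions = None
    else:
        fractions = {k: areas[k] / classified for k in CLASSES}
    return masks, CompositionResult(areas, fractions, meta)


def composition_of_field(
    field: FieldImage,
    preprocess: PreprocessConfig | None = None,
    windows: HueWindows | None = None,
    compartment: str = "all",
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> CompositionResult:
    """End-to-end cone-type composition of one two-channel field.

    Chain: per-channel flat-fielding -> channel intensity matching ->
    median filter + contrast stretch with limits pooled over both
    channels (so quantization preserves the red/green balance and hence
    hue) -> brightness thresholding on the per-pixel channel maximum ->
    optional restriction to the outer-segment compartment -> RGB merge
    -> hue partition.

    ``compartment`` is ``"all"`` (whole cones; used at ages where opsin
    has redistributed to surviving cell bodies) or ``"segments"``
    (outer segments only; used at ages where segments dominate).
    """
    cfg = preprocess or PreprocessConfig()
    s = flatten_illumination(field.channel_s, cfg)
    ml = flatten_illumination(field.channel_ml, cfg)
    s, ml, match_info = match_channel_intensity(s, ml, cfg.match_percentile)
    # black point at the common background mode (so unlabeled pixels map
    # to ~0 in each channel and hue is undistorted); white point pooled
    # over both channels so quantization preserves the red/green balance
    _, hi = stretch_bounds([s, ml], cfg)
    bounds = (background_mode([s, ml]), hi)
    s8 = clean_and_quantize(s, cfg, bounds)
    ml8 = clean_and_quantize(ml, cfg, bounds)
    brightness = np.maximum(s8, ml8)
    mask, thr_meta = threshold_all_cones(
        brightness, threshold_method, fixed_threshold
    )
    if compartment == "segments":
        # the split sees an unfiltered raster: a median filter erases the
        # narrow bundle-like segments it is meant to isolate
        import dataclasses

        cfg_nofilter = dataclasses.replace(cfg, noise_filter_radius=0)
        bright_sharp = np.maximum(
            clean_and_quantize(s, cfg_nofilter, bounds),
            clean_and_quantize(ml, cfg_nofilter, bounds),
        )
        mask_set = split_segments_somata(bright_sharp, mask)
        mask = mask_set.segments
    elif compartment != "all":
        raise ValueError(f"unknown compartment {compartment!r}")
    rgb = merge_channels(s8, ml8)
    meta = {
        "field": dict(field.metadata),
        "compartment": compartment,
        "threshold": thr_meta,
        "channel_match": match_info,
        "stretch_bounds": bounds,
    }
    _, result = hue_partition(rgb, mask, windows, meta)
    return result
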