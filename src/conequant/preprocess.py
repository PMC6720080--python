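"""Image conditioning: flat-fielding, channel matching, denoise, 8-bit.

The chain mirrors routine fluorescence wholemount pre-processing:
retrospective flat-field correction of uneven illumination, rescaling of
the two channels to comparable labeling intensity, small-radius median
filtering against noise/dust, percentile contrast stretch, and
quantization to 8-bit.  Order is fixed:
flatten -> match -> median -> levels -> quantize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the conditioning chain.

    flatten_kernel_scale:
        Low-pass kernel extent as a fraction of the image diagonal
        (Gaussian sigma = kernel / 4).
    noise_filter_radius:
        Median filter radius in pixels (0 disables).
    level_percentiles:
        (low, high) percentiles mapped to 0 and 255 by the contrast
        stretch.
    match_percentile:
        Robust upper percentile equalized between channels.
    sharpen:
        Optional unsharp masking before the median filter; off by default
        because sharpening ahead of thresholding changes measured areas.
    """

    flatten_kernel_scale: float = 0.25
    flatten_method: str = "poly"
    noise_filter_radius: int = 1
    level_percentiles: tuple[float, float] = (0.5, 99.5)
    quantize_bits: int = 8
    match_percentile: float = 99.0
    sharpen: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.level_percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("level percentiles must satisfy 0 < low < high < 100")
        if not 0 < self.flatten_kernel_scale <= 1:
            raise ValueError("flatten_kernel_scale must be in (0, 1]")
        if self.flatten_method not in ("poly", "gaussian"):
            raise ValueError("flatten_method must be poly or gaussian")
        if self.quantize_bits != 8:
            raise ValueError("only 8-bit quantization is supported")


def _poly_background(raster: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Degree-2 polynomial surface fitted to the unlabeled background.

    Iterative sigma-clipping removes bright (labeled) pixels from the
    fit so the surface tracks the illumination of the background rather
    than the average cell signal.  Fitted on a 4x-downsampled copy.
    """
    ds = 4
    small = raster[::ds, ::ds]
    h, w = small.shape
    y, x = np.mgrid[0:h, 0:w]
    xn = x.ravel() / max(w - 1, 1) - 0.5
    yn = y.ravel() / max(h - 1, 1) - 0.5
    design = np.column_stack(
        [np.ones_like(xn), xn, yn, xn * yn, xn**2, yn**2]
    )
    vals = small.ravel()
    keep = np.ones(vals.size, dtype=bool)
    coef = None
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(design[keep], vals[keep], rcond=None)
        resid = vals - design @ coef
        neg = resid[resid < 0]
        sigma = np.sqrt(np.mean(neg**2)) if neg.size else resid.std()
        new_keep = resid < 2.5 * max(sigma, 1e-12)
        if new_keep.sum() < 6 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    hf, wf = raster.shape
    yf, xf = np.mgrid[0:hf, 0:wf]
    xfn = xf.ravel() / max(wf - 1, 1) - 0.5
    yfn = yf.ravel() / max(hf - 1, 1) - 0.5
    full = np.column_stack(
        [np.ones_like(xfn), xfn, yfn, xfn * yfn, xfn**2, yfn**2]
    )
    return (full @ coef).reshape(raster.shape)


def _gaussian_background(
    raster: np.ndarray, kernel_scale: float
) -> np.ndarray:
    diag = float(np.hypot(*raster.shape))
    sigma = kernel_scale * diag / 4.0
    ds = 4
    small = resize(raster, (max(raster.shape[0] // ds, 8),
                            max(raster.shape[1] // ds, 8)),
                   order=1, anti_aliasing=False, preserve_range=True)
    bg_small = ndimage.gaussian_filter(small, sigma / ds, mode="nearest")
    return resize(bg_small, raster.shape, order=1, preserve_range=True)


def flatten_illumination(
    raster: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Divide out a smooth illumination estimate, preserving the mean.

    The default background model is a degree-2 polynomial surface —
    exact for the linear/quadratic gradients typical of slide
    illumination and free of the edge bias of windowed filters; a heavy
    Gaussian low-pass (``flatten_method="gaussian"``, kernel 25% of the
    diagonal) is available for backgrounds with more structure.  The
    result is rescaled to the input mean, so a constant raster is
    returned unchanged.
    """
    config = config or PreprocessConfig()
    raster = np.asarray(raster, dtype=float)
    if np.any(raster < 0):
        raise ValueError("raster must be non-negative")
    mean_in = raster.mean()
    if mean_in <= 0:
        warnings.warn("all-zero raster; flat-fielding skipped")
        return raster.copy()
    if config.flatten_method == "poly":
        bg = _poly_background(raster)
    else:
        bg = _gaussian_background(raster, config.flatten_kernel_scale)
    bg = np.clip(bg, 1e-9 * mean_in + 1e-30, None)
    out = raster / bg
    out *= mean_in / out.mean()
    return np.clip(out, 0.0, None)


def _labeling_intensity(img: np.ndarray) -> float | None:
    """Median per-cell peak intensity of one channel.

    Cells are 8-connected components above a robust threshold (Otsu,
    floored at median + 6 sigma so a noise-only channel yields nothing).
    Returns ``None`` when the channel carries no credible label — it
    must then not be rescaled into the noise.
    """
    from skimage.filters import threshold_otsu
    from scipy.ndimage import label, labeled_comprehension

    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - med))
    floor = med + 6.0 * max(sigma, 1e-12)
    if img.max() <= floor:
        return None
    thr = max(float(threshold_otsu(img)), floor)
    mask = img >= thr
    labels, n = label(mask, structure=np.ones((3, 3), dtype=int))
    if n < 3:
        return None
    peaks = labeled_comprehension(
        img, labels, np.arange(1, n + 1), np.max, float, np.nan
    )
    sizes = np.bincount(labels.ravel())[1:]
    peaks = peaks[sizes >= 4]  # ignore speckle
    if peaks.size < 3:
        return None
    return float(np.median(peaks))


def match_channel_intensity(
    raster_a: np.ndarray,
    raster_b: np.ndarray,
    percentile: float = 99.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rescale the dimmer channel to approximately equal labeling intensity.

    The matching statistic is the median per-cell peak brightness
    (:func:`_labeling_intensity`), which tracks how strongly individual
    cells label and is insensitive to how *many* cells each channel
    contains — a global percentile is not, and would over-amplify the
    scarcer label.  A channel with no credible signal (e.g. the M/L-opsin
    channel in a quadrant where that cone type has vanished) is left
    untouched and flagged.
    """
    a = np.asarray(raster_a, dtype=float)
    b = np.asarray(raster_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    la, lb = _labeling_intensity(a), _labeling_intensity(b)
    info = {
        "scaled": None,
        "factor": 1.0,
        "intensity_a": la,
        "intensity_b": lb,
        "percentile_a": float(np.percentile(a, percentile)),
        "percentile_b": float(np.percentile(b, percentile)),
    }
    if la is None or lb is None or min(la, lb) <= 0:
        info["scaled"] = "skipped"
        return a.copy(), b.copy(), info
    if la >= lb:
        info.update(scaled="b", factor=float(la / lb))
        return a.copy(), b * (la / lb), info
    info.update(scaled="a", factor=float(lb / la))
    return a * (lb / la), b.copy(), info


def clean_and_quantize(
    raster: np.ndarray,
    config: PreprocessConfig | None = None,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Median filter, percentile contrast stretch, quantize to uint8.

    ``bounds`` overrides the stretch limits (e.g. limits pooled across
    both channels of a field so that the red/green balance — and hence
    pixel hue — is preserved by quantization).
    """
    config = config or PreprocessConfig()
    img = np.asarray(raster, dtype=float)
    if np.any(img < 0):
        raise ValueError("raster must be non-negative")
    if config.sharpen:
        blur = ndimage.gaussian_filter(img, 1.0)
        img = np.clip(img + 0.5 * (img - blur), 0.0, None)
    r = config.noise_filter_radius
    if r > 0:
        img = ndimage.median_filter(img, size=2 * r + 1)
    if bounds is None:
        lo, hi = np.percentile(img, config.level_percentiles)
    else:
        lo, hi = bounds
    if hi <= lo:
        warnings.warn("degenerate contrast range; returning flat mid-gray")
        return np.full(img.shape, 128, dtype=np.uint8)
    out = (img - lo) / (hi - lo) * 255.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def stretch_bounds(
    rasters: list[np.ndarray], config: PreprocessConfig | None = None
) -> tuple[float, float]:
    """Shared contrast-stretch limits pooled over several rasters."""
    config = config or PreprocessConfig()
    pooled = np.concatenate([np.ravel(r) for r in rasters])
    lo, hi = np.percentile(pooled, config.level_percentiles)
    return float(lo), float(hi)


def background_mode(rasters: list[np.ndarray], n_bins: int = 64) -> float:
    """Histogram-mode estimate of the common background level.

    In fluorescence fields the unlabeled background forms the tallest
    histogram peak; its level is the natural black point for the
    contrast stretch, so that a pixel carrying no label in one channel
    maps to ~0 there and pure-colour pixels keep extreme hues after the
    RGB merge.
    """
    pooled = np.concatenate([np.ravel(r) for r in rasters])
    hi = np.percentile(pooled, 99.9)
    hist, edges = np.histogram(pooled, bins=n_bins, range=(0.0, max(hi, 1e-9)))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))
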