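"""Render synthetic two-channel opsin immunofluorescence fields.

The intensity model mirrors the appearance of opsin-labeled cones in
wholemounts: cell bodies are wide ovoid blobs of moderate intensity,
outer segments are narrow bundle-like blobs labeling at a multiple of
the soma intensity.  Each channel receives its own smooth multiplicative
illumination field (the two channels are separate exposures) plus
additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from conequant.mosaic import ConeGroundTruth, SEGMENT_AXES_UM
from conequant.presets import GeneratorPreset, DEFAULT_PIXEL_SIZE_UM

#: constant background level, 8-bit scale
BACKGROUND = 10.0
#: peak soma intensity on the 8-bit scale
SOMA_PEAK = 90.0
#: outer segments label at this multiple of the soma amplitude
SEGMENT_AMP_FACTOR = 2.5
#: blob sigma as a fraction of the stated ellipse axis
_AXIS_TO_SIGMA = 0.25


@dataclass
class FieldImage:
    """One two-channel fluorescence field with physical metadata.

    ``channel_s`` carries the S-opsin (red) label, ``channel_ml`` the
    M/L-opsin (green) label; both are non-negative float rasters of the
    same shape.  ``truth`` optionally holds generator side products
    (noiseless composites, per-compartment intensity, illumination
    fields) for validation against ground truth.
    """

    channel_s: np.ndarray
    channel_ml: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    metadata: dict = dc_field(default_factory=dict)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.channel_ml is not None and (
            self.channel_s.shape != self.channel_ml.shape
        ):
            raise ValueError("channel shapes differ")
        if np.any(self.channel_s < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channel_s.shape

    @property
    def size_um(self) -> tuple[float, float]:
        """(width, height) in micrometres."""
        h, w = self.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


def _add_blob(
    img: np.ndarray,
    x: float,
    y: float,
    sigma_major: float,
    sigma_minor: float,
    theta: float,
    amplitude: float,
) -> None:
    """Add one rotated anisotropic Gaussian blob in place (pixel units)."""
    r = int(np.ceil(3.5 * sigma_major))
    h, w = img.shape
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    xx, yy = np.meshgrid(xs, ys)
    c, s = np.cos(theta), np.sin(theta)
    u = c * xx + s * yy
    v = -s * xx + c * yy
    g = np.exp(-0.5 * ((u / sigma_major) ** 2 + (v / sigma_minor) ** 2))
    img[y0c:y1c, x0c:x1c] += amplitude * g


def polynomial_illumination(
    shape: tuple[int, int],
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth multiplicative illumination field, mean ~1.

    A random quadratic in normalized coordinates, rescaled so the maximum
    relative deviation from 1 equals ``amplitude``.
    """
    if amplitude <= 0:
        return np.ones(shape)
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    xn = 2.0 * x / max(w - 1, 1) - 1.0
    yn = 2.0 * y / max(h - 1, 1) - 1.0
    coeffs = rng.uniform(-1.0, 1.0, 5)
    f = (
        coeffs[0] * xn
        + coeffs[1] * yn
        + coeffs[2] * xn * yn
        + coeffs[3] * xn**2
        + coeffs[4] * yn**2
    )
    f -= f.mean()
    peak = np.max(np.abs(f))
    if peak < 1e-12:
        return np.ones(shape)
    return 1.0 + amplitude * f / peak


def render_field(
    ground_truth: ConeGroundTruth,
    preset: GeneratorPreset,
    rng: np.random.Generator,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    keep_truth: bool = True,
) -> FieldImage:
    """Render a cone mosaic into a two-channel field image.

    Somata are rendered as ovoid Gaussian blobs at the per-cone channel
    amplitudes; surviving outer segments as compact elongated blobs at
    ``SEGMENT_AMP_FACTOR`` times the soma amplitude, slightly offset from
    the soma centre.  Illumination and noise come from the preset; output
    is clipped at zero (values may exceed 255 before quantization).
    """
    width, height = preset.field_um
    shape = (int(round(height / pixel_size_um)), int(round(width / pixel_size_um)))
    clean = {
        "s": np.full(shape, BACKGROUND, dtype=float),
        "ml": np.full(shape, BACKGROUND, dtype=float),
    }
    soma_int = np.zeros(shape)
    seg_int = np.zeros(shape)

    df = ground_truth.cones
    seg_sig = (
        SEGMENT_AXES_UM[0] * _AXIS_TO_SIGMA / pixel_size_um,
        SEGMENT_AXES_UM[1] * _AXIS_TO_SIGMA / pixel_size_um,
    )
    n = len(df)
    seg_dir = rng.uniform(0.0, 2 * np.pi, n)
    seg_theta = rng.uniform(0.0, np.pi, n)
    for i, cone in enumerate(df.itertuples(index=False)):
        x = cone.x_um / pixel_size_um
        y = cone.y_um / pixel_size_um
        sig_maj = cone.soma_major_um * _AXIS_TO_SIGMA / pixel_size_um
        sig_min = cone.soma_minor_um * _AXIS_TO_SIGMA / pixel_size_um
        for ch, amp in (("s", cone.amp_s), ("ml", cone.amp_ml)):
            if amp <= 0:
                continue
            _add_blob(clean[ch], x, y, sig_maj, sig_min, cone.orientation, amp)
        _add_blob(soma_int, x, y, sig_maj, sig_min, cone.orientation,
                  max(cone.amp_s, cone.amp_ml))
        if cone.has_segment:
            # en face the segment projects over its own soma; a small
            # jitter keeps it off-centre without breaching the exclusion
            # zone of neighbouring cones
            sx = x + 1.0 * np.cos(seg_dir[i]) / pixel_size_um
            sy = y + 1.0 * np.sin(seg_dir[i]) / pixel_size_um
            for ch, amp in (("s", cone.amp_s), ("ml", cone.amp_ml)):
                if amp <= 0:
                    continue
                _add_blob(clean[ch], sx, sy, seg_sig[0], seg_sig[1],
                          seg_theta[i], SEGMENT_AMP_FACTOR * amp)
            _add_blob(seg_int, sx, sy, seg_sig[0], seg_sig[1], seg_theta[i],
                      SEGMENT_AMP_FACTOR * max(cone.amp_s, cone.amp_ml))

    illum = {
        ch: polynomial_illumination(shape, preset.illumination_amplitude, rng)
        for ch in ("s", "ml")
    }
    out = {}
    for ch in ("s", "ml"):
        img = clean[ch] * illum[ch]
        if preset.noise_sd > 0:
            img = img + rng.normal(0.0, preset.noise_sd, shape)
        out[ch] = np.clip(img, 0.0, None)

    truth = None
    if keep_truth:
        truth = {
            "clean_s": clean["s"],
            "clean_ml": clean["ml"],
            "soma_intensity": soma_int,
            "segment_intensity": seg_int,
            "illumination_s": illum["s"],
            "illumination_ml": illum["ml"],
            "ground_truth": ground_truth,
        }
    meta = {
        "preset": preset.label,
        "timepoint": preset.timepoint,
        "quadrant": preset.quadrant,
        "eccentricity": preset.eccentricity,
        "n_cones": n,
    }
    return FieldImage(out["s"], out["ml"], pixel_size_um, meta, truth)


def truth_masks(
    field: FieldImage, margin: float = 20.0
) -> dict[str, np.ndarray]:
    """Ground-truth pixel masks derived from generator side products.

    A pixel is above background when the noiseless composite exceeds
    ``BACKGROUND + margin`` in either channel; it is a segment pixel when
    the segment contribution additionally dominates the soma contribution.
    """
    if field.truth is None:
        raise ValueError("field was rendered without ground-truth side products")
    t = field.truth
    above = np.maximum(t["clean_s"], t["clean_ml"]) > BACKGROUND + margin
    segments = above & (t["segment_intensity"] > t["soma_intensity"])
    return {"above_background": above, "segments": segments,
            "somata": above & ~segments}
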