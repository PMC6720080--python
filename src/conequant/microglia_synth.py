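"""Synthetic Iba1/CD68 microglia scenes.

Wholemount scenes contain a Poisson number of Iba1+ cells, a preset
fraction of which are *activated*: compact amoeboid somata that co-label
for the phagocytic marker CD68.  The remainder are quiescent ramified
cells — a dimmer soma with several thin processes and no CD68 signal.
Transverse-section strips place amoeboid cells along an ONL band at a
preset linear density (cells/mm), with a sprinkling of ramified inner-
retina cells outside the band.

Channel convention matches the wholemount figures: CD68 occupies the
first (red) channel slot, Iba1 the second (green) slot of
:class:`~conequant.render.FieldImage`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import line

from conequant.mosaic import hardcore_points
from conequant.presets import GeneratorPreset, DEFAULT_PIXEL_SIZE_UM
from conequant.render import BACKGROUND, FieldImage, _add_blob, polynomial_illumination

#: minimum centre-to-centre microglia spacing, micrometres
MICROGLIA_SPACING_UM = 18.0
IBA1_AMOEBOID_PEAK = 180.0
IBA1_RAMIFIED_PEAK = 140.0
CD68_PEAK = 160.0
PROCESS_INTENSITY = 45.0

#: transverse strip geometry: height of the strip and the ONL band, um
TRANSVERSE_STRIP_HEIGHT_UM = 200.0
ONL_BAND_UM = (50.0, 150.0)


def _draw_ramified(
    iba1: np.ndarray, x: float, y: float, rng: np.random.Generator
) -> None:
    """Soma plus 3-6 thin radial processes, all connected to the soma."""
    _add_blob(iba1, x, y, 2.5, 2.0, rng.uniform(0, np.pi), IBA1_RAMIFIED_PEAK)
    h, w = iba1.shape
    for _ in range(rng.integers(3, 7)):
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(12, 25)
        x1 = int(np.clip(x + length * np.cos(ang), 0, w - 1))
        y1 = int(np.clip(y + length * np.sin(ang), 0, h - 1))
        rr, cc = line(int(np.clip(y, 0, h - 1)), int(np.clip(x, 0, w - 1)), y1, x1)
        iba1[rr, cc] += PROCESS_INTENSITY


def _draw_amoeboid(
    iba1: np.ndarray,
    cd68: np.ndarray,
    x: float,
    y: float,
    rng: np.random.Generator,
) -> None:
    theta = rng.uniform(0, np.pi)
    _add_blob(iba1, x, y, 3.5, 3.0, theta, IBA1_AMOEBOID_PEAK)
    _add_blob(cd68, x, y, 3.0, 2.6, theta, CD68_PEAK)


def make_microglia_scene(
    preset: GeneratorPreset,
    rng: np.random.Generator,
    geometry: str = "wholemount",
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[FieldImage, pd.DataFrame]:
    """Render one microglia scene and its per-cell ground truth.

    Returns ``(field, cells)`` where ``cells`` has one row per cell:
    ``x_um, y_um, activated, in_band``.  The field's first channel is
    CD68, the second Iba1; transverse band bounds and strip length are
    recorded in the field metadata.
    """
    if preset.microglia is None:
        raise ValueError(f"preset {preset.label} carries no microglia parameters")
    density, activated_fraction = preset.microglia
    if geometry == "wholemount":
        width, height = preset.field_um
        mean_n = density * width * height / 1e6
    elif geometry == "transverse":
        width, height = preset.field_um[0], TRANSVERSE_STRIP_HEIGHT_UM
        mean_n = density * width / 1000.0
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    shape = (int(round(height / pixel_size_um)), int(round(width / pixel_size_um)))
    iba1 = np.full(shape, BACKGROUND)
    cd68 = np.full(shape, BACKGROUND)

    n = int(rng.poisson(mean_n)) if mean_n > 0 else 0
    band = None
    if geometry == "wholemount":
        pts = hardcore_points(n, width, height, MICROGLIA_SPACING_UM, rng)
        in_band = np.ones(n, dtype=bool)
        activated = rng.random(n) < activated_fraction
    else:
        band = ONL_BAND_UM
        band_h = band[1] - band[0]
        pts = hardcore_points(n, width, band_h, MICROGLIA_SPACING_UM, rng)
        pts[:, 1] += band[0]
        # quiescent inner-retina cells below the band, outside the count
        n_extra = int(rng.poisson(0.2 * mean_n))
        lower = TRANSVERSE_STRIP_HEIGHT_UM - band[1]
        extra = hardcore_points(n_extra, width, lower - 5.0, MICROGLIA_SPACING_UM, rng)
        extra[:, 1] += band[1] + 5.0
        in_band = np.concatenate([np.ones(n, bool), np.zeros(n_extra, bool)])
        activated = np.concatenate(
            [rng.random(n) < activated_fraction, np.zeros(n_extra, bool)]
        )
        pts = np.vstack([pts, extra]) if n_extra else pts

    for (x_um, y_um), act in zip(pts, activated):
        x, y = x_um / pixel_size_um, y_um / pixel_size_um
        if act:
            _draw_amoeboid(iba1, cd68, x, y, rng)
        else:
            _draw_ramified(iba1, x, y, rng)

    for img in (iba1, cd68):
        img *= polynomial_illumination(shape, preset.illumination_amplitude, rng)
        if preset.noise_sd > 0:
            img += rng.normal(0.0, preset.noise_sd, shape)
        np.clip(img, 0.0, None, out=img)

    meta = {
        "preset": preset.label,
        "geometry": geometry,
        "timepoint": preset.timepoint,
        "n_cells": int(len(pts)),
        "strip_length_mm": width / 1000.0,
        "band_um": band,
    }
    cells = pd.DataFrame(
        {
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "activated": activated,
            "in_band": in_band,
        }
    )
    field = FieldImage(cd68, iba1, pixel_size_um, meta)
    return field, cells
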