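"""Quantification toolkit for cone photoreceptor and microglia degeneration.

The package models the analysis chain used to characterise secondary cone
degeneration in the Rd1 (*Pde6b*^rd1) mouse retina from two-channel opsin
immunofluorescence wholemounts:

* a seeded synthetic-retina generator whose presets encode measured
  cone-type compositions, survival fractions, microglia densities and
  qPCR expression levels as ground truth (:mod:`conequant.presets`,
  :mod:`conequant.mosaic`, :mod:`conequant.render`,
  :mod:`conequant.microglia_synth`, :mod:`conequant.qpcr_synth`);
* image conditioning — flat-field correction, channel intensity matching,
  denoising, contrast stretch and 8-bit quantization
  (:mod:`conequant.preprocess`);
* mask-based quantification — brightness thresholding, outer-segment /
  soma separation, particle analysis (:mod:`conequant.segmentation`);
* hue-window cone-type classification on merged red/green images
  (:mod:`conequant.cone_typing`);
* spatio-temporal survival aggregation (:mod:`conequant.spatiotemporal`);
* Iba1/CD68 microglia counting (:mod:`conequant.microglia`);
* efficiency-corrected comparative-Ct relative quantification
  (:mod:`conequant.qpcr`).
"""

from conequant.presets import make_preset, list_presets, GeneratorPreset
from conequant.mosaic import sample_cone_mosaic, ConeGroundTruth
from conequant.render import render_field, FieldImage

__version__ = "0.1.0"


def composition_of_field(*args, **kwargs):
    """Lazy alias for :func:`conequant.cone_typing.composition_of_field`."""
    from conequant.cone_typing import composition_of_field as _impl

    return _impl(*args, **kwargs)

__all__ = [
    "make_preset",
    "list_presets",
    "GeneratorPreset",
    "sample_cone_mosaic",
    "ConeGroundTruth",
    "render_field",
    "FieldImage",
    "composition_of_field",
    "__version__",
]
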