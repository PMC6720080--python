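"""Reading and writing fields, ground truth and results.

Rasters travel as 1- or 2-page grayscale TIFF (page 1 = S-opsin or CD68
channel, page 2 = M/L-opsin or Iba1 channel) with an optional JSON
sidecar (same stem, ``.json``) carrying pixel size and field metadata.
Tabular results are long-format CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from conequant.presets import DEFAULT_PIXEL_SIZE_UM
from conequant.render import FieldImage


class FieldFormatError(ValueError):
    """Unusable raster file, with a remedy hint in the message."""


def write_field(field: FieldImage, path: str | Path) -> Path:
    """Write a field as a 2-page grayscale TIFF plus JSON sidecar.

    Intensities are rounded to uint16 (the generator's 8-bit-scale
    values fit comfortably); the sidecar records pixel size, channel
    order and field metadata.
    """
    path = Path(path)
    pages = [np.round(field.channel_s).astype(np.uint16)]
    if field.channel_ml is not None:
        pages.append(np.round(field.channel_ml).astype(np.uint16))
    tifffile.imwrite(path, np.stack(pages))
    sidecar = {
        "pixel_size_um": field.pixel_size_um,
        "channel_order": ["S/CD68", "ML/Iba1"][: len(pages)],
        "metadata": _jsonable(field.metadata),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_field(
    path: str | Path,
    pixel_size_um: float | None = None,
    metadata: dict | None = None,
) -> FieldImage:
    """Read a 1- or 2-page grayscale TIFF into a :class:`FieldImage`.

    The JSON sidecar supplies pixel size and metadata when present;
    explicit arguments override it.  Missing pixel size falls back to
    the 1 um/px default with a warning.  RGB input and stacks of more
    than two pages are rejected with a remedy hint.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise FieldFormatError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(pages)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FieldFormatError(
            f"{path}: unsupported TIFF layout {arr.shape}; expected 1-2 "
            "grayscale pages"
        )
    if arr.shape[0] > 2:
        if arr.shape[-1] in (3, 4) and arr.ndim == 3:
            raise FieldFormatError(
                f"{path}: looks like an RGB image; split it into per-channel "
                "grayscale pages first"
            )
        raise FieldFormatError(
            f"{path}: {arr.shape[0]} pages; expected at most 2 "
            "(S/CD68 first, ML/Iba1 second)"
        )
    if arr.shape[-1] in (3, 4) and arr.ndim == 4:
        raise FieldFormatError(
            f"{path}: RGB pages are not supported; provide grayscale channels"
        )

    sidecar_path = path.with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    px = pixel_size_um or sidecar.get("pixel_size_um")
    if px is None:
        warnings.warn(
            f"{path}: no pixel size in sidecar or arguments; "
            f"assuming {DEFAULT_PIXEL_SIZE_UM} um/px"
        )
        px = DEFAULT_PIXEL_SIZE_UM
    meta = dict(sidecar.get("metadata", {}))
    meta.update(metadata or {})
    ml = arr[1].astype(float) if arr.shape[0] == 2 else None
    return FieldImage(arr[0].astype(float), ml, float(px), meta)


def write_ground_truth(cells: pd.DataFrame, path: str | Path) -> Path:
    """Sidecar CSV with one row per simulated cell."""
    path = Path(path)
    cells.to_csv(path, index=False)
    return path


def write_preset_json(preset, path: str | Path) -> Path:
    """Record the generating preset next to its scene."""
    from dataclasses import asdict

    path = Path(path)
    path.write_text(json.dumps(_jsonable(asdict(preset)), indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
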