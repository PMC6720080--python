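"""Aggregate per-field areas into survival series and spatial summaries.

Survival is measured as thresholded opsin+ pixel area per field,
normalized to the group mean at a reference age: outer segments to the
first measurable timepoint (P14), cell bodies to P21 (dense segments
obscure somata before that).  Spatial summaries capture the hemispheric
asymmetry of degeneration and the inferior-quadrant survival advantage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from conequant.presets import SURVIVAL_FIELD_UM

QUANT_COLUMNS = [
    "field_id", "timepoint", "quadrant", "eccentricity",
    "compartment", "channel", "area_um2",
]


@dataclass(frozen=True)
class FieldPlacement:
    """One sampling field on the wholemount, relative to the optic disc."""

    quadrant: str
    eccentricity: str
    centre_mm: tuple[float, float]
    field_um: tuple[float, float]


_QUADRANT_ANGLES = {
    "superior": 90.0,
    "nasal": 0.0,
    "inferior": 270.0,
    "temporal": 180.0,
}


def field_layout(
    optic_disc_centre_mm: tuple[float, float] = (0.0, 0.0),
    eccentricity_mm: float = 1.5,
    disc_radius_mm: float = 0.25,
    field_um: tuple[float, float] = SURVIVAL_FIELD_UM,
) -> list[FieldPlacement]:
    """Standard 8-field sampling layout: 4 central + 4 peripheral.

    Central fields sit directly superior / temporal / inferior / nasal
    of the disc with their inner edge at the disc margin; peripheral
    fields are centred ``eccentricity_mm`` from the disc centre (never
    closer than the central ones, so eccentricity 0 collapses onto the
    central layout).  Nasal is +x for a left-eye wholemount mounted
    ganglion-side up; flip x for the right eye.
    """
    cx, cy = optic_disc_centre_mm
    half_radial_mm = field_um[1] / 2000.0
    d_central = disc_radius_mm + half_radial_mm
    d_peripheral = max(eccentricity_mm, d_central)
    placements = []
    for ecc, dist in (("central", d_central), ("peripheral", d_peripheral)):
        for quad, ang in _QUADRANT_ANGLES.items():
            theta = np.deg2rad(ang)
            centre = (cx + dist * np.cos(theta), cy + dist * np.sin(theta))
            placements.append(FieldPlacement(quad, ecc, centre, field_um))
    return placements


def survival_series(
    records: pd.DataFrame,
    reference_timepoint: int,
    group_keys: tuple[str, ...] = ("compartment", "channel", "eccentricity"),
) -> pd.DataFrame:
    """Per-group survival fractions over time, with SEM across fields.

    ``records`` is tidy with :data:`QUANT_COLUMNS`.  Within each group
    the per-timepoint mean area is divided by the group's mean area at
    ``reference_timepoint``; SEM is propagated from the per-field areas
    on the same scale.  Survival at the reference timepoint is exactly 1.
    """
    missing = set(QUANT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    out = []
    for keys, grp in records.groupby(list(group_keys)):
        ref = grp[grp["timepoint"] == reference_timepoint]["area_um2"]
        if ref.empty:
            raise ValueError(
                f"group {dict(zip(group_keys, np.atleast_1d(keys)))} has no "
                f"records at reference timepoint {reference_timepoint}"
            )
        ref_mean = ref.mean()
        for tp, sub in grp.groupby("timepoint"):
            vals = sub["area_um2"] / ref_mean if ref_mean > 0 else sub["area_um2"] * np.nan
            n = len(vals)
            row = dict(zip(group_keys, np.atleast_1d(keys)))
            row.update(
                timepoint=tp,
                survival=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                n=n,
            )
            out.append(row)
    df = pd.DataFrame(out).sort_values([*group_keys, "timepoint"])
    # the reference point is 1 by construction; pin it exactly
    df.loc[df["timepoint"] == reference_timepoint, "survival"] = 1.0
    return df.reset_index(drop=True)


def hemispheric_asymmetry(
    series_superior: pd.DataFrame, series_inferior: pd.DataFrame
) -> pd.DataFrame:
    """Superior / inferior survival ratio per timepoint.

    Both inputs are single-group outputs of :func:`survival_series`;
    timepoints must match one-to-one.  Zero-denominator ratios are NaN
    and flagged in the ``flag`` column.
    """
    sup = series_superior.sort_values("timepoint").reset_index(drop=True)
    inf = series_inferior.sort_values("timepoint").reset_index(drop=True)
    if len(sup) != len(inf) or not (
        sup["timepoint"].to_numpy() == inf["timepoint"].to_numpy()
    ).all():
        raise ValueError("superior and inferior series timepoints differ")
    denom = inf["survival"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, sup["survival"].to_numpy() / denom, np.nan)
    return pd.DataFrame(
        {
            "timepoint": sup["timepoint"],
            "ratio": ratio,
            "flag": np.where(denom > 0, "", "zero inferior survival"),
        }
    )


def quadrant_total_survival(areas: dict[str, float]) -> dict:
    """Inferior-quadrant survival advantage from total cone areas.

    ``areas`` maps the four quadrant names to total cone area.  Returns
    the inferior area over the mean of the other three, plus all
    pairwise inferior/other ratios; zero denominators are flagged.
    """
    required = {"superior", "inferior", "nasal", "temporal"}
    missing = required - set(areas)
    if missing:
        raise ValueError(f"missing quadrants: {sorted(missing)}")
    others = [areas[q] for q in ("superior", "nasal", "temporal")]
    mean_others = float(np.mean(others))
    result: dict = {"flags": []}
    if mean_others > 0:
        result["inferior_vs_others"] = areas["inferior"] / mean_others
    else:
        result["inferior_vs_others"] = np.nan
        result["flags"].append("zero mean area in non-inferior quadrants")
    for q in ("superior", "nasal", "temporal"):
        if areas[q] > 0:
            result[f"inferior_vs_{q}"] = areas["inferior"] / areas[q]
        else:
            result[f"inferior_vs_{q}"] = np.nan
            result["flags"].append(f"zero area in {q}")
    return result
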