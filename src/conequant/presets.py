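"""Preset catalogue for the synthetic-retina generator.

Each preset bundles the ground-truth parameters of one experimental
condition — cone-type composition of a retinal quadrant, per-compartment
survival relative to a reference age, microglia density and activation,
qPCR expression level — so that every quantification stage of the package
can be exercised against a scene whose true answer is known.

Compositions are area fractions ``(p_S, p_dual, p_ML)`` of the classified
cone area: genuine S-cones (S-opsin only, red in the merged image), dual
cones (both opsins, yellow) and genuine M/L-cones (M/L-opsin only, green).
Printed triples that do not sum exactly to 100% are renormalized to a
proper distribution; the raw triple is retained in ``composition_raw``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

QUADRANTS = ("superior", "inferior", "nasal", "temporal")
ECCENTRICITIES = ("central", "peripheral")

#: default linear pixel size, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 1.0
#: survival-series field, micrometres (width, height)
SURVIVAL_FIELD_UM = (720.0, 540.0)
#: cone-type composition field, micrometres (width, height)
COMPOSITION_FIELD_UM = (526.5, 422.5)

#: wild-type-equivalent cone density, cones per mm^2 (order of magnitude of
#: published mouse cone densities; fractions, not absolute counts, are the
#: quantities this package validates)
WT_CONE_DENSITY_MM2 = 10_000.0

#: minimum centre-to-centre cone spacing, micrometres
HARDCORE_SPACING_UM = 8.0


class PresetError(KeyError):
    """Requested condition is not in the preset catalogue."""


@dataclass(frozen=True)
class GeneratorPreset:
    """Ground-truth parameters for one synthetic scene.

    Attributes
    ----------
    label:
        Human-readable key, e.g. ``"P60/inferior/peripheral"``.
    timepoint:
        Condition label: ``"WT"`` or a postnatal day string like ``"P60"``.
    quadrant, eccentricity:
        Anatomical location of the field.
    composition:
        ``(p_S, p_dual, p_ML)`` renormalized to sum to 1.
    composition_raw:
        The catalogued triple before renormalization (may sum to != 1).
    cone_density:
        Wild-type-equivalent cone density, cones / mm^2; the realized
        density is ``cone_density * soma_survival``.
    segment_survival:
        Fraction of surviving cones that retain an outer segment.
    soma_survival:
        Cone cell-body survival relative to the wild-type-equivalent
        density (density scaler in [0, 1]).
    illumination_amplitude:
        Relative modulation of the smooth multiplicative illumination
        field, in [0, 0.5].
    noise_sd:
        Additive Gaussian noise, 8-bit intensity units.
    microglia:
        ``(iba1_density, activated_fraction)`` when the condition carries
        microglia parameters, else ``None``.  Density is per mm^2 for
        wholemount scenes and per mm for transverse strips.
    field_um:
        Physical field size (width, height) in micrometres.
    """

    label: str
    timepoint: str
    quadrant: str
    eccentricity: str
    composition: tuple[float, float, float]
    composition_raw: tuple[float, float, float]
    cone_density: float = WT_CONE_DENSITY_MM2
    segment_survival: float = 1.0
    soma_survival: float = 1.0
    illumination_amplitude: float = 0.25
    noise_sd: float = 4.0
    microglia: Optional[tuple[float, float]] = None
    field_um: tuple[float, float] = COMPOSITION_FIELD_UM
    hardcore_um: float = HARDCORE_SPACING_UM
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS + ("any",):
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if self.eccentricity not in ECCENTRICITIES:
            raise ValueError(f"unknown eccentricity {self.eccentricity!r}")
        s = sum(self.composition)
        if not abs(s - 1.0) < 1e-9:
            raise ValueError(f"composition must sum to 1, got {s}")
        for p in self.composition:
            if not 0.0 <= p <= 1.0:
                raise ValueError("composition fractions must be in [0, 1]")
        for name in ("segment_survival", "soma_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cone_density < 0:
            raise ValueError("cone_density must be >= 0")
        if not 0.0 <= self.illumination_amplitude <= 0.5:
            raise ValueError("illumination_amplitude must be in [0, 0.5]")


def _renorm(triple: tuple[float, float, float]) -> tuple[float, float, float]:
    s = sum(triple)
    if s <= 0:
        raise ValueError("composition triple must have positive sum")
    return tuple(p / s for p in triple)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Cone-type composition catalogue (peripheral fields, 1.5 mm eccentricity).
# Triples are (p_S, p_dual, p_ML) in percent as printed; P14 superior,
# P60 nasal and P60 temporal do not sum to 100 and are renormalized.
# ---------------------------------------------------------------------------

_COMPOSITION_PCT: dict[tuple[str, str], tuple[float, float, float]] = {
    ("WT", "any"): (14.0, 35.0, 50.0),
    ("P14", "superior"): (15.6, 40.4, 38.1),
    ("P14", "inferior"): (37.5, 35.3, 27.2),
    ("P14", "nasal"): (41.3, 34.5, 24.2),
    ("P14", "temporal"): (41.6, 29.9, 28.5),
    ("P60", "superior"): (8.2, 53.7, 38.1),
    ("P60", "inferior"): (97.7, 2.3, 0.0),
    ("P60", "nasal"): (23.2, 46.3, 18.6),
    ("P60", "temporal"): (30.2, 58.1, 23.7),
}

# Total cone area at P60 per quadrant (mean pixel areas of the combined
# cone mask): inferior 1,154,292; superior 342,175; nasal 402,722;
# temporal 390,130 px^2 — roughly threefold greater survival inferiorly.
# Encoded as soma_survival scalers anchored at 0.10 for the inferior
# quadrant: low enough that thresholded pixel area stays ~proportional
# to cell number (blob overlap would otherwise compress the ratio), and
# absolute density is not a validated quantity — ratios are.
_P60_AREA_PX2 = {
    "superior": 342_175.0,
    "inferior": 1_154_292.0,
    "nasal": 402_722.0,
    "temporal": 390_130.0,
}
_P60_SOMA_SURVIVAL = {
    q: 0.10 * a / _P60_AREA_PX2["inferior"] for q, a in _P60_AREA_PX2.items()
}

# Per-timepoint (soma_survival, segment_survival) for composition presets.
# At P14 nearly all cones retain (misshapen) outer segments; by P60 the
# overwhelming majority of segments have degenerated and opsin has
# redistributed to the soma.
_COMPOSITION_SURVIVAL = {
    "WT": (1.0, 1.0),
    "P14": (0.95, 0.95),
    "P60": None,  # quadrant-specific, see _P60_SOMA_SURVIVAL
}


def make_preset(
    timepoint: str | int,
    quadrant: str,
    eccentricity: str = "peripheral",
) -> GeneratorPreset:
    """Look up the cone-composition preset for one catalogued condition.

    Parameters
    ----------
    timepoint:
        ``"WT"`` or a postnatal day (``"P60"`` or ``60``).
    quadrant:
        One of superior / inferior / nasal / temporal (``"any"`` for the
        quadrant-independent wild-type preset; any quadrant name also
        resolves to it).
    eccentricity:
        ``"peripheral"`` (the only catalogued composition eccentricity)
        or ``"central"``.

    Raises
    ------
    PresetError
        If the (timepoint, quadrant, eccentricity) tuple is not catalogued;
        the message lists the available conditions.
    """
    tp = f"P{timepoint}" if isinstance(timepoint, int) else str(timepoint)
    quad = quadrant.lower()
    key = (tp, quad)
    if tp == "WT":
        key = (tp, "any")
    if key not in _COMPOSITION_PCT or eccentricity != "peripheral":
        avail = ", ".join(
            f"{t}/{q}/peripheral" for t, q in sorted(_COMPOSITION_PCT)
        )
        raise PresetError(
            f"no composition preset for {tp}/{quadrant}/{eccentricity}; "
            f"available: {avail}"
        )
    raw_pct = _COMPOSITION_PCT[key]
    raw = tuple(p / 100.0 for p in raw_pct)
    if tp == "P60":
        soma = _P60_SOMA_SURVIVAL[quad]
        seg = 0.02
    else:
        soma, seg = _COMPOSITION_SURVIVAL[tp]
    return GeneratorPreset(
        label=f"{tp}/{key[1]}/{eccentricity}",
        timepoint=tp,
        quadrant=key[1],
        eccentricity=eccentricity,
        composition=_renorm(raw),
        composition_raw=raw,
        soma_survival=soma,
        segment_survival=seg,
    )


def list_presets() -> list[str]:
    """Labels of all catalogued cone-composition presets."""
    return [f"{t}/{q}/peripheral" for t, q in sorted(_COMPOSITION_PCT)]


# ---------------------------------------------------------------------------
# Survival time-course catalogue for the degeneration series.
# Values are absolute per-compartment area scalers vs the wild-type-
# equivalent field: segment area is referenced to P14 (first measurable
# timepoint) and soma area to P21 (segments obscure somata before that).
# Anchors: central segment loss effectively complete by P21; >90% of
# peripheral segments lost by P45; central soma survival ~25% vs ~75%
# peripheral at P60.
# ---------------------------------------------------------------------------

_SURVIVAL_CURVES: dict[str, dict[int, tuple[float, float]]] = {
    # eccentricity -> {postnatal day: (soma_abs, segment_abs)}
    "central": {
        14: (1.00, 1.000),
        21: (1.00, 0.030),
        30: (0.60, 0.010),
        45: (0.40, 0.005),
        60: (0.25, 0.003),
        90: (0.12, 0.002),
    },
    "peripheral": {
        14: (1.00, 1.000),
        21: (1.00, 0.550),
        30: (0.85, 0.300),
        45: (0.80, 0.080),
        60: (0.75, 0.040),
        90: (0.45, 0.020),
    },
}

SEGMENT_REFERENCE_DAY = 14
SOMA_REFERENCE_DAY = 21


def survival_timepoints(eccentricity: str) -> list[int]:
    """Postnatal days catalogued for the survival time-course."""
    return sorted(_SURVIVAL_CURVES[eccentricity])


def expected_survival(
    timepoint: int, eccentricity: str, compartment: str
) -> float:
    """Ground-truth area-survival fraction for one catalogued condition.

    ``compartment`` is ``"segments"`` (reference P14) or ``"somata"``
    (reference P21).
    """
    curve = _SURVIVAL_CURVES[eccentricity]
    soma, seg = curve[timepoint]
    if compartment == "segments":
        ref = curve[SEGMENT_REFERENCE_DAY][1]
        return seg / ref
    if compartment == "somata":
        ref = curve[SOMA_REFERENCE_DAY][0]
        return soma / ref
    raise ValueError(f"unknown compartment {compartment!r}")


def make_survival_preset(
    timepoint: int,
    eccentricity: str,
    quadrant: str = "inferior",
    density_scale: float = 1.0,
) -> GeneratorPreset:
    """Preset for one point of the degeneration time-course.

    The field renders single-opsin cones (composition is irrelevant for
    area-survival readouts); ``density_scale`` allows reduced-scale
    fields for fast checks.
    """
    curve = _SURVIVAL_CURVES.get(eccentricity)
    if curve is None or timepoint not in curve:
        raise PresetError(
            f"no survival preset for P{timepoint}/{eccentricity}; "
            f"catalogued days: { {e: sorted(c) for e, c in _SURVIVAL_CURVES.items()} }"
        )
    soma_abs, seg_abs = curve[timepoint]
    return GeneratorPreset(
        label=f"P{timepoint}/{quadrant}/{eccentricity}/survival",
        timepoint=f"P{timepoint}",
        quadrant=quadrant,
        eccentricity=eccentricity,
        composition=(1.0, 0.0, 0.0),
        composition_raw=(1.0, 0.0, 0.0),
        cone_density=WT_CONE_DENSITY_MM2 * density_scale,
        soma_survival=soma_abs,
        segment_survival=min(1.0, seg_abs / soma_abs),
        field_um=SURVIVAL_FIELD_UM,
    )


# ---------------------------------------------------------------------------
# Microglia catalogue.  Wholemount activated fractions (CD68+/Iba1+):
# 79.1% at P21, 17.6% at P60, 2.6% at P300; Iba1+ numbers fall to 67% of
# the P21 level by P60 and 33.9% by P300.  Transverse ONL linear density:
# 62 cells/mm at P14, 26 at P21, 9 at P75.  Absolute wholemount density is
# not printed; 150 cells/mm^2 at P21 is a realistic order of magnitude for
# retinal microglia and only fractions are validated.
# ---------------------------------------------------------------------------

_MICROGLIA_WHOLEMOUNT: dict[str, tuple[float, float]] = {
    # timepoint -> (iba1 density per mm^2, activated fraction)
    "P21": (150.0, 0.791),
    "P60": (150.0 * 0.67, 0.176),
    "P300": (150.0 * 0.339, 0.026),
}

_MICROGLIA_TRANSVERSE: dict[str, tuple[float, float]] = {
    # timepoint -> (iba1 linear density per mm of ONL, amoeboid fraction)
    "P14": (62.0, 0.9),
    "P21": (26.0, 0.7),
    "P75": (9.0, 0.4),
}


def make_microglia_preset(
    timepoint: str | int, geometry: str = "wholemount"
) -> GeneratorPreset:
    """Preset for an Iba1/CD68 microglia scene.

    ``geometry`` selects wholemount (density per mm^2, activated fraction
    catalogued) or transverse (ONL linear density per mm).
    """
    tp = f"P{timepoint}" if isinstance(timepoint, int) else str(timepoint)
    table = (
        _MICROGLIA_WHOLEMOUNT if geometry == "wholemount" else _MICROGLIA_TRANSVERSE
    )
    if tp not in table:
        raise PresetError(
            f"no {geometry} microglia preset for {tp}; "
            f"available: {sorted(table)}"
        )
    # transverse strips span 2 mm of retina; wholemount fields use the
    # standard sampling field
    field = SURVIVAL_FIELD_UM if geometry == "wholemount" else (2000.0, 200.0)
    return GeneratorPreset(
        label=f"{tp}/microglia/{geometry}",
        timepoint=tp,
        quadrant="any",
        eccentricity="peripheral",
        composition=(1.0, 0.0, 0.0),
        composition_raw=(1.0, 0.0, 0.0),
        cone_density=0.0,
        microglia=table[tp],
        field_um=field,
    )


# ---------------------------------------------------------------------------
# qPCR expression catalogue: opsin mRNA levels relative to wild type.
# Both opsin mRNAs decline roughly linearly from P14 to 16% of the WT
# level at P90; S-opsin slightly faster early on.  Reference genes
# (GAPDH, cyclophilin) are constant at 1 by definition.
# ---------------------------------------------------------------------------

QPCR_GROUPS = ("WT", "P14", "P30", "P45", "P60", "P75", "P90")

_EXPRESSION_VS_WT: dict[str, dict[str, float]] = {
    "ML-opsin": {
        "WT": 1.0, "P14": 0.85, "P30": 0.60, "P45": 0.45,
        "P60": 0.32, "P75": 0.22, "P90": 0.16,
    },
    "S-opsin": {
        "WT": 1.0, "P14": 0.80, "P30": 0.50, "P45": 0.38,
        "P60": 0.28, "P75": 0.20, "P90": 0.16,
    },
    "GAPDH": {g: 1.0 for g in QPCR_GROUPS},
    "cyclophilin": {g: 1.0 for g in QPCR_GROUPS},
}

REFERENCE_GENES = ("GAPDH", "cyclophilin")
TARGET_GENES = ("S-opsin", "ML-opsin")


def expression_levels(gene: str) -> dict[str, float]:
    """Ground-truth relative expression (vs WT) for one gene by group."""
    if gene not in _EXPRESSION_VS_WT:
        raise PresetError(
            f"no expression preset for {gene!r}; "
            f"available: {sorted(_EXPRESSION_VS_WT)}"
        )
    return dict(_EXPRESSION_VS_WT[gene])
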