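"""Spatial realization of a cone mosaic from a generator preset.

Cone centres are drawn from a hardcore point process (random sequential
adsorption with a minimum centre-to-centre spacing, mimicking the
exclusion zone of photoreceptor somata); type labels are multinomial in
the preset composition and outer-segment presence is Bernoulli in the
preset segment survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conequant.presets import GeneratorPreset

CONE_TYPES = ("S", "dual", "ML")

#: soma ellipse axes (major, minor) in micrometres — wide ovoid cell body
SOMA_AXES_UM = (8.0, 6.0)
#: outer-segment blob axes (major, minor) in micrometres — narrow bundle
SEGMENT_AXES_UM = (5.0, 2.0)

# jamming coverage of 2-D random sequential adsorption of equal discs;
# densities requesting more than ~95% of it are rejected as infeasible
_RSA_JAMMING = 0.547


class PackingError(RuntimeError):
    """Requested density and hardcore spacing are jointly infeasible."""


@dataclass
class ConeGroundTruth:
    """Per-cone ground-truth records for one synthetic field.

    ``cones`` has one row per cone: ``x_um, y_um, type, has_segment,
    soma_major_um, soma_minor_um, orientation, amp_s, amp_ml`` where the
    amplitudes are per-channel peak soma intensities (8-bit scale).
    Dual cones have both amplitudes positive, genuine S-cones have
    ``amp_ml == 0`` and genuine M/L-cones ``amp_s == 0``.
    """

    cones: pd.DataFrame
    preset: GeneratorPreset
    hardcore_um: float

    def __len__(self) -> int:
        return len(self.cones)

    @property
    def positions(self) -> np.ndarray:
        return self.cones[["x_um", "y_um"]].to_numpy(float)

    def type_counts(self) -> dict[str, int]:
        c = self.cones["type"].value_counts()
        return {t: int(c.get(t, 0)) for t in CONE_TYPES}


def _empty_cones() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "type": pd.Series(dtype=object),
            "has_segment": pd.Series(dtype=bool),
            "soma_major_um": pd.Series(dtype=float),
            "soma_minor_um": pd.Series(dtype=float),
            "orientation": pd.Series(dtype=float),
            "amp_s": pd.Series(dtype=float),
            "amp_ml": pd.Series(dtype=float),
        }
    )


def hardcore_points(
    n: int,
    width: float,
    height: float,
    spacing: float,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> np.ndarray:
    """Place ``n`` points in a (width x height) rectangle with pairwise
    distance >= ``spacing`` by random sequential adsorption.

    Returns an (n, 2) array.  Raises :class:`PackingError` when the
    requested coverage exceeds the RSA jamming limit or placement stalls.
    """
    if n == 0:
        return np.empty((0, 2))
    area = width * height
    coverage = n * np.pi * (spacing / 2.0) ** 2 / area
    if coverage > 0.95 * _RSA_JAMMING:
        raise PackingError(
            f"{n} points at spacing {spacing} in {width}x{height} "
            f"requires coverage {coverage:.3f}, beyond the RSA limit"
        )
    if max_attempts is None:
        max_attempts = max(500 * n, 100_000)

    # uniform grid with at most one point per cell for O(1) conflict checks
    cell = spacing / np.sqrt(2.0)
    nx = int(width / cell) + 1
    ny = int(height / cell) + 1
    grid = np.full((nx + 4, ny + 4), -1, dtype=np.int64)  # pad 2 cells
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    s2 = spacing * spacing
    batch = 4096
    while placed < n and attempts < max_attempts:
        cand = rng.uniform((0.0, 0.0), (width, height), size=(batch, 2))
        attempts += batch
        cx = (cand[:, 0] / cell).astype(np.int64) + 2
        cy = (cand[:, 1] / cell).astype(np.int64) + 2
        for k in range(batch):
            gx, gy = cx[k], cy[k]
            ok = True
            neigh = grid[gx - 2 : gx + 3, gy - 2 : gy + 3]
            idx = neigh[neigh >= 0]
            if idx.size:
                d = pts[idx] - cand[k]
                if np.min(d[:, 0] ** 2 + d[:, 1] ** 2) < s2:
                    ok = False
            if ok:
                pts[placed] = cand[k]
                grid[gx, gy] = placed
                placed += 1
                if placed == n:
                    break
    if placed < n:
        raise PackingError(
            f"placed only {placed}/{n} points after {attempts} attempts "
            f"(coverage {coverage:.3f}); reduce density or spacing"
        )
    return pts


def sample_cone_mosaic(
    preset: GeneratorPreset,
    rng: np.random.Generator,
    n_override: int | None = None,
) -> ConeGroundTruth:
    """Draw a cone mosaic realization of ``preset``.

    The expected cone count is ``cone_density * soma_survival * area``;
    the realized count is Poisson unless ``n_override`` pins it.  Type
    labels are i.i.d. multinomial in the preset composition and
    ``has_segment`` is Bernoulli in ``segment_survival``.
    """
    width, height = preset.field_um
    area_mm2 = width * height / 1e6
    if n_override is not None:
        n = int(n_override)
    else:
        mean = preset.cone_density * preset.soma_survival * area_mm2
        n = int(rng.poisson(mean)) if mean > 0 else 0
        # truncate at the hardcore packing ceiling: a mosaic cannot hold
        # more somata than the exclusion zones allow
        cap = int(
            0.95 * _RSA_JAMMING * width * height
            / (np.pi * (preset.hardcore_um / 2.0) ** 2)
        )
        n = min(n, cap)
    if n == 0:
        return ConeGroundTruth(_empty_cones(), preset, preset.hardcore_um)

    pts = hardcore_points(n, width, height, preset.hardcore_um, rng)
    types = rng.choice(CONE_TYPES, size=n, p=np.asarray(preset.composition))
    has_segment = rng.random(n) < preset.segment_survival

    major = rng.normal(SOMA_AXES_UM[0], 0.5, n).clip(5.0, 11.0)
    minor = rng.normal(SOMA_AXES_UM[1], 0.4, n).clip(4.0, 9.0)
    orientation = rng.uniform(0.0, np.pi, n)

    # overall brightness jitter is shared between the channels of a dual
    # cone; only the secondary channel is attenuated (bounded so pixel
    # hue stays inside the yellow window).  This keeps the brightness
    # profile max(S, ML) identically distributed across cone types, so
    # thresholded area per cone carries no type bias.
    from conequant.render import SOMA_PEAK

    jit = rng.uniform(0.85, 1.15, n)
    ratio = rng.uniform(0.80, 1.0, n)
    s_dominant = rng.random(n) < 0.5
    amp = SOMA_PEAK * jit
    is_dual = types == "dual"
    amp_s = np.where(np.isin(types, ("S",)) | (is_dual & s_dominant), amp, 0.0)
    amp_s = np.where(is_dual & ~s_dominant, amp * ratio, amp_s)
    amp_ml = np.where(np.isin(types, ("ML",)) | (is_dual & ~s_dominant), amp, 0.0)
    amp_ml = np.where(is_dual & s_dominant, amp * ratio, amp_ml)

    cones = pd.DataFrame(
        {
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "type": types,
            "has_segment": has_segment,
            "soma_major_um": major,
            "soma_minor_um": minor,
            "orientation": orientation,
            "amp_s": amp_s,
            "amp_ml": amp_ml,
        }
    )
    return ConeGroundTruth(cones, preset, preset.hardcore_um)
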