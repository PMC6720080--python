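from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conequant.presets import (
    expected_survival,
    make_survival_preset,
    survival_timepoints,
)
from conequant.pipeline import quantify_preset_areas
from conequant.spatiotemporal import (
    field_layout,
    hemispheric_asymmetry,
    quadrant_total_survival,
    survival_series,
)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "field_id", "timepoint", "quadrant", "eccentricity",
            "compartment", "channel", "area_um2",
        ],
    )


class TestFieldLayout:
    def test_eight_placements_four_peripheral_at_eccentricity(self):
        layout = field_layout()
        assert len(layout) == 8
        peripheral = [p for p in layout if p.eccentricity == "peripheral"]
        assert len(peripheral) == 4
        for p in peripheral:
            assert np.hypot(*p.centre_mm) == pytest.approx(1.5)

    def test_quadrant_angles_90_degrees_apart(self):
        layout = field_layout()
        for ecc in ("central", "peripheral"):
            pts = [p.centre_mm for p in layout if p.eccentricity == ecc]
            angles = sorted(np.degrees(np.arctan2(y, x)) % 360 for x, y in pts)
            diffs = np.diff(angles + [angles[0] + 360])
            assert np.allclose(diffs, 90.0)

    def test_zero_eccentricity_collapses_onto_central(self):
        layout = field_layout(eccentricity_mm=0.0)
        central = {p.quadrant: p.centre_mm for p in layout if p.eccentricity == "central"}
        for p in layout:
            if p.eccentricity == "peripheral":
                assert p.centre_mm == pytest.approx(central[p.quadrant])


class TestSurvivalSeries:
    def test_flat_areas_give_unit_survival(self):
        rows = [
            (f"f{t}{i}", t, "inferior", "peripheral", "somata", "S", 50.0)
            for t in (21, 30, 45) for i in range(3)
        ]
        out = survival_series(_records(rows), 21, group_keys=("compartment",))
        assert np.allclose(out["survival"], 1.0)

    def test_halved_area_gives_half_survival(self):
        rows = [("a", 21, "q", "e", "somata", "S", 100.0),
                ("b", 21, "q", "e", "somata", "S", 100.0),
                ("c", 30, "q", "e", "somata", "S", 50.0),
                ("d", 30, "q", "e", "somata", "S", 50.0)]
        out = survival_series(_records(rows), 21, group_keys=("compartment",))
        assert out.set_index("timepoint").loc[30, "survival"] == 0.5

    def test_reference_is_exactly_one(self):
        rng = np.random.default_rng(0)
        rows = [(f"f{t}{i}", t, "q", "e", "somata", "S", rng.uniform(10, 90))
                for t in (21, 30) for i in range(4)]
        out = survival_series(_records(rows), 21, group_keys=("compartment",))
        assert out.set_index("timepoint").loc[21, "survival"] == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        rows = [(f"f{t}{i}", t, "q", "e", "somata", "S", rng.uniform(10, 90))
                for t in (21, 30, 45) for i in range(4)]
        df = _records(rows)
        a = survival_series(df, 21, group_keys=("compartment",))
        df2 = df.assign(area_um2=df["area_um2"] * 7.3)
        b = survival_series(df2, 21, group_keys=("compartment",))
        assert np.allclose(a["survival"], b["survival"])
        assert np.allclose(a["sem"].dropna(), b["sem"].dropna())

    def test_missing_reference_names_group(self):
        rows = [("a", 30, "q", "e", "somata", "S", 1.0),
                ("b", 30, "q", "e", "somata", "S", 1.0)]
        with pytest.raises(ValueError, match="somata"):
            survival_series(_records(rows), 21, group_keys=("compartment",))


class TestHemisphericAsymmetry:
    def _series(self, survivals):
        return pd.DataFrame(
            {"timepoint": range(len(survivals)), "survival": survivals}
        )

    def test_identical_series_ratio_one(self):
        s = self._series([1.0, 0.6, 0.3])
        out = hemispheric_asymmetry(s, s)
        assert np.allclose(out["ratio"], 1.0)

    def test_manual_two_point_oracle(self):
        out = hemispheric_asymmetry(
            self._series([1.0, 0.2]), self._series([1.0, 0.8])
        )
        assert out["ratio"].tolist() == pytest.approx([1.0, 0.25])

    def test_zero_denominator_flagged(self):
        out = hemispheric_asymmetry(
            self._series([1.0, 0.2]), self._series([1.0, 0.0])
        )
        assert np.isnan(out["ratio"].iloc[1])
        assert out["flag"].iloc[1] != ""

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hemispheric_asymmetry(
                self._series([1.0]), self._series([1.0, 0.5])
            )


class TestQuadrantTotalSurvival:
    def test_equal_areas_ratio_one(self):
        r = quadrant_total_survival(
            {q: 5.0 for q in ("superior", "inferior", "nasal", "temporal")}
        )
        assert r["inferior_vs_others"] == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        r = quadrant_total_survival(
            {"inferior": 4.0, "superior": 1.0, "nasal": 1.0, "temporal": 1.0}
        )
        assert r["inferior_vs_others"] == pytest.approx(4.0)
        assert r["inferior_vs_nasal"] == pytest.approx(4.0)

    def test_zero_denominator_flagged(self):
        r = quadrant_total_survival(
            {"inferior": 4.0, "superior": 0.0, "nasal": 0.0, "temporal": 0.0}
        )
        assert np.isnan(r["inferior_vs_others"])
        assert r["flags"]

    def test_missing_quadrant(self):
        with pytest.raises(ValueError):
            quadrant_total_survival({"inferior": 1.0})


class TestSurvivalRecovery:
    def test_time_course_recovered_from_synthetic_fields(self):
        """Segment and soma survival curves recovered within +-0.07."""
        frames = []
        for ecc in ("central", "peripheral"):
            for tp in survival_timepoints(ecc):
                p = replace(
                    make_survival_preset(tp, ecc, density_scale=0.2),
                    field_um=(360.0, 270.0),
                )
                frames.append(
                    quantify_preset_areas(p, [1, 2, 3], expected_counts=True)
                )
        rec = pd.concat(frames)
        seg = survival_series(rec, 14, group_keys=("compartment", "eccentricity"))
        for _, row in seg[seg.compartment == "segments"].iterrows():
            exp = expected_survival(row.timepoint, row.eccentricity, "segments")
            assert row.survival == pytest.approx(exp, abs=0.07)
        som = survival_series(
            rec[rec.timepoint >= 21], 21,
            group_keys=("compartment", "eccentricity"),
        )
        for _, row in som[som.compartment == "somata"].iterrows():
            exp = expected_survival(row.timepoint, row.eccentricity, "somata")
            assert row.survival == pytest.approx(exp, abs=0.07)

    def test_central_segment_loss_complete_by_p21(self):
        frames = [
            quantify_preset_areas(
                replace(make_survival_preset(tp, "central", density_scale=0.2),
                        field_um=(360.0, 270.0)),
                [1, 2], expected_counts=True,
            )
            for tp in (14, 21)
        ]
        rec = pd.concat(frames)
        out = survival_series(rec, 14, group_keys=("compartment",))
        p21 = out[(out.compartment == "segments") & (out.timepoint == 21)]
        assert float(p21["survival"].iloc[0]) <= 0.05
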