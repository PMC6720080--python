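import colorsys
from dataclasses import replace

import numpy as np
import pytest

from conequant.cone_typing import (
    CompositionResult,
    HueWindows,
    composition_of_field,
    hue_partition,
    hue_wheel,
    merge_channels,
)
from conequant.mosaic import sample_cone_mosaic
from conequant.presets import make_preset
from conequant.render import FieldImage, render_field


class TestMergeChannels:
    def test_pure_red_green_yellow(self):
        s = np.array([[255, 0, 200]], dtype=np.uint8)
        ml = np.array([[0, 255, 200]], dtype=np.uint8)
        rgb = merge_channels(s, ml)
        assert tuple(rgb[0, 0]) == (255, 0, 0)
        assert tuple(rgb[0, 1]) == (0, 255, 0)
        hue = np.round(hue_wheel(rgb))
        assert hue[0, 0] == 0
        assert hue[0, 2] == 42  # balanced yellow: 60 deg on the 0-255 wheel
        assert hue[0, 1] == 85  # pure green: 120 deg

    def test_shape_and_dtype_checks(self):
        with pytest.raises(ValueError):
            merge_channels(np.zeros((2, 2), np.uint8), np.zeros((3, 2), np.uint8))
        with pytest.raises(ValueError):
            merge_channels(np.zeros((2, 2)), np.zeros((2, 2)))


class TestHueWindows:
    def test_defaults_disjoint(self):
        HueWindows()  # must not raise

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            HueWindows(red=((0, 30),), yellow=((22, 63),))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            HueWindows(green=((100, 300),))


class TestHueWheelProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(r=st.integers(0, 255), g=st.integers(0, 255))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_hue_matches_colorsys_for_merged_pixels(self, r, g):
        rgb = np.array([[[r, g, 0]]], dtype=np.uint8)
        ours = hue_wheel(rgb)[0, 0]
        ref = colorsys.rgb_to_hsv(r / 255, g / 255, 0.0)[0] * 255
        assert ours == pytest.approx(ref, abs=1e-9)

    @given(r=st.integers(0, 255), g=st.integers(0, 255), b=st.integers(0, 255))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_every_pixel_lands_in_exactly_one_class(self, r, g, b):
        rgb = np.array([[[r, g, b]]], dtype=np.uint8)
        masks, _ = hue_partition(rgb, np.ones((1, 1), bool))
        hits = sum(int(masks[k][0, 0]) for k in ("S", "dual", "ML", "unclassified"))
        assert hits == 1


class TestHuePartition:
    def test_matches_per_pixel_brute_force_oracle(self):
        # 10^4 random RGB pixels classified identically by an independent
        # colorsys-based scalar classifier
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        mask = np.ones((100, 100), dtype=bool)
        windows = HueWindows()
        masks, _ = hue_partition(rgb, mask, windows)

        def classify(r, g, b):
            h = round(colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)[0] * 255)
            for name, attr in (("S", "red"), ("dual", "yellow"), ("ML", "green")):
                for lo, hi in getattr(windows, attr):
                    if lo <= h <= hi:
                        return name
            return "unclassified"

        for y in range(100):
            for x in range(100):
                expected = classify(*rgb[y, x])
                assert masks[expected][y, x], (rgb[y, x], expected)

    def test_all_red_pixels(self):
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        rgb[..., 0] = 200
        _, res = hue_partition(rgb, np.ones((10, 10), bool))
        assert res.fractions == {"S": 1.0, "dual": 0.0, "ML": 0.0}

    def test_balanced_pixels_are_dual(self):
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        rgb[..., 0] = rgb[..., 1] = 180
        _, res = hue_partition(rgb, np.ones((10, 10), bool))
        assert res.fractions["dual"] == 1.0

    def test_area_conservation_exact(self, rng):
        rgb = rng.integers(0, 256, (50, 50, 3), dtype=np.uint8)
        mask = rng.random((50, 50)) > 0.4
        masks, res = hue_partition(rgb, mask)
        total = sum(res.areas.values())
        assert total == mask.sum()
        union = masks["S"] | masks["dual"] | masks["ML"] | masks["unclassified"]
        assert np.array_equal(union, mask)

    def test_empty_mask_flagged_not_nan(self):
        rgb = np.zeros((5, 5, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="no classified"):
            _, res = hue_partition(rgb, np.zeros((5, 5), bool))
        assert res.fractions is None
        assert res.metadata["flag"] == "empty classified area"


@pytest.fixture(scope="module")
def quiet_field():
    p = replace(make_preset("P14", "inferior"), noise_sd=0.0,
                illumination_amplitude=0.0, soma_survival=0.25)
    gen = np.random.default_rng(5)
    gt = sample_cone_mosaic(p, gen)
    return p, render_field(gt, p, gen)


class TestCompositionOfField:
    def test_channel_swap_symmetry_exact(self, quiet_field):
        # on a noise-free field swapping channels maps p_S <-> p_ML and
        # leaves the dual fraction unchanged (hue mirror about 42.5)
        _, f = quiet_field
        res = composition_of_field(f)
        swapped = FieldImage(f.channel_ml.copy(), f.channel_s.copy(),
                             f.pixel_size_um, dict(f.metadata))
        res_sw = composition_of_field(swapped)
        assert res_sw.areas["S"] == res.areas["ML"]
        assert res_sw.areas["ML"] == res.areas["S"]
        assert res_sw.areas["dual"] == res.areas["dual"]

    def test_blank_ml_channel_yields_pure_s(self, quiet_field):
        p, f = quiet_field
        from conequant.render import BACKGROUND

        blank = FieldImage(
            f.channel_s.copy(), np.full_like(f.channel_ml, BACKGROUND),
            f.pixel_size_um,
        )
        res = composition_of_field(blank)
        assert res.fractions["ML"] == 0.0
        assert res.fractions["dual"] == 0.0

    def test_hue_containment_single_type_fields(self):
        # noise-free single-type mosaics classify 100% into their window
        for comp, key in [((1.0, 0.0, 0.0), "S"), ((0.0, 1.0, 0.0), "dual"),
                          ((0.0, 0.0, 1.0), "ML")]:
            p = replace(make_preset("P60", "superior"), noise_sd=0.0,
                        illumination_amplitude=0.0, soma_survival=0.1,
                        composition=comp, composition_raw=comp)
            gen = np.random.default_rng(9)
            f = render_field(sample_cone_mosaic(p, gen), p, gen)
            res = composition_of_field(f)
            assert res.fractions[key] == 1.0, (key, res.fractions)

    def test_recovery_within_tolerance_single_preset(self):
        p = make_preset("P60", "superior")
        fractions = []
        for seed in (1, 2, 3):
            gen = np.random.default_rng(seed)
            f = render_field(sample_cone_mosaic(p, gen), p, gen)
            fractions.append(composition_of_field(f).fractions["dual"])
        assert np.mean(fractions) == pytest.approx(p.composition[1], abs=0.05)

    def test_provenance_recorded(self, quiet_field):
        _, f = quiet_field
        res = composition_of_field(f)
        assert "threshold" in res.metadata
        assert "stretch_bounds" in res.metadata

    def test_unknown_compartment(self, quiet_field):
        _, f = quiet_field
        with pytest.raises(ValueError):
            composition_of_field(f, compartment="axons")
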