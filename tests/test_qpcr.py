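import numpy as np
import pandas as pd
import pytest

from conequant.presets import REFERENCE_GENES
from conequant.qpcr import (
    EfficiencyError,
    estimate_efficiency,
    normalization_factor,
    relative_expression,
)
from conequant.qpcr_synth import CtTable, simulate_ct_table

ALL_E2 = {"ML-opsin": 2.0, "GAPDH": 2.0, "cyclophilin": 2.0}


def _table(expression, group_ns, efficiencies=None, sd=0.0, seed=0):
    expr = dict(expression)
    expr.setdefault("GAPDH", {})
    expr.setdefault("cyclophilin", {})
    eff = efficiencies or {g: 2.0 for g in expr}
    return simulate_ct_table(
        expr, group_ns, eff, np.random.default_rng(seed), noise_sd=sd
    )


class TestEstimateEfficiency:
    def test_perfect_doubling_series(self):
        q = np.array([100.0, 10.0, 1.0, 0.1])
        ct = 20.0 - np.log10(q) / np.log10(2.0)  # slope -3.3219/decade
        est = estimate_efficiency(q, ct)
        assert est.efficiency == pytest.approx(2.0, abs=1e-9)
        assert est.slope == pytest.approx(-3.3219, abs=1e-3)
        assert est.r_squared == pytest.approx(1.0)

    def test_noisy_series_recovers_efficiency(self):
        rng = np.random.default_rng(0)
        true_e = 1.95
        q = np.repeat([100.0, 10.0, 1.0, 0.1], 3)
        estimates = []
        for _ in range(10):
            ct = 22.0 - np.log(q) / np.log(true_e) + rng.normal(0, 0.1, q.size)
            estimates.append(estimate_efficiency(q, ct).efficiency)
        assert np.mean(estimates) == pytest.approx(true_e, abs=0.03)

    def test_two_point_series_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            estimate_efficiency([1.0, 0.1], [20.0, 23.3])

    def test_rising_ct_with_input_rejected(self):
        with pytest.raises(EfficiencyError):
            estimate_efficiency([1.0, 10.0, 100.0], [20.0, 22.0, 24.0])


class TestNormalizationFactor:
    def test_sample_at_calibrator_mean_gives_unity(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 1.0}},
                   {"WT": 3, "P90": 3})
        nf = normalization_factor(t, "WT")
        assert np.allclose(nf["nf"], 1.0)

    def test_one_cycle_reference_shift_doubles_factor(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 1.0}}, {"WT": 3, "P90": 3})
        df = t.data.copy()
        refs = df["gene"].isin(REFERENCE_GENES) & (df["group"] == "P90")
        df.loc[refs, "ct"] -= 1.0  # both refs 1 cycle earlier: 2x input
        nf = normalization_factor(CtTable(df, t.efficiencies), "WT")
        assert np.allclose(nf.set_index("group").loc["P90", "nf"], 2.0)

    def test_matches_brute_force_formula(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.3}},
                   {"WT": 4, "P90": 4}, sd=0.4, seed=3)
        nf = normalization_factor(t, "WT").set_index(["group", "replicate"])
        df = t.data
        for (group, rep) in nf.index:
            logs = []
            for ref in REFERENCE_GENES:
                cal = df[(df.gene == ref) & (df.group == "WT")]["ct"].mean()
                ct = df[(df.gene == ref) & (df.group == group)
                        & (df.replicate == rep)]["ct"].iloc[0]
                logs.append(np.log(2.0) * (cal - ct))
            expected = np.exp(np.mean(logs))
            assert nf.loc[(group, rep), "nf"] == pytest.approx(expected)

    def test_missing_reference_named(self):
        t = _table({"ML-opsin": {"WT": 1.0}}, {"WT": 3})
        df = t.data[t.data.gene != "cyclophilin"]
        with pytest.raises(ValueError, match="cyclophilin"):
            normalization_factor(CtTable(df, t.efficiencies), "WT")


class TestRelativeExpression:
    def test_calibrator_rq_is_exactly_one(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.3}},
                   {"WT": 5, "P90": 5}, sd=0.3, seed=1)
        res = relative_expression(t, "ML-opsin", "WT").set_index("group")
        assert res.loc["WT", "rq"] == 1.0

    def test_one_cycle_shift_halves_rq(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.5}}, {"WT": 3, "P90": 3})
        res = relative_expression(t, "ML-opsin", "WT").set_index("group")
        assert res.loc["P90", "rq"] == pytest.approx(0.5, abs=1e-12)

    def test_noise_free_round_trip_machine_precision(self):
        levels = {"WT": 1.0, "P14": 0.85, "P90": 0.16}
        t = _table({"ML-opsin": levels}, {g: 4 for g in levels},
                   efficiencies={"ML-opsin": 1.93, "GAPDH": 1.97,
                                 "cyclophilin": 1.91})
        res = relative_expression(t, "ML-opsin", "WT").set_index("group")
        for g, level in levels.items():
            assert res.loc[g, "rq"] == pytest.approx(level, rel=1e-9)

    def test_shift_invariance(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.4}},
                   {"WT": 4, "P90": 4}, sd=0.2, seed=5)
        baseline = relative_expression(t, "ML-opsin", "WT")

        @given(shift=st.floats(-4.0, 4.0, allow_nan=False))
        @settings(max_examples=30, deadline=None, derandomize=True)
        def check(shift):
            shifted = CtTable(t.data.assign(ct=t.data.ct + shift),
                              t.efficiencies)
            b = relative_expression(shifted, "ML-opsin", "WT")
            assert np.allclose(baseline["rq"], b["rq"])

        check()

    def test_global_reference_shift_cancels(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.4}},
                   {"WT": 4, "P90": 4}, sd=0.2, seed=6)
        df = t.data.copy()
        df.loc[df.gene == "GAPDH", "ct"] += 2.0
        a = relative_expression(t, "ML-opsin", "WT")
        b = relative_expression(CtTable(df, t.efficiencies), "ML-opsin", "WT")
        assert np.allclose(a["rq"], b["rq"])

    def test_simulated_p90_level_recovered(self):
        rqs = []
        for seed in (1, 2, 3, 4, 5):
            t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.16}},
                       {"WT": 6, "P90": 6},
                       efficiencies={g: 1.95 for g in
                                     ("ML-opsin", "GAPDH", "cyclophilin")},
                       sd=0.15, seed=seed)
            res = relative_expression(t, "ML-opsin", "WT").set_index("group")
            rqs.append(res.loc["P90", "rq"])
        assert np.mean(rqs) == pytest.approx(0.16, abs=0.02)

    def test_missing_gene_and_calibrator_errors(self):
        t = _table({"ML-opsin": {"WT": 1.0, "P90": 0.4}}, {"WT": 3, "P90": 3})
        with pytest.raises(ValueError, match="S-opsin"):
            relative_expression(t, "S-opsin", "WT")
        with pytest.raises(ValueError, match="calibrator"):
            relative_expression(t, "ML-opsin", "P300")


class TestCtTableValidation:
    def test_replicate_minimum(self):
        df = pd.DataFrame(
            {"gene": ["GAPDH"], "group": ["WT"], "replicate": [1], "ct": [20.0]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            CtTable(df)

    def test_ct_range(self):
        df = pd.DataFrame(
            {"gene": ["GAPDH"] * 2, "group": ["WT"] * 2,
             "replicate": [1, 2], "ct": [20.0, 45.0]}
        )
        with pytest.raises(ValueError, match="\\(5, 40\\)"):
            CtTable(df)

    def test_efficiency_range(self):
        df = pd.DataFrame(
            {"gene": ["GAPDH"] * 2, "group": ["WT"] * 2,
             "replicate": [1, 2], "ct": [20.0, 20.1]}
        )
        with pytest.raises(ValueError, match="efficiency"):
            CtTable(df, {"GAPDH": 2.5})

    def test_non_positive_level_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_ct_table(
                {"ML-opsin": {"WT": 0.0}, "GAPDH": {}, "cyclophilin": {}},
                {"WT": 3}, {"ML-opsin": 2.0, "GAPDH": 2.0, "cyclophilin": 2.0},
                np.random.default_rng(0),
            )
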