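"""Quantification tests: charge averaging, normalization, pooled testing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptidome.quant import (
    ChannelDesign,
    FoldClass,
    Group,
    IntensityObservation,
    RelativeLevelSet,
    Tier,
    average_charge_states,
    differential_table,
    fold_change_tally,
    pool_and_test,
    rank_plot_data,
    relative_levels,
)

KEY = ("PEPTIDEK", "")
DESIGN = ChannelDesign.two_by_two("run1")


def obs(intensities, run="run1", charge=2, key=KEY):
    return IntensityObservation(key, run, charge, intensities)


class TestAverageChargeStates:
    def test_single_state_unchanged(self):
        o = obs({"D0": 100.0, "D3": 50.0})
        combined = average_charge_states([o])
        assert combined.intensity_by_channel == {"D0": 100.0, "D3": 50.0}
        assert combined.charge == 0

    def test_two_states_averaged(self):
        combined = average_charge_states(
            [obs({"D0": 100.0}, charge=2), obs({"D0": 200.0}, charge=3)]
        )
        assert combined.intensity_by_channel["D0"] == 150.0

    def test_mean_over_available_states_only(self):
        combined = average_charge_states(
            [obs({"D0": 100.0, "D3": 50.0}, charge=2),
             obs({"D3": 150.0}, charge=3)]
        )
        assert combined.intensity_by_channel == {"D0": 100.0, "D3": 100.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_charge_states([])

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError):
            average_charge_states([obs({"D0": 1.0}), obs({"D0": 1.0}, run="run2")])


class TestRelativeLevels:
    def test_worked_example(self):
        """Controls 80 and 120, treated 300: control mean 100 gives 0.8/1.2/3.0."""
        levels = relative_levels(
            obs({"D0": 80.0, "D3": 120.0, "D6": 300.0}), DESIGN
        )
        assert levels.ratio_by_channel == pytest.approx(
            {"D0": 0.8, "D3": 1.2, "D6": 3.0}
        )

    def test_equal_channels_all_unity(self):
        levels = relative_levels(
            obs({c: 7.0 for c in DESIGN.channels}), DESIGN
        )
        assert all(r == pytest.approx(1.0) for r in levels.ratio_by_channel.values())

    def test_missing_treated_channel_stays_nd(self):
        levels = relative_levels(obs({"D0": 80.0, "D3": 120.0, "D6": 300.0}), DESIGN)
        assert "D9" not in levels.ratio_by_channel

    def test_no_control_detected_unquantifiable(self):
        with pytest.raises(ValueError, match="unquantifiable"):
            relative_levels(obs({"D6": 10.0, "D9": 12.0}), DESIGN)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(c1=st.floats(0.1, 1e6), c2=st.floats(0.1, 1e6),
           t1=st.floats(0.1, 1e6))
    def test_control_self_normalization_exact(self, c1, c2, t1):
        """Mean of the two control ratios is 1 to 1e-12 (algebraic identity)."""
        levels = relative_levels(obs({"D0": c1, "D3": c2, "D6": t1}), DESIGN)
        mean = (levels.ratio_by_channel["D0"] + levels.ratio_by_channel["D3"]) / 2
        assert abs(mean - 1.0) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3),
           c1=st.floats(0.1, 1e3), c2=st.floats(0.1, 1e3),
           t1=st.floats(0.1, 1e3), t2=st.floats(0.1, 1e3))
    def test_scale_invariance(self, scale, c1, c2, t1, t2):
        raw = {"D0": c1, "D3": c2, "D6": t1, "D9": t2}
        scaled = {ch: v * scale for ch, v in raw.items()}
        a = relative_levels(obs(raw), DESIGN).ratio_by_channel
        b = relative_levels(obs(scaled), DESIGN).ratio_by_channel
        for ch in raw:
            assert a[ch] == pytest.approx(b[ch], rel=1e-9)


def _levels(run, ratios):
    return RelativeLevelSet(KEY, run, ratios)


DESIGNS = {"run1": ChannelDesign.two_by_two("run1"),
           "run2": ChannelDesign.two_by_two("run2")}


class TestPoolAndTest:
    def test_student_t_worked_example(self):
        """Control {0.9, 1.1} vs treated {1.9, 2.1}: t = 7.071, p ~ 0.0194."""
        res = pool_and_test(
            [_levels("run1", {"D0": 0.9, "D3": 1.1, "D6": 1.9, "D9": 2.1})],
            DESIGNS,
        )
        assert res.p_value == pytest.approx(0.0194, abs=2e-4)
        assert res.tier is Tier.P05
        # pooled mean exactly 2 is not > 2: strict threshold keeps it WITHIN
        assert res.fold_class is FoldClass.WITHIN
        assert (res.n_control, res.n_treated) == (2, 2)

    def test_zero_variance_equal_means_is_ns(self):
        res = pool_and_test(
            [_levels("run1", {"D0": 1.0, "D3": 1.0, "D6": 1.0, "D9": 1.0})],
            DESIGNS,
        )
        assert res.tier is Tier.NS and not res.degenerate

    def test_zero_variance_unequal_means_degenerate(self):
        res = pool_and_test(
            [_levels("run1", {"D0": 1.0, "D3": 1.0, "D6": 2.5, "D9": 2.5})],
            DESIGNS,
        )
        assert res.degenerate and res.p_value is None and res.tier is Tier.NS

    def test_large_increase_top_tier(self):
        """A ~5.7-fold increase with tight replicates lands in the p<0.001
        tier and the >2-fold class."""
        res = pool_and_test(
            [_levels("run1", {"D0": 0.95, "D3": 1.05, "D6": 5.65, "D9": 5.75}),
             _levels("run2", {"D0": 0.9, "D3": 1.1, "D6": 5.70, "D9": 5.82})],
            DESIGNS,
        )
        assert res.treated_mean == pytest.approx(5.73, abs=0.01)
        assert res.tier is Tier.P001
        assert res.fold_class is FoldClass.UP_2X
        assert res.n_control == 4  # pooled across runs

    def test_insufficient_replicates_flagged(self):
        res = pool_and_test(
            [_levels("run1", {"D0": 1.0, "D3": 1.0, "D6": 2.0})], DESIGNS
        )
        assert res.insufficient and res.p_value is None


class TestDifferentialTable:
    def test_min_runs_filter(self):
        levels = {
            KEY: [_levels("run1", {"D0": 0.9, "D3": 1.1, "D6": 2.0, "D9": 2.2}),
                  _levels("run2", {"D0": 0.8, "D3": 1.2, "D6": 1.9, "D9": 2.1})],
            ("OTHER", ""): [
                RelativeLevelSet(("OTHER", ""), "run1",
                                 {"D0": 0.9, "D3": 1.1, "D6": 1.0, "D9": 1.0})
            ],
        }
        out = differential_table(levels, DESIGNS, min_runs=2)
        assert [r.peptide_key for r in out] == [KEY]
        assert out[0].bh_q is not None

    def test_control_mean_unity_by_construction(self):
        levels = {
            KEY: [_levels("run1", {"D0": 0.7, "D3": 1.3, "D6": 2.0, "D9": 2.2}),
                  _levels("run2", {"D0": 1.2, "D3": 0.8, "D6": 1.9, "D9": 2.1}),
                  _levels("run3", {"D0": 1.0, "D3": 1.0, "D6": 2.0, "D9": 2.0})],
        }
        designs = dict(DESIGNS)
        designs["run3"] = ChannelDesign.two_by_two("run3")
        (res,) = differential_table(levels, designs, min_runs=3)
        assert res.control_mean == pytest.approx(1.0, abs=1e-12)
        assert res.n_control == 6


class TestRankPlot:
    def test_sorted_with_ranks(self):
        assert rank_plot_data([2.0, 0.5, 1.0]) == [(1, 0.5), (2, 1.0), (3, 2.0)]

    def test_ties_keep_input_order(self):
        out = rank_plot_data([1.0, 1.0, 1.0])
        assert out == [(1, 1.0), (2, 1.0), (3, 1.0)]

    def test_empty(self):
        assert rank_plot_data([]) == []

    def test_large_input_nondecreasing(self):
        rng = np.random.default_rng(0)
        out = rank_plot_data(rng.lognormal(0, 1, 1000).tolist())
        assert len(out) == 1000
        values = [v for _, v in out]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rank_plot_data([1.0, float("nan")])


class TestFoldChangeTally:
    def test_threshold_rule(self):
        out = fold_change_tally([0.4, 3.0, 1.0])
        assert (out["DOWN_2X"], out["UP_2X"], out["WITHIN"]) == (1, 1, 1)
        assert out["fraction_changed"] == pytest.approx(2 / 3)

    def test_exactly_twofold_is_within(self):
        out = fold_change_tally([2.0, 0.5])
        assert out["WITHIN"] == 2 and out["fraction_changed"] == 0.0

    def test_empty(self):
        out = fold_change_tally([])
        assert out["total"] == 0 and out["fraction_changed"] == 0.0
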