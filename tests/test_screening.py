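"""Marker-level statistics: classification rules, ANOVA against exhaustive
permutation, stain index against hand-computed values, ΔΔCt arithmetic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lyoscreen import (
    POP_NEG,
    POP_POS,
    ScreenConfig,
    background_stats,
    classify_positive,
    ddct_fold,
    fold_increase,
    flag_enriched,
    run_screen,
    si_fold,
    simulate_well,
    stain_index,
    test_marker,
)

from conftest import make_mini_config

# rSD = 1.4826 * MAD; three points at median +/- one MAD give an exact handle
_MAD_UNIT = 10.0 / 1.4826


class TestClassifyPositive:
    @pytest.mark.parametrize("p1,p2,expected", [
        (13.8, 2.0, True),   # dimly-positive marker, one population only
        (0.0, 0.0, False),
        (5.4999, 5.4999, False),
        (5.5, 0.0, True),    # inclusive at the 5.5% boundary
        (0.0, 5.5, True),
    ])
    def test_inclusive_rule(self, p1, p2, expected):
        assert classify_positive(p1, p2, 5.5) is expected


class TestFoldIncrease:
    def test_arithmetic(self):
        assert fold_increase(30, 10) == (3.0, False)
        assert fold_increase(7.0, 7.0) == (1.0, False)
        fold, floored = fold_increase(13.8, 2.0)
        assert fold == pytest.approx(6.9)
        assert not floored

    def test_floor_applied_and_flagged(self):
        fold, floored = fold_increase(10.0, 0.0, floor=0.5)
        assert fold == 20.0
        assert floored


class TestTestMarker:
    def test_identical_groups_give_p_one(self):
        assert test_marker([10, 10, 10], [10, 10, 10]) == 1.0

    def test_matches_textbook_f_statistic(self):
        # groups {10,12,14} vs {20,22,24}: SSB=150 (df 1), SSW=16 (df 4),
        # F = 150/(16/4) = 37.5, p = sf(37.5; 1, 4) = 0.0036022
        p = test_marker([10, 12, 14], [20, 22, 24])
        assert p == pytest.approx(0.0036022326, rel=1e-6)

    def test_matches_exhaustive_permutation(self):
        # all C(6,3)=20 assignments of the pooled values; the exhaustive
        # permutation p is granular in steps of 1/20, so the comparison is
        # made where the F distribution puts p near an attainable value
        a, b = [10.0, 13.0, 16.0], [13.75, 16.75, 19.75]
        pooled = a + b
        observed = abs(np.mean(a) - np.mean(b))
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            if abs(np.mean(ga) - np.mean(gb)) >= observed - 1e-12:
                count += 1
            total += 1
        p_perm = count / total  # = 4/20
        p_anova = test_marker(a, b)
        assert abs(p_anova - p_perm) <= 0.02

    def test_paired_mode_and_input_validation(self):
        p = test_marker([10, 12, 14], [20, 23, 24],
                        ScreenConfig(test="paired-t"))
        assert 0 < p < 0.05
        assert test_marker([1, 2], [1, 2], ScreenConfig(test="paired-t")) == 1.0
        with pytest.raises(ValueError, match="2 donors"):
            test_marker([1], [2])


class TestFlagEnriched:
    @pytest.mark.parametrize("fold,p,expected", [
        (1.6, 0.01, True),
        (1.5, 0.049, True),   # fold boundary inclusive
        (1.5, 0.05, False),   # alpha strict
        (1.49, 0.001, False),
        (float("nan"), 0.001, False),
    ])
    def test_boundary_semantics(self, fold, p, expected):
        assert flag_enriched(fold, p) is expected


class TestStainIndex:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert stain_index(x, x) == 0.0

    def test_hand_computed_value(self):
        control = np.array([100.0 - _MAD_UNIT, 100.0, 100.0 + _MAD_UNIT])
        stained = np.array([300.0])
        # median(control)=100, rSD=1.4826*MAD=10 -> SI=(300-100)/(2*10)=10
        assert stain_index(stained, control) == pytest.approx(10.0)

    def test_constant_control_undefined(self):
        assert math.isnan(stain_index(np.array([300.0]), np.full(10, 100.0)))
        assert math.isnan(stain_index(np.array([]), np.array([1.0, 2.0])))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-1e4, 1e4), st.floats(0.1, 100.0))
    def test_shift_invariance_and_spread_scaling(self, shift, scale):
        control = np.array([80.0, 90.0, 100.0, 110.0, 120.0])
        stained = np.array([250.0, 300.0, 350.0])
        base = stain_index(stained, control)
        shifted = stain_index(stained + shift, control + shift)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        med_c = 100.0
        scaled = stain_index((stained - med_c) * scale + med_c,
                             (control - med_c) * scale + med_c)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_plain_sd_spread_option(self):
        control = np.array([90.0, 100.0, 110.0])
        si = stain_index(np.array([300.0]), control, robust=False)
        assert si == pytest.approx((300 - 100) / (2 * np.std(control, ddof=1)))


class TestSiFold:
    def test_ratios(self):
        assert si_fold(10.0, 10.0) == 1.0
        assert si_fold(20.8, 2.0) == pytest.approx(10.4)

    def test_nonpositive_denominator_undefined(self):
        assert math.isnan(si_fold(5.0, 0.0))
        assert math.isnan(si_fold(5.0, -1.0))
        assert math.isnan(si_fold(float("nan"), 2.0))


class TestBackgroundStats:
    def test_recovers_planted_background_ratio(self):
        # simulated isotype well, populations split by planted labels: the
        # estimated FCS/PLT background ratio matches the configured 13x
        cfg = make_mini_config({"M1": (0.0, 0.0)}, events=50_000, seed=17,
                               debris=0.0, doublet=0.0, dead=0.0)
        events, _ = simulate_well(cfg, "H12", seed=17)
        rep = events.channel("reporter")
        controls = {
            POP_POS: [rep[events.label(f"truth_pop_{POP_POS}")]],
            POP_NEG: [rep[events.label(f"truth_pop_{POP_NEG}")]],
        }
        df = background_stats(controls)
        assert df["ratio_fcs_over_plt"].iloc[0] == pytest.approx(13.0, rel=0.10)

    def test_identical_populations_ratio_near_one(self):
        rng = np.random.default_rng(2)
        a, b = rng.lognormal(5, 0.3, 20_000), rng.lognormal(5, 0.3, 20_000)
        df = background_stats({POP_POS: [a], POP_NEG: [b]})
        assert df["ratio_fcs_over_plt"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_low_n_flagged_and_empty_rejected(self):
        df = background_stats({POP_POS: [np.array([1.0, 2.0, 3.0])],
                               POP_NEG: [np.array([1.0, 2.0, 3.0])]})
        assert df["low_n"].all()
        assert np.isfinite(df["ratio_fcs_over_plt"]).all()
        with pytest.raises(ValueError, match="control"):
            background_stats({})


class TestDdct:
    def test_equal_delta_ct_gives_unit_fold(self):
        assert ddct_fold([20, 20], [18, 18], [25, 25], [23, 23]) == 1.0

    def test_arithmetic_oracle(self):
        # ddCt = (20-18) - (22-18) = -2 -> fold 4
        assert ddct_fold([20.0], [18.0], [22.0], [18.0]) == 4.0
        # one fewer cycle on target in the first condition only -> fold 2
        assert ddct_fold([21.0], [18.0], [22.0], [18.0]) == 2.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            ddct_fold([], [18.0], [22.0], [18.0])
        with pytest.raises(ValueError, match="finite"):
            ddct_fold([float("nan")], [18.0], [22.0], [18.0])


@pytest.fixture(scope="module")
def small_screen():
    from lyoscreen import GateConfig

    cfg = make_mini_config(
        {"EN1": (0.5, 0.2), "EQ1": (0.7, 0.7), "NEG1": (0.0, 0.0)},
        events=20_000, seed=5, n_donors=3, donor_logit_sd=0.05,
    )
    return run_screen(cfg, GateConfig(min_events_per_well=5_000))


class TestPipeline:
    def test_classification_recovers_planted_structure(self, small_screen):
        cls = small_screen.classification
        assert bool(cls.loc["EN1", "enriched"])
        assert bool(cls.loc["EQ1", "positive"]) and not bool(cls.loc["EQ1", "enriched"])
        assert not bool(cls.loc["NEG1", "positive"])
        assert cls.loc["EN1", "fold"] == pytest.approx(2.5, rel=0.15)

    def test_flag_hierarchy(self, small_screen):
        cls = small_screen.classification
        assert (cls["enriched"] <= cls["variable"]).all()
        assert (cls["variable"] <= cls["positive"]).all()
        counts = small_screen.flag_counts()
        assert counts["enriched"] <= counts["variable"] <= counts["positive"] <= counts["markers"]

    def test_pipeline_background_ratio(self, small_screen):
        assert small_screen.background["ratio_fcs_over_plt"].iloc[0] == pytest.approx(
            13.0, rel=0.10)

    def test_stain_index_separates_enriched_marker(self, small_screen):
        cls = small_screen.classification
        assert cls.loc["EN1", "si_plt"] > cls.loc["EN1", "si_fcs"]
        assert cls.loc["EN1", "si_fold"] > 1.0

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_reduced_scale_multi_seed_recovery(self, seed):
        # full 356-marker layout at reduced events/well: all 13 planted
        # enriched markers recovered with at most 2 false positives
        from lyoscreen import GateConfig, default_screen_config

        cfg = default_screen_config(seed=seed, events_per_well=10_000,
                                    n_donors=3, donor_logit_sd=0.05)
        result = run_screen(cfg, GateConfig(min_events_per_well=5_000))
        from lyoscreen.synthetic import default_marker_names

        enriched_true = set(default_marker_names()[0])
        called = set(result.enriched_markers())
        assert len(enriched_true & called) >= 12
        assert len(called - enriched_true) <= 2
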