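"""Gating chain: stage-by-stage recovery of planted contamination fractions,
control-referenced thresholds and barcode demultiplexing."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lyoscreen import (
    ChannelMap,
    DemultiplexError,
    EventTable,
    GateConfig,
    POP_NEG,
    POP_POS,
    demultiplex_barcode,
    exclude_dead,
    exclude_doublets,
    gate_cells,
    gate_well,
    percent_positive,
    qc_well,
    set_positivity_gate,
    simulate_well,
)
from lyoscreen import GateError
from lyoscreen.synthetic import overlap_populations

from conftest import make_mini_config


def _reporter_table(values):
    return EventTable(pd.DataFrame({"APC-A": np.asarray(values, float)}))


def _binomial_3se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestQC:
    @pytest.mark.parametrize("n,expected", [(9_999, False), (10_000, True), (0, False)])
    def test_event_count_floor(self, n, expected):
        events = EventTable(pd.DataFrame({"FSC-A": np.ones(n)}))
        ok, reason = qc_well(events, GateConfig())
        assert ok is expected
        if n == 0:
            assert "empty" in reason


class TestScatterGate:
    def test_planted_debris_fraction_recovered(self, contaminated_well):
        _, events, truth = contaminated_well
        kept = gate_cells(events)
        removed = 1 - len(kept) / len(events)
        planted = truth.n_debris / truth.n_events
        assert abs(removed - planted) <= _binomial_3se(planted, truth.n_events)

    def test_zero_debris_retains_nearly_all(self):
        cfg = make_mini_config({"M1": (0.3, 0.1)}, events=50_000, seed=4,
                               debris=0.0, doublet=0.0, dead=0.0)
        events, _ = simulate_well(cfg, "A1", seed=4)
        kept = gate_cells(events)
        assert len(kept) / len(events) >= 0.995

    def test_empty_input_is_degenerate_not_fatal(self, caplog):
        empty = EventTable(pd.DataFrame({"FSC-A": np.array([], dtype=float)}))
        with caplog.at_level("WARNING", logger="lyoscreen.gating"):
            out = gate_cells(empty)
        assert len(out) == 0
        assert "empty" in caplog.text


class TestSingletGate:
    def test_planted_doublet_fraction_recovered(self, contaminated_well):
        _, events, truth = contaminated_well
        cells = gate_cells(events)
        singlets = exclude_doublets(cells)
        removed = 1 - len(singlets) / len(cells)
        planted = truth.n_doublet / len(cells)
        assert abs(removed - planted) <= _binomial_3se(planted, len(cells))

    def test_no_doublets_high_retention(self):
        cfg = make_mini_config({"M1": (0.3, 0.1)}, events=50_000, seed=9,
                               debris=0.0, doublet=0.0, dead=0.0)
        events, _ = simulate_well(cfg, "A1", seed=9)
        singlets = exclude_doublets(events)
        assert len(singlets) / len(events) >= 0.99

    def test_perfectly_proportional_height_removes_nothing(self):
        a = np.linspace(1_000, 80_000, 500)
        events = EventTable(pd.DataFrame({"FSC-A": a, "FSC-H": a}))
        assert len(exclude_doublets(events)) == 500

    def test_tiny_input_skipped_with_warning(self, caplog):
        events = EventTable(pd.DataFrame({"FSC-A": np.ones(10), "FSC-H": np.ones(10)}))
        with caplog.at_level("WARNING", logger="lyoscreen.gating"):
            out = exclude_doublets(events)
        assert len(out) == 10
        assert "unstable" in caplog.text


class TestLiveGate:
    def test_planted_dead_fraction_recovered(self):
        cfg = make_mini_config({"M1": (0.0, 0.0)}, events=50_000, seed=6,
                               debris=0.0, doublet=0.0, dead=0.10)
        events, truth = simulate_well(cfg, "A1", seed=6)
        ctrl_cfg = make_mini_config({"M1": (0.0, 0.0)}, events=50_000, seed=8,
                                    debris=0.0, doublet=0.0, dead=0.0)
        control, _ = simulate_well(ctrl_cfg, "A1", seed=8)
        live, threshold = exclude_dead(events, control)
        removed = 1 - len(live) / len(events)
        planted = truth.n_dead / truth.n_events
        # removal = planted dead + the 0.1% control-quantile tail of live cells
        assert abs(removed - (planted + 0.001)) <= _binomial_3se(planted, truth.n_events)
        assert np.isfinite(threshold)

    def test_control_identical_to_sample_removes_tail_only(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"DAPI-A": rng.lognormal(4, 0.4, 50_000)})
        events = EventTable(frame, ChannelMap(viability="DAPI-A"))
        live, _ = exclude_dead(events, events)
        removed = 1 - len(live) / len(events)
        assert 0.0005 <= removed <= 0.0015

    def test_all_below_threshold_is_identity(self):
        events = EventTable(pd.DataFrame({"DAPI-A": np.full(200, 10.0)}),
                            ChannelMap(viability="DAPI-A"))
        ctrl = EventTable(pd.DataFrame({"DAPI-A": np.linspace(50, 100, 1_000)}),
                          ChannelMap(viability="DAPI-A"))
        live, _ = exclude_dead(events, ctrl)
        assert len(live) == 200


class TestDemultiplex:
    def test_one_to_one_pool_recovered(self, clean_well):
        _, events, _ = clean_well
        neg, pos, thr = demultiplex_barcode(events)
        assert len(neg) + len(pos) == len(events)
        frac_pos = len(pos) / len(events)
        assert abs(frac_pos - 0.5) <= _binomial_3se(0.5, len(events))
        # agreement with planted population labels should be essentially exact
        truth_pos = events.label(f"truth_pop_{POP_POS}")
        mis = np.mean(truth_pos != (events.channel("barcode") > thr))
        assert mis < 0.001

    def test_fully_labelled_pool_is_unimodal_error(self):
        cfg = make_mini_config({"M1": (0.0, 0.0)}, events=20_000, seed=3,
                               debris=0.0, doublet=0.0, dead=0.0,
                               pooling_ratio=1e9)
        events, _ = simulate_well(cfg, "A1", seed=3)
        with pytest.raises(DemultiplexError, match="unimodal"):
            demultiplex_barcode(events)

    def test_overlap_preset_matches_bayes_misassignment(self):
        # barcode modes 2 common log-SDs apart: the optimal boundary sits at
        # the midpoint and misassigns Phi(-1) = 15.87% of events
        cfg = make_mini_config({"M1": (0.0, 0.0)}, events=50_000, seed=12,
                               populations=overlap_populations(2.0),
                               debris=0.0, doublet=0.0, dead=0.0)
        events, _ = simulate_well(cfg, "A1", seed=12)
        neg, pos, thr = demultiplex_barcode(
            events, GateConfig(barcode_method="otsu"))
        truth_pos = events.label(f"truth_pop_{POP_POS}")
        mis = float(np.mean(truth_pos != (events.channel("barcode") > thr)))
        bayes = float(stats.norm.cdf(-1.0))  # 0.158655
        assert abs(mis - bayes) <= _binomial_3se(bayes, len(events))

    def test_fixed_threshold_method(self, clean_well):
        _, events, _ = clean_well
        neg, pos, thr = demultiplex_barcode(
            events, GateConfig(barcode_method="fixed", barcode_fixed_threshold=2_000.0))
        assert thr == 2_000.0
        assert len(neg) + len(pos) == len(events)


class TestPositivityGate:
    def test_type7_quantile_on_integer_grid(self):
        # brute-force order-statistic oracle on 1..1000 at 0.999:
        # index (n-1)q = 998.001 -> 999 + 0.001*(1000-999) = 999.001
        ctrl = _reporter_table(np.arange(1, 1001, dtype=float))
        assert set_positivity_gate(ctrl, 0.999) == pytest.approx(999.001)

    def test_constant_control_gate_equals_constant(self):
        ctrl = _reporter_table(np.full(500, 42.0))
        assert set_positivity_gate(ctrl, 0.999) == 42.0

    def test_confidence_bounds_control_exceedance(self):
        rng = np.random.default_rng(1)
        ctrl = _reporter_table(rng.lognormal(5, 0.4, 1_000_000))
        thr = set_positivity_gate(ctrl, 0.999)
        frac_above = np.mean(ctrl.channel("reporter") > thr)
        assert frac_above <= 0.001
        assert frac_above == pytest.approx(0.001, abs=2e-4)

    def test_too_few_control_events_rejected(self):
        with pytest.raises(GateError, match="too few"):
            set_positivity_gate(_reporter_table(np.ones(50)), 0.999)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1.0, 1e6), min_size=100, max_size=400),
           st.lists(st.floats(0.5, 0.9999), min_size=2, max_size=6))
    def test_threshold_monotone_in_confidence(self, values, confidences):
        ctrl = _reporter_table(values)
        thresholds = [set_positivity_gate(ctrl, c) for c in sorted(confidences)]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))


class TestPercentPositive:
    def test_counts_strictly_above_threshold(self):
        events = _reporter_table([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        assert percent_positive(events, 7) == 30.0  # 8, 9, 10
        assert percent_positive(events, 10) == 0.0  # ties are negative
        assert percent_positive(events, 0.5) == 100.0

    def test_empty_input_flagged_undefined(self):
        assert np.isnan(percent_positive(_reporter_table([]), 1.0))


class TestGateWell:
    def test_stage_monotonicity_and_partition(self, contaminated_well):
        _, events, _ = contaminated_well
        gated = gate_well(events)
        c = gated.result.counts
        assert c["total"] >= c["non_debris"] >= c["singlet"] >= c["live"]
        assert c[POP_POS] + c[POP_NEG] == c["live"]
        assert gated.qc_pass

    def test_deterministic_thresholds_and_counts(self, contaminated_well):
        _, events, _ = contaminated_well
        a = gate_well(events)
        b = gate_well(events)
        assert a.result.counts == b.result.counts
        assert a.result.barcode_threshold == b.result.barcode_threshold

    def test_percent_positive_recovery_on_clean_wells(self):
        # control-referenced gates recover planted positive fractions within
        # 3 binomial SEs once the (1-confidence) control leak is accounted for
        cfg = make_mini_config({"M1": (0.6, 0.2), "M2": (0.08, 0.3)},
                               events=50_000, seed=21,
                               debris=0.0, doublet=0.0, dead=0.0)
        iso_events, _ = simulate_well(cfg, "H12", seed=99)
        iso = gate_well(iso_events)
        thresholds = {pop: set_positivity_gate(sub, 0.999)
                      for pop, sub in iso.populations.items()}
        for well, name in (("A1", "M1"), ("A2", "M2")):
            events, truth = simulate_well(cfg, well, seed=33)
            gated = gate_well(events, positivity_thresholds=thresholds)
            for pop, sub in gated.populations.items():
                planted = truth.per_population[pop]["positive_fraction"]
                expected = planted + (1 - planted) * 0.001
                est = gated.result.pct_positive[pop] / 100.0
                assert abs(est - expected) <= _binomial_3se(expected, len(sub)), (name, pop)
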