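import numpy as np
import pandas as pd
import pytest

from avnet import ModelParams, TrialRecord, auditory_bias, detect_rt, perceived_position
from avnet.experiments import (
    run_bias_vs_isi,
    run_sensitivity,
    run_singles,
    run_switch_pairs,
    run_sw_grid,
    run_ventriloquism,
    rt_summary,
    run_rt_task,
)


class TestDetectRt:
    def make_trace(self, dt, pairs, t_end):
        """Piecewise-linear synthetic premotor trace from (t, value) knots."""
        t = np.arange(0.0, t_end, dt)
        knots_t, knots_v = zip(*pairs)
        return np.interp(t, knots_t, knots_v)

    def test_simple_crossing(self):
        trace = self.make_trace(1.0, [(0, 0), (100, 0), (350, 0.6)], 500)
        # linear rise 0 -> 0.6 over 250 ms crosses 0.30 at onset + 125
        assert detect_rt(trace, 1.0, 100.0) == pytest.approx(225.0 - 100.0, abs=1.0)

    def test_subthreshold_trace_gives_none(self):
        trace = self.make_trace(1.0, [(0, 0), (200, 0.29), (400, 0.29)], 500)
        assert detect_rt(trace, 1.0, 50.0) is None

    def test_anticipatory_crossing_is_reported(self):
        trace = self.make_trace(0.5, [(0, 0), (100, 0), (140, 0.8)], 300)
        rt = detect_rt(trace, 0.5, 100.0)
        assert rt == pytest.approx(15.0, abs=1.0)
        rec = TrialRecord("SwA", rt_ms=rt, anticipatory=rt < 100.0, no_response=False)
        assert rec.anticipatory

    def test_waits_for_previous_response_to_fall(self):
        trace = self.make_trace(1.0, [(0, 0), (50, 0.9), (200, 0.9),
                                      (250, 0.0), (400, 0.0), (500, 0.9)], 600)
        rt = detect_rt(trace, 1.0, 150.0)
        # above threshold at onset: the tail is skipped, the next upward
        # crossing (~433 ms) is the response
        assert 250.0 < rt < 350.0

    def test_onset_outside_trace_rejected(self):
        trace = np.zeros(100)
        with pytest.raises(ValueError):
            detect_rt(trace, 1.0, 200.0)

    def test_response_window_enforced(self):
        trace = self.make_trace(1.0, [(0, 0), (800, 0), (900, 0.9)], 1000)
        assert detect_rt(trace, 1.0, 100.0, response_window_ms=500.0) is None

    def test_2d_traces_reduce_over_units(self):
        t2 = np.zeros((300, 4))
        t2[150:, 2] = 0.9
        assert detect_rt(t2, 1.0, 100.0) == pytest.approx(50.0, abs=1.5)


class TestPerceivedPosition:
    def test_point_masses(self, positions):
        a = np.zeros(180)
        a[100] = 0.7  # unit at +10 deg
        assert perceived_position(a, positions) == pytest.approx(10.0)
        a[90] = 0.7
        assert perceived_position(a, positions) == pytest.approx(5.0)

    def test_weighted_mean(self, positions):
        a = np.zeros(180)
        a[90], a[95] = 0.2, 0.6
        assert perceived_position(a, positions) == pytest.approx(3.75)

    def test_no_percept_for_silent_area(self, positions):
        assert perceived_position(np.zeros(180), positions) is None


class TestAuditoryBias:
    def test_endpoints_and_worked_example(self):
        assert auditory_bias(10.0, true_a=10.0, true_v=0.0) == 0.0
        assert auditory_bias(0.0, true_a=10.0, true_v=0.0) == 100.0
        assert auditory_bias(6.5, true_a=10.0, true_v=0.0) == pytest.approx(35.0)

    def test_zero_disparity_undefined(self):
        with pytest.raises(ValueError):
            auditory_bias(1.0, true_a=0.0, true_v=0.0)


class TestProtocolsSmoke:
    """Small-n runs of each protocol; the full-scale statistical checks live in
    the acceptance suite."""

    def test_ventriloquism_shape_and_symmetry(self, params):
        trials = run_ventriloquism(params, disparities_deg=(10.0,), n_reps=6,
                                   seed=2, keep_trials=True)
        assert set(trials.disparity_deg) == {10.0, -10.0}
        assert trials.bias_pct.notna().all()
        table = run_ventriloquism(params, disparities_deg=(10.0,), n_reps=6, seed=2)
        assert list(table.columns) == ["abs_disparity_deg", "mean_bias_pct",
                                       "sem_bias_pct", "n"]
        assert table.n.iloc[0] == 12

    def test_bias_vs_isi_consistent_with_synchronous_protocol(self, params):
        sync = run_ventriloquism(params, disparities_deg=(5.0,), n_reps=8, seed=3)
        zero_isi = run_bias_vs_isi(params, isis_ms=(0.0,), disparities_deg=(5.0,),
                                   n_reps=8, seed=3)
        assert zero_isi.mean_bias_pct.iloc[0] == pytest.approx(
            sync.mean_bias_pct.iloc[0], abs=2.0)

    def test_sw_grid_records_every_cell(self, params):
        g = run_sw_grid(params, isis_ms=(0.0, 200.0), disparities_deg=(0.0, 20.0),
                        n_reps=4, seed=4)
        assert len(g) == 4
        assert (g.n > 0).all()

    def test_switch_pairs_labels_balanced(self, params):
        pairs = run_switch_pairs(params, n_reps=3, seed=5, isi_low_ms=1000.0,
                                 isi_high_ms=1200.0)
        counts = pairs.groupby("label").size()
        for label in ("RpA", "SwA", "RpV", "SwV", "RpAV", "SwA->AV", "SwV->AV"):
            assert counts[label] == 3

    def test_rt_task_covers_seven_configurations(self, params):
        records = run_rt_task(params, n_valid_per_config=2, seq_len=12, seed=6)
        summary = rt_summary(records)
        assert set(summary.index) == {"RpA", "SwA", "RpV", "SwV", "RpAV",
                                      "SwA->AV", "SwV->AV"}
        assert (summary.n >= 2).all()
        valid = records[~records.anticipatory & ~records.no_response]
        assert (valid.rt_ms > 0).all()

    def test_sensitivity_sweep_grids(self, params):
        table = run_sensitivity(params, wva0_values=(0.12,), lin0_values=(4.0,),
                                n_reps=3, seed=7)
        assert list(table.sweep) == ["wva0", "lin0"]
        verb = run_sensitivity(params, n_reps=1, seed=7, verbatim_wva0=True)
        assert set(verb[verb.sweep == "wva0"].value) == {0.08, 0.012, 0.016}

    def test_singles_rt_ordering(self, params):
        s = run_singles(params, n_reps=25, seed=8)
        means = s[~s.no_response].groupby("label").rt_ms.mean()
        assert means["AV"] < means["A"] < means["V"]
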