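import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from avnet.analysis import (
    RtCdf,
    benefit_area,
    empirical_cdf,
    multisensory_gain,
    pooled_percentile_grid,
    raab_race_cdf,
    switch_cost,
)

rt_samples = st.lists(st.floats(min_value=80.0, max_value=900.0), min_size=1, max_size=60)


class TestEmpiricalCdf:
    def test_basic_proportions(self):
        cdf = empirical_cdf([200.0, 300.0], grid_ms=[150.0, 250.0, 350.0])
        assert list(cdf.prob) == [0.0, 0.5, 1.0]

    def test_single_rt_is_step_function(self):
        cdf = empirical_cdf([250.0], grid_ms=[249.0, 250.0, 251.0])
        assert list(cdf.prob) == [0.0, 1.0, 1.0]

    @settings(max_examples=100, deadline=None)
    @given(rt_samples)
    def test_matches_counting_oracle(self, rts):
        grid = np.linspace(50, 1000, 21)
        cdf = empirical_cdf(rts, grid)
        brute = np.array([np.mean([r <= t for r in rts]) for t in grid])
        assert np.allclose(cdf.prob, brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([], [100.0])


class TestRaabRace:
    def test_independence_formula(self):
        g = np.array([1.0, 2.0, 3.0])
        a = RtCdf(g, np.array([0.3, 0.5, 1.0]), 10)
        v = RtCdf(g, np.array([0.0, 0.5, 1.0]), 10)
        race = raab_race_cdf(a, v)
        assert race.prob[0] == pytest.approx(0.3)   # (p, 0) -> p
        assert race.prob[1] == pytest.approx(0.75)  # (0.5, 0.5) -> 0.75
        assert race.prob[2] == pytest.approx(1.0)   # (1, 1) -> 1

    @settings(max_examples=100, deadline=None)
    @given(rt_samples, rt_samples)
    def test_race_dominates_both_unisensory_cdfs(self, rts_a, rts_v):
        grid = pooled_percentile_grid(rts_a, rts_v)
        a, v = empirical_cdf(rts_a, grid), empirical_cdf(rts_v, grid)
        race = raab_race_cdf(a, v)
        assert np.all(race.prob >= np.maximum(a.prob, v.prob) - 1e-12)

    def test_shared_grid_required(self):
        a = RtCdf(np.array([1.0, 2.0]), np.array([0.1, 0.2]), 5)
        v = RtCdf(np.array([1.0, 3.0]), np.array([0.1, 0.2]), 5)
        with pytest.raises(ValueError):
            raab_race_cdf(a, v)


class TestAreas:
    def test_zero_when_upper_equals_envelope(self):
        g = np.linspace(100, 400, 7)
        a = RtCdf(g, np.linspace(0, 1, 7), 10)
        v = RtCdf(g, np.linspace(0, 0.8, 7), 10)
        assert benefit_area(a, a, v) == pytest.approx(0.0)

    def test_rectangle_area(self):
        # upper exceeds the envelope by 0.1 over a 100-ms span
        g = np.array([0.0, 100.0])
        upper = RtCdf(g, np.array([0.1, 0.1]), 10)
        lo = RtCdf(g, np.array([0.0, 0.0]), 10)
        assert benefit_area(upper, lo, lo) == pytest.approx(10.0)

    def test_negative_differences_clamped(self):
        g = np.array([0.0, 100.0])
        below = RtCdf(g, np.array([0.0, 0.5]), 10)
        env = RtCdf(g, np.array([0.2, 0.9]), 10)
        assert benefit_area(below, env, env) == 0.0
        assert multisensory_gain(below, env) == 0.0

    def test_gain_stable_under_grid_refinement(self):
        rng = np.random.default_rng(0)
        rts_a = rng.normal(300, 30, 400)
        rts_v = rng.normal(320, 30, 400)
        rts_av = rng.normal(270, 25, 400)
        gains = []
        for n_grid in (40, 400):
            grid = np.linspace(150, 450, n_grid)
            race = raab_race_cdf(empirical_cdf(rts_a, grid), empirical_cdf(rts_v, grid))
            gains.append(multisensory_gain(empirical_cdf(rts_av, grid), race))
        assert gains[0] == pytest.approx(gains[1], rel=0.05)

    def test_gain_bounded_by_benefit_when_race_dominates_envelope(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(150, 450, 30)
        a = empirical_cdf(rng.normal(300, 30, 200), grid)
        v = empirical_cdf(rng.normal(320, 30, 200), grid)
        av = empirical_cdf(rng.normal(270, 25, 200), grid)
        race = raab_race_cdf(a, v)
        assert multisensory_gain(av, race) <= benefit_area(av, a, v) + 1e-9


class TestSwitchCost:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["label", "rt_ms"])

    def test_arithmetic(self):
        rows = [("SwA", 400), ("RpA", 350), ("SwV", 400), ("RpV", 350)]
        assert switch_cost(self.frame(rows)) == pytest.approx(50.0)

    def test_identical_distributions_give_zero(self):
        rows = [("SwA", 300), ("RpA", 300), ("SwV", 280), ("RpV", 280)]
        assert switch_cost(self.frame(rows)) == 0.0

    def test_modality_asymmetric_costs_average(self):
        rows = [("SwA", 340), ("RpA", 300), ("SwV", 360), ("RpV", 300)]
        assert switch_cost(self.frame(rows)) == pytest.approx(50.0)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            switch_cost(self.frame([("SwA", 300), ("RpA", 280)]))


class TestRtCdfInvariants:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            RtCdf(np.array([1.0, 2.0]), np.array([0.5, 0.4]), 3)
        with pytest.raises(ValueError):
            RtCdf(np.array([2.0, 1.0]), np.array([0.1, 0.2]), 3)
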