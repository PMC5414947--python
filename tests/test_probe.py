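"""Probe-line Monte Carlo engine and its oracles."""

import numpy as np
import pandas as pd
import pytest

from avrescue import (
    EmpiricalDistribution,
    ProbeLineModel,
    SpeedLaw,
    default_survival_curve,
    run_area_sweep,
    search_speed,
)
from avrescue.probe import ProbeLineResults, default_depth_grid


class TestSearchSpeed:
    def test_published_endpoints(self):
        assert search_speed(0.5) == pytest.approx(13.0)
        assert search_speed(2.5) == pytest.approx(1.5)

    def test_power_law_value_at_one_metre(self):
        # 13 * (0.5/1.0)**beta with beta = ln(13/1.5)/ln(5)
        assert search_speed(1.0) == pytest.approx(5.129, abs=1e-3)

    def test_monotone_decreasing(self):
        d = np.linspace(0.5, 2.5, 201)
        v = search_speed(d)
        assert np.all(np.diff(v) < 0)

    def test_clamped_outside_range_and_positive_domain(self):
        assert search_speed(0.3) == pytest.approx(13.0)
        assert search_speed(3.0) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            search_speed(-0.1)

    def test_custom_law_endpoints(self):
        law = SpeedLaw(v_shallow=10.0, v_deep=2.0)
        assert search_speed(0.5, law) == pytest.approx(10.0)
        assert search_speed(2.5, law) == pytest.approx(2.0)


@pytest.fixture()
def point_mass_model():
    return ProbeLineModel(EmpiricalDistribution([1.0]), area_m2=5000, n_rescuers=20)


class TestSimulateRun:
    def test_miss_rule_sets_survival_to_zero(self, point_mass_model, rng):
        s = point_mass_model.simulate_run(0.9, rng)
        assert not s.found and s.p_survival == 0.0

    def test_tie_counts_as_found(self, point_mass_model, rng):
        s = point_mass_model.simulate_run(1.0, rng)
        assert s.found

    def test_time_decomposition(self, point_mass_model, rng):
        s = point_mass_model.simulate_run(1.5, rng)
        assert s.t_total_min == pytest.approx(s.t_search_min + s.t_dig_min)
        assert s.t_dig_min == pytest.approx(1.0 / 0.15)

    def test_vanishing_area_gives_closed_form(self, rng):
        d0 = 1.2
        m = ProbeLineModel(EmpiricalDistribution([d0]), area_m2=1e-9)
        s = m.simulate_run(2.0, rng)
        expected = default_survival_curve().survival_at(d0 / 0.15)
        assert s.p_survival == pytest.approx(expected, abs=1e-6)


class TestRunGrid:
    def test_mean_matches_quadrature_oracle_on_point_mass(self):
        """MC mean at a degenerate depth equals 1-D quadrature over position."""
        d0 = 1.0
        m = ProbeLineModel(EmpiricalDistribution([d0]), area_m2=5000, n_rescuers=20)
        res = m.fit(n_runs=20_000, seed=11)
        curve = default_survival_curve()
        for pd_m in (1.0, 1.5, 2.5):
            v = search_speed(pd_m)
            xs = (np.arange(20_000) + 0.5) / 20_000 * m.strip_length_m
            oracle = curve.survival_at(xs / (v * 20) + d0 / 0.15).mean()
            row = res.table.loc[pd_m]
            assert abs(row["mean_survival"] - oracle) < 3 * row["se_mean"]

    def test_miss_fraction_matches_distribution_tail(self, depth_dist):
        m = ProbeLineModel(depth_dist, area_m2=5000, n_rescuers=20)
        res = m.fit(n_runs=10_000, seed=3)
        for pd_m in (0.5, 1.0, 2.0):
            p = depth_dist.tail_fraction(pd_m)
            se = np.sqrt(max(p * (1 - p), 1e-12) / 10_000)
            assert abs(res.table.loc[pd_m, "miss_fraction"] - p) <= 3 * se + 1e-12

    def test_miss_fraction_non_increasing_in_depth(self, depth_dist):
        res = ProbeLineModel(depth_dist, area_m2=1000).fit(n_runs=4000, seed=5)
        assert np.all(np.diff(res.miss_fraction.to_numpy()) <= 0)

    def test_mean_survival_bounded_by_find_probability(self, depth_dist):
        res = ProbeLineModel(depth_dist, area_m2=5000, n_rescuers=20).fit(
            n_runs=4000, seed=6
        )
        smax = default_survival_curve().probabilities.max()
        assert np.all(
            res.mean_survival.to_numpy()
            <= (1 - res.miss_fraction.to_numpy()) * smax + 1e-12
        )

    def test_fixed_seed_bit_identical(self, depth_dist):
        m = ProbeLineModel(depth_dist, area_m2=500)
        a = m.fit(n_runs=2000, seed=42)
        b = m.fit(n_runs=2000, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_run_doubling_convergence(self, depth_dist):
        """Doubling the runs moves each mean by < 3 pooled standard errors."""
        m = ProbeLineModel(depth_dist, area_m2=5000, n_rescuers=20)
        r1 = m.fit(n_runs=5000, seed=21)
        r2 = m.fit(n_runs=10_000, seed=22)
        pooled = np.sqrt(r1.table["se_mean"] ** 2 + r2.table["se_mean"] ** 2)
        assert np.all(
            np.abs(r1.table["mean_survival"] - r2.table["mean_survival"])
            < 3 * pooled + 1e-12
        )


class TestOptimalDepth:
    def _results_with_survival(self, depth_dist, values):
        m = ProbeLineModel(depth_dist, area_m2=100, depth_grid_m=[1.7, 1.8, 1.9, 2.0])
        table = pd.DataFrame(
            {
                "depth_m": [1.7, 1.8, 1.9, 2.0],
                "mean_survival": values,
                "se_mean": 0.0,
                "miss_fraction": 0.0,
            }
        ).set_index("depth_m")
        return ProbeLineResults(m, table, 1, 0, 0.0)

    def test_unique_argmax(self, depth_dist):
        r = self._results_with_survival(depth_dist, [0.1, 0.2, 0.5, 0.3])
        assert r.optimal_depth_m == 1.9

    def test_tie_breaks_to_smallest_depth(self, depth_dist):
        r = self._results_with_survival(depth_dist, [0.1, 0.5, 0.5, 0.3])
        assert r.optimal_depth_m == 1.8

    def test_shallow_point_mass_optimum_is_first_covering_depth(self):
        dist = EmpiricalDistribution([0.72])
        res = ProbeLineModel(dist, area_m2=50, n_rescuers=5).fit(
            n_runs=2000, seed=8
        )
        # any depth >= 0.72 finds the subject; deeper only slows the line
        assert res.optimal_depth_m == pytest.approx(0.8)


class TestAreaSweep:
    def test_reproducible_and_policy_applied(self, depth_dist):
        areas = [100, 5000]
        s1 = run_area_sweep(areas, depth_dist, n_runs=2000, seed=4)
        s2 = run_area_sweep(areas, depth_dist, n_runs=2000, seed=4)
        for a in areas:
            pd.testing.assert_frame_equal(s1[a].table, s2[a].table)
        assert s1[100].model.n_rescuers == 5
        assert s1[5000].model.n_rescuers == 20

    def test_fixed_crew_override(self, depth_dist):
        s = run_area_sweep([100], depth_dist, rescuer_policy=7, n_runs=500, seed=1)
        assert s[100].model.n_rescuers == 7

    def test_invalid_model_parameters_rejected(self, depth_dist):
        with pytest.raises(ValueError):
            ProbeLineModel(depth_dist, area_m2=-5)
        with pytest.raises(ValueError):
            ProbeLineModel(depth_dist, area_m2=100, n_rescuers=0)
        with pytest.raises(ValueError):
            ProbeLineModel(depth_dist, area_m2=100, depth_grid_m=[1.0, 0.5])

    def test_default_grid_is_21_points(self):
        g = default_depth_grid()
        assert g.size == 21 and g[0] == 0.5 and g[-1] == 2.5
        assert np.allclose(np.diff(g), 0.1)
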