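"""Quantification pipeline: distributions, laws, benchmarks, recovery."""
import numpy as np
import pytest
from scipy import stats

import thallus as th
from thallus.mesh import MeshError
from thallus.metrics import (benchmarks_table, division_statistics,
                             neighbor_mean_sides, report)
from conftest import center_cell


class TestSideDistribution:
    def test_honeycomb_all_hexagons(self, honeycomb19):
        hist, mean = th.side_distribution(honeycomb19)
        assert hist == {6: 1.0} and mean == 6.0

    def test_periodic_square_mean_four(self):
        t = th.build_lattice("square", 4, 4, periodic=True)
        _, mean = th.side_distribution(t)
        assert mean == 4.0

    def test_no_interior_cells_rejected(self):
        from test_mesh import unit_polygon_cell
        t, _ = unit_polygon_cell([(0, 0), (1, 0), (1, 1), (0, 1)])
        with pytest.raises(MeshError, match="no interior"):
            th.side_distribution(t)

    def test_histogram_sums_to_one(self, small_run):
        hist, _ = th.side_distribution(small_run.final)
        assert sum(hist.values()) == pytest.approx(1.0, abs=1e-9)


class TestAngleDistribution:
    def test_honeycomb_all_120(self, honeycomb19):
        s = th.angle_distribution(honeycomb19)
        assert s.mean == pytest.approx(120.0)
        assert s.frac_in == 1.0
        # 120.0 sits on a bin edge; float noise may land either side of it
        assert s.histogram[110.0] + s.histogram[120.0] == pytest.approx(1.0)

    def test_square_lattice_interior_all_90(self):
        t = th.build_lattice("square", 4, 4)
        s = th.angle_distribution(t)
        assert s.mean == pytest.approx(90.0)
        assert s.frac_in == 0.0


class TestAngleIdentity:
    @pytest.mark.parametrize("mean_sides,expected", [(6, 120.0), (5, 108.0)])
    def test_algebraic_identity(self, mean_sides, expected):
        assert 180.0 * (1 - 2 / mean_sides) == pytest.approx(expected)

    def test_two_routes_agree_on_honeycomb(self, honeycomb19):
        direct = th.angle_distribution(honeycomb19).mean
        identity = th.mean_interior_angle_identity(honeycomb19)
        assert identity == pytest.approx(direct, abs=1e-9)

    def test_two_routes_agree_on_simulation(self, small_run):
        t = small_run.final
        direct = th.angle_distribution(t).mean
        identity = th.mean_interior_angle_identity(t)
        assert identity == pytest.approx(direct, abs=1e-6)


class TestLewisFit:
    def test_single_class_rejected(self, honeycomb19):
        with pytest.raises(MeshError, match="3 side classes"):
            th.lewis_fit(honeycomb19)

    def test_matches_brute_force_groupby_regression(self, small_run):
        t = small_run.final
        interior = sorted(th.interior_cells(t))
        by_n = {}
        for c in interior:
            by_n.setdefault(th.cell_sides(t, c), []).append(t.cell_area(c))
        means = {n: np.mean(a) for n, a in by_n.items() if len(a) >= 5}
        assert len(means) >= 3, "fixture run too small for a Lewis fit"
        ns = np.array(sorted(means))
        ys = np.array([means[n] for n in ns])
        # closed-form least squares, independent of scipy
        slope = ((ns - ns.mean()) * (ys - ys.mean())).sum() / ((ns - ns.mean()) ** 2).sum()
        fit = th.lewis_fit(t)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.classes == pytest.approx(means)

    def test_planted_linear_relation_recovered(self):
        # regression helper on a planted exact line area(n) = c (n - 2)
        from thallus.metrics import _fit_line
        c = 37.5
        ns = [4, 5, 6, 7, 8]
        slope, intercept, r2 = _fit_line(ns, [c * (n - 2) for n in ns])
        assert slope == pytest.approx(c)
        assert intercept == pytest.approx(-2 * c)
        assert r2 == pytest.approx(1.0)

    def test_mature_simulation_has_positive_slope(self, small_run):
        fit = th.lewis_fit(small_run.final)
        assert fit.slope > 0


class TestAboavWeaire:
    def test_honeycomb_m6_is_6(self):
        t = th.build_honeycomb(3)
        m = neighbor_mean_sides(t)
        assert m == {6: pytest.approx(6.0)}

    def test_matches_brute_force_neighbor_averaging(self, small_run):
        t = small_run.final
        inc = t.inc
        sides = {c: th.cell_sides(t, c) for c in t.cells}
        by_n = {}
        for c in sorted(th.interior_cells(t)):
            nbrs = set()
            cyc = t.cells[c]
            for i in range(len(cyc)):
                for o in inc.wall_cells[t.wall_between(cyc[i], cyc[(i + 1) % len(cyc)])]:
                    if o != c:
                        nbrs.add(o)
            by_n.setdefault(sides[c], []).append(np.mean([sides[x] for x in nbrs]))
        expected = {n: np.mean(v) for n, v in by_n.items() if len(v) >= 5}
        assert neighbor_mean_sides(t) == pytest.approx(expected)

    def test_mn_decreasing_in_n(self, small_run):
        m = neighbor_mean_sides(small_run.final, min_cells_per_class=3)
        ns = sorted(m)
        if len(ns) >= 3:
            assert stats.spearmanr(ns, [m[n] for n in ns]).statistic < 0


class TestDivisionStatistics:
    def test_single_midpoint_division_of_hexagon(self, honeycomb19, rng):
        rule = th.DivisionRule(cut_tilt_sd_deg=0, cut_shift_frac=0,
                               connected_pair_prob=0)
        _, ev = th.divide_cell(honeycomb19, center_cell(honeycomb19), rule, rng)
        s = division_statistics([ev])
        assert s.ds_mean == pytest.approx(0.0)
        assert s.sr_mean == pytest.approx(1.0)
        assert s.interval_histogram == {2: 1.0}
        assert s.unconnected_frac == 1.0

    def test_empty_log_rejected(self):
        with pytest.raises(MeshError, match="empty"):
            division_statistics([])

    def test_unconnected_fraction_binomial_check(self, small_run):
        s = division_statistics(small_run.events)
        p = 1 - small_run.config.rule.connected_pair_prob
        sigma = (p * (1 - p) / s.n_events) ** 0.5
        assert abs(s.unconnected_frac - p) <= 3 * sigma + 1e-12

    def test_planted_tilt_recovered_within_three_se(self, rng):
        """Parameter recovery: DS mean of a generated log matches an
        independent direct sampler of the same cleavage-plane model."""
        tilt = 12.0
        rule = th.DivisionRule(cut_tilt_sd_deg=tilt, cut_shift_frac=0,
                               connected_pair_prob=0)
        ds_sim = []
        for k in range(250):
            t = th.build_honeycomb(1)
            _, ev = th.divide_cell(t, center_cell(t), rule,
                                   np.random.default_rng(k))
            ds_sim.extend(ev.ds_values)
        # independent oracle: rotate the mid-chord of a regular hexagon
        # about its centre and intersect with the cut walls analytically
        g = np.random.default_rng(999)
        ds_ref = []
        s = 10.0
        for _ in range(4000):
            th_ = np.radians(tilt) * g.standard_normal()
            # opposite mid-edges of a regular hexagon are 2*apothem apart
            apothem = s * np.sqrt(3) / 2
            offset = apothem * np.tan(th_)        # along each cut wall, µm
            ds_ref.append(min(abs(offset) / s, 0.45))
        ds_sim, ds_ref = np.array(ds_sim), np.array(ds_ref)
        se = np.sqrt(ds_sim.var() / len(ds_sim) + ds_ref.var() / len(ds_ref))
        assert abs(ds_sim.mean() - ds_ref.mean()) < 3 * se


class TestReport:
    def test_honeycomb_report(self, honeycomb19):
        rep = report(honeycomb19)
        assert rep.frac_sides_5_7 == 1.0
        assert rep.mean_sides == 6.0
        assert rep.junction_3fold_frac == 1.0
        assert rep.length_class == "short"
        assert rep.angle_identity_mean == pytest.approx(rep.mean_angle)

    def test_benchmarks_table_structure(self, honeycomb19):
        table = benchmarks_table(report(honeycomb19))
        assert list(table.columns) == ["metric", "value",
                                       "paper_reference_interval", "pass"]
        assert set(table.metric) == set(th.PAPER_BENCHMARKS)
        row = table.set_index("metric").loc["frac_sides_5_7"]
        assert row["pass"] and row["value"] == 1.0

    def test_trajectory_report_includes_division_stats(self, small_run):
        rep = report(small_run)
        assert rep.division is not None
        assert rep.division.n_events == len(small_run.events)

    def test_boundary_cells_do_not_change_report(self, honeycomb19):
        # metrics are computed over interior cells only: growing the ring
        # of boundary cells around the same interior leaves them unchanged
        rep = report(honeycomb19)
        assert rep.n_interior_cells == 7
        assert rep.mean_sides == 6.0 and rep.mean_angle == pytest.approx(120.0)
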