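"""Cleavage rules: DS/SR arithmetic, pair selection, division surgery."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import thallus as th
from thallus.division import DivisionError, DivisionRule
from conftest import center_cell


def hexagon_walls(t, cid):
    cyc = t.cells[cid]
    return [t.wall_between(cyc[i], cyc[(i + 1) % len(cyc)])
            for i in range(len(cyc))]


class TestDivisionSection:
    @pytest.mark.parametrize("s1,s2,expected", [
        (5, 5, 0.0), (3, 7, 0.2), (1, 3, 0.25),
    ])
    def test_printed_formula(self, s1, s2, expected):
        assert th.division_section(s1, s2) == pytest.approx(expected)

    def test_symmetry_and_errors(self):
        assert th.division_section(3, 7) == pytest.approx(
            th.division_section(7, 3))
        with pytest.raises(DivisionError):
            th.division_section(0, 5)

    @given(st.floats(0.01, 100), st.floats(0.01, 100),
           st.floats(1e-3, 1e3))
    def test_scale_invariance(self, s1, s2, c):
        assert th.division_section(c * s1, c * s2) == pytest.approx(
            th.division_section(s1, s2), abs=1e-12)


class TestSizeRatio:
    @pytest.mark.parametrize("a1,a2,expected", [
        (100, 100, 1.0), (50, 100, 0.5), (100, 50, 0.5),
    ])
    def test_order_invariance(self, a1, a2, expected):
        assert th.size_ratio(a1, a2) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(DivisionError):
            th.size_ratio(-1, 5)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, a1, a2, c):
        assert th.size_ratio(c * a1, c * a2) == pytest.approx(
            th.size_ratio(a1, a2), abs=1e-12)


class TestIntervalSides:
    def test_hexagon_cases(self, honeycomb7):
        cid = center_cell(honeycomb7)
        w = hexagon_walls(honeycomb7, cid)
        assert th.interval_sides(honeycomb7, cid, w[0], w[3]) == 2
        assert th.interval_sides(honeycomb7, cid, w[0], w[1]) == 0
        assert th.interval_sides(honeycomb7, cid, w[0], w[2]) == 1

    def test_pentagon_min_of_both_directions(self):
        from test_mesh import unit_polygon_cell
        import math
        ang = np.linspace(0, 2 * math.pi, 6)[:-1]
        t, _ = unit_polygon_cell(np.column_stack([np.cos(ang), np.sin(ang)]) * 10)
        cid = next(iter(t.cells))
        w = hexagon_walls(t, cid)
        assert th.interval_sides(t, cid, w[0], w[2]) == 1   # min(1, 2)

    def test_wall_not_on_cell_rejected(self, honeycomb7):
        cid = center_cell(honeycomb7)
        boundary_wall = next(iter(honeycomb7.inc.boundary_walls))
        w = hexagon_walls(honeycomb7, cid)
        with pytest.raises(DivisionError, match="not on the boundary"):
            th.interval_sides(honeycomb7, cid, w[0], boundary_wall)


class TestSelectDivisionPair:
    def test_hexagon_paper_mode_picks_opposite_pair(self, honeycomb7, rng):
        cid = center_cell(honeycomb7)
        rule = DivisionRule(connected_pair_prob=0)
        wa, wb = th.select_division_pair(honeycomb7, cid, rule, rng)
        assert th.interval_sides(honeycomb7, cid, wa, wb) == 2

    def test_square_paper_mode_picks_opposite_pair(self, rng):
        from test_mesh import unit_polygon_cell
        t, _ = unit_polygon_cell([(0, 0), (10, 0), (10, 10), (0, 10)])
        cid = next(iter(t.cells))
        wa, wb = th.select_division_pair(t, cid, DivisionRule(connected_pair_prob=0), rng)
        assert th.interval_sides(t, cid, wa, wb) == 1

    def test_uniform_pair_connected_probability(self, honeycomb7, rng):
        cid = center_cell(honeycomb7)
        rule = DivisionRule(pair_selection="uniform_pair")
        draws = 100_000
        connected = 0
        for _ in range(draws):
            wa, wb = th.select_division_pair(honeycomb7, cid, rule, rng)
            connected += th.interval_sides(honeycomb7, cid, wa, wb) == 0
        p, phat = 6 / 15, connected / draws
        sigma = (p * (1 - p) / draws) ** 0.5
        assert abs(phat - p) < 3 * sigma

    def test_triangle_rejected_in_paper_mode(self, rng):
        from test_mesh import unit_polygon_cell
        t, _ = unit_polygon_cell([(0, 0), (10, 0), (5, 9)])
        with pytest.raises(DivisionError, match=">= 4"):
            th.select_division_pair(t, next(iter(t.cells)),
                                    DivisionRule(connected_pair_prob=0), rng)


class TestDivideCell:
    def test_honeycomb_center_accounting(self, honeycomb19, rng):
        t = honeycomb19
        cid = center_cell(t)
        f0, e0, v0 = t.counts
        sides0 = sum(len(c) for c in t.cells.values())
        rule = DivisionRule(connected_pair_prob=0)
        t, ev = th.divide_cell(t, cid, rule, rng)
        f1, e1, v1 = t.counts
        assert (f1 - f0, e1 - e0, v1 - v0) == (1, 3, 2)
        assert sum(len(c) for c in t.cells.values()) - sides0 == 6
        assert th.euler_characteristic(t) == 1
        assert th.validate(t).passed
        degs = t.inc.junction_walls
        assert all(len(degs[j]) == 3 for j in ev.new_junctions)

    def test_neighbors_gain_one_side_each(self, honeycomb19, rng):
        t = honeycomb19
        cid = center_cell(t)
        before = {c: len(cyc) for c, cyc in t.cells.items()}
        t, ev = th.divide_cell(t, cid, DivisionRule(connected_pair_prob=0), rng)
        gained = [c for c in before if c in t.cells
                  and len(t.cells[c]) == before[c] + 1]
        unchanged = [c for c in before if c in t.cells
                     and len(t.cells[c]) == before[c]]
        assert len(gained) == 2 and len(gained) + len(unchanged) == len(before) - 1

    def test_daughters_partition_mother_area(self, honeycomb19, rng):
        t = honeycomb19
        cid = center_cell(t)
        area0 = t.cell_area(cid)
        t, ev = th.divide_cell(t, cid, DivisionRule(), rng)
        assert sum(t.cell_area(d) for d in ev.daughters) == pytest.approx(area0)
        assert 0 < ev.sr <= 1

    def test_connected_pair_cut_yields_triangle_daughter(self, honeycomb19, rng):
        t = honeycomb19
        cid = center_cell(t)
        w = hexagon_walls(t, cid)
        rule = DivisionRule(cut_tilt_sd_deg=0, cut_shift_frac=0)
        t, ev = th.divide_cell(t, cid, rule, rng, pair=(w[0], w[1]))
        assert ev.interval_sides == 0
        assert min(len(t.cells[d]) for d in ev.daughters) == 3

    def test_fourfold_mode_creates_degree_four_junction(self, honeycomb19, rng):
        t = honeycomb19
        cid = center_cell(t)
        rule = DivisionRule(junction_mode="fourfold_at_vertex",
                            connected_pair_prob=0)
        t, ev = th.divide_cell(t, cid, rule, rng)
        degs = th.junction_degrees(t, interior_only=True)
        assert degs.get(4) == 1
        assert len(ev.new_junctions) == 1       # only one junction created
        assert th.euler_characteristic(t) == 1

    def test_unbalanced_daughters_never_below_four_raw_sides(self, rng):
        # unconnected cut of any polygon leaves both daughters with >= 4
        t = th.build_honeycomb(2)
        for _ in range(30):
            interior = sorted(th.interior_cells(t))
            cid = interior[int(rng.integers(len(interior)))]
            try:
                t, ev = th.divide_cell(t, cid, DivisionRule(connected_pair_prob=0), rng)
            except DivisionError:
                continue
            assert all(len(t.cells[d]) >= 4 for d in ev.daughters)

    def test_division_fuzz_accounting(self, rng):
        """Per-division accounting over many random interior divisions."""
        t = th.build_honeycomb(4)
        rule = DivisionRule(connected_pair_prob=0)
        done = 0
        while done < 250:
            interior = sorted(th.interior_cells(t))
            cid = interior[int(rng.integers(len(interior)))]
            f0, e0, v0 = t.counts
            sides0 = sum(len(c) for c in t.cells.values())
            try:
                t, ev = th.divide_cell(t, cid, rule, rng)
            except DivisionError:
                continue
            f1, e1, v1 = t.counts
            assert (f1 - f0, e1 - e0, v1 - v0) == (1, 3, 2)
            assert sum(len(c) for c in t.cells.values()) - sides0 == 6
            assert all(len(t.inc.junction_walls[j]) == 3
                       for j in ev.new_junctions)
            done += 1
        assert th.euler_characteristic(t) == 1
        assert th.validate(t).passed


class TestSidesBeforeDivision:
    def test_empty_and_single(self, honeycomb19, rng):
        assert th.sides_before_division([]) == {}
        cid = center_cell(honeycomb19)
        _, ev = th.divide_cell(honeycomb19, cid, DivisionRule(), rng)
        assert th.sides_before_division([ev]) == {6: 1}

    def test_modal_class_in_5_to_7_for_paper_rule_run(self, small_run):
        hist = th.sides_before_division(small_run.events)
        modal = max(hist, key=hist.get)
        assert modal in (5, 6, 7)
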