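"""Mesh data model: lattices, topology queries, side counting, validation."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import thallus as th
from thallus.mesh import (MeshError, Tessellation, counted_cycle,
                          polygon_interior_angles, shoelace_area)


def unit_polygon_cell(coords):
    t = Tessellation()
    jids = [t.add_junction(x, y) for x, y in coords]
    t.add_cell(jids)
    return t, jids


class TestLattices:
    def test_honeycomb7_counts(self, honeycomb7):
        assert honeycomb7.counts == (7, 30, 24)
        assert th.euler_characteristic(honeycomb7) == 1

    @pytest.mark.parametrize("kind,z", [("hexagonal", 3), ("square", 4),
                                        ("triangular", 6)])
    def test_periodic_uniform_degree_and_mean_sides(self, kind, z):
        t = th.build_lattice(kind, 4, 4, periodic=True)
        degrees = th.junction_degrees(t)
        assert set(degrees) == {z}
        _, mean = th.side_distribution(t)
        assert mean == pytest.approx(2 * z / (z - 2))

    @pytest.mark.parametrize("kind", ["hexagonal", "square", "triangular"])
    def test_nonperiodic_lattices_are_valid_patches(self, kind):
        t = th.build_lattice(kind, 3, 4)
        assert th.euler_characteristic(t) == 1
        assert th.validate(t).passed

    def test_hexagonal_interior_cells_have_six_sides(self):
        t = th.build_lattice("hexagonal", 3, 3)
        for cid in th.interior_cells(t):
            assert th.cell_sides(t, cid) == 6

    def test_unknown_kind_rejected(self):
        with pytest.raises(MeshError, match="unknown lattice kind"):
            th.build_lattice("kagome", 3, 3)

    def test_periodic_requires_three_rows(self):
        with pytest.raises(MeshError, match="periodic"):
            th.build_lattice("square", 2, 4, periodic=True)


class TestEuler:
    def test_single_hexagon(self):
        t, _ = unit_polygon_cell([(math.cos(a), math.sin(a))
                                  for a in np.linspace(0, 2 * math.pi, 7)[:-1]])
        assert t.counts == (1, 6, 6)
        assert th.euler_characteristic(t) == 1

    def test_disconnected_mesh_diagnosed(self):
        t, _ = unit_polygon_cell([(0, 0), (1, 0), (0, 1)])
        jids = [t.add_junction(x + 10, y) for x, y in [(0, 0), (1, 0), (0, 1)]]
        t.add_cell(jids)
        with pytest.raises(MeshError, match="disconnected"):
            th.euler_characteristic(t)

    def test_periodic_rejected(self):
        t = th.build_lattice("square", 3, 3, periodic=True)
        with pytest.raises(MeshError):
            th.euler_characteristic(t)


class TestSideCounting:
    def test_regular_hexagon_six_sides(self, honeycomb7):
        cid = next(iter(th.interior_cells(honeycomb7)))
        assert th.cell_sides(honeycomb7, cid) == 6

    def test_sub_threshold_wall_merges_into_next_side(self):
        # hexagon-like cell with one 0.8 µm wall: 5 counted sides
        coords = [(0, 0), (10, 0), (15, 8), (14.5, 8.6), (5, 9), (-4, 5)]
        d = math.hypot(15 - 14.5, 8.6 - 8)
        assert d < 1.0
        t, jids = unit_polygon_cell(coords)
        cid = next(iter(t.cells))
        assert th.cell_sides(t, cid) == 5
        # merged polygon keeps the endpoint of each counted wall
        kept = counted_cycle(t, cid)
        assert len(kept) == 5 and jids[3] not in kept

    def test_zero_threshold_returns_raw_count(self):
        coords = [(0, 0), (10, 0), (15, 8), (14.5, 8.6), (5, 9), (-4, 5)]
        t, _ = unit_polygon_cell(coords)
        cid = next(iter(t.cells))
        assert th.cell_sides(t, cid, min_side_length=0) == 6


class TestInteriorCells:
    def test_single_cell_has_no_interior(self):
        t, _ = unit_polygon_cell([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert th.interior_cells(t) == set()

    def test_honeycomb_center_only(self, honeycomb7, honeycomb19):
        assert len(th.interior_cells(honeycomb7)) == 1
        assert len(th.interior_cells(honeycomb19)) == 7

    def test_interior_matches_brute_force_wall_scan(self, small_run):
        t = small_run.final
        inc = t.inc
        got = th.interior_cells(t)
        for cid, cyc in t.cells.items():
            shared = all(
                len(inc.wall_cells[t.wall_between(cyc[i], cyc[(i + 1) % len(cyc)])]) == 2
                for i in range(len(cyc)))
            assert (cid in got) == shared


class TestInteriorAngles:
    def test_regular_hexagon_all_120(self, honeycomb7):
        cid = next(iter(th.interior_cells(honeycomb7)))
        assert np.allclose(th.interior_angles(honeycomb7, cid), 120.0)

    def test_square_all_90(self):
        t, _ = unit_polygon_cell([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert np.allclose(th.interior_angles(t, next(iter(t.cells))), 90.0)

    def test_right_triangle_arctangent_oracle(self):
        t, _ = unit_polygon_cell([(0, 0), (4, 0), (4, 3)])
        angles = sorted(th.interior_angles(t, next(iter(t.cells))))
        expected = sorted([90.0, math.degrees(math.atan2(3, 4)),
                           math.degrees(math.atan2(4, 3))])
        assert np.allclose(angles, expected, atol=1e-9)

    def test_degenerate_polygon_rejected(self):
        t = Tessellation()
        jids = [t.add_junction(x, 0.0) for x in (0, 10, 20)]
        t.cells[0] = jids                    # bypass add_cell's checks
        for i in range(3):
            t._ensure_wall(jids[i], jids[(i + 1) % 3])
        with pytest.raises(MeshError, match="degenerate"):
            th.interior_angles(t, 0)

    @given(st.integers(min_value=3, max_value=12),
           st.floats(min_value=0.3, max_value=3.0))
    def test_angle_sum_identity_on_regular_polygons(self, n, scale):
        ang = np.linspace(0, 2 * math.pi, n + 1)[:-1]
        coords = np.column_stack([np.cos(ang), np.sin(ang)]) * scale
        angles = polygon_interior_angles(coords)
        assert angles.sum() == pytest.approx((n - 2) * 180.0, rel=1e-9)


class TestJunctionDegrees:
    def test_honeycomb_interior_all_threefold(self, honeycomb19):
        assert set(th.junction_degrees(honeycomb19, interior_only=True)) == {3}

    def test_periodic_square_all_fourfold(self):
        t = th.build_lattice("square", 3, 3, periodic=True)
        assert th.junction_degrees(t) == {4: 9}


class TestValidate:
    def test_lattice_passes_all_checks(self):
        rep = th.validate(th.build_lattice("hexagonal", 3, 3))
        assert rep.passed, rep.summary()

    def test_crossing_wall_names_the_pair(self):
        t = th.build_lattice("square", 2, 2)
        # a spurious wall between opposite lattice corners crosses others
        corners = sorted(t.junctions,
                         key=lambda j: (t.junctions[j][0] + t.junctions[j][1]))
        bad = t._ensure_wall(corners[0], corners[-1])
        rep = th.validate(t)
        assert not rep.passed
        planarity = rep["planarity"]
        assert not planarity.passed and str(bad) in planarity.detail

    def test_hole_fails_gap_free(self):
        t = th.build_lattice("square", 3, 3)
        center = min(t.cells, key=lambda c: float(
            np.linalg.norm(t.cell_centroid(c) - np.array([15.0, 15.0]))))
        t.remove_cell(center)
        rep = th.validate(t)
        assert not rep["gap_free"].passed


class TestCanonicalize:
    def test_interior_degree2_junction_merged(self, honeycomb7):
        t = honeycomb7
        inc = t.inc
        wid = next(w for w, cs in inc.wall_cells.items() if len(cs) == 2)
        a, b = t.walls[wid]
        mid = t.add_junction(*(0.5 * (t.position(a) + t.position(b))))
        t.drop_wall(a, b)
        t._ensure_wall(a, mid)
        t._ensure_wall(mid, b)
        for cid in inc.wall_cells[wid]:
            cyc = t.cells[cid]
            n = len(cyc)
            for i in range(n):
                if {cyc[i], cyc[(i + 1) % n]} == {a, b}:
                    t.cells[cid] = cyc[:i + 1] + [mid] + cyc[i + 1:]
                    break
        t._bump()
        th.canonicalize(t)
        assert mid not in t.junctions
        assert th.validate(t).passed

    def test_boundary_corners_survive(self):
        t = th.build_lattice("square", 2, 2)
        v0 = len(t.junctions)
        th.canonicalize(t)
        assert len(t.junctions) == v0    # degree-2 corners are geometric


class TestGapFreeInvariant:
    def test_sum_of_areas_equals_hull_area(self, small_run):
        t = small_run.final
        total = sum(t.cell_area(c) for c in t.cells)
        assert total == pytest.approx(t.hull_area(), rel=1e-9)
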