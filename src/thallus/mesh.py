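"""Planar tessellation data model for single-layer cell sheets.

A thallus sheet is represented as a planar mesh of *junctions* (vertices),
*walls* (straight edges) and *cells* (simple polygonal faces) tiling a patch
of the plane with no gaps or overlaps.  Units follow light-microscopy
conventions throughout the package: lengths in micrometres (µm), areas in
µm², angles in degrees.  Cell boundaries are stored counterclockwise.

The mesh obeys the planar-patch form of Euler's law, F − E + V = 1 with the
outer face excluded, and side counting follows the microscopy convention
that a boundary segment only counts as a side when it is longer than the
wall thickness (1 µm by default); shorter segments are merged into the next
side counterclockwise for counting and angle measurement only — the mesh
topology is never edited by the side counter.
"""
from __future__ import annotations

import math
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

__all__ = [
    "Tessellation",
    "Incidence",
    "ValidationReport",
    "build_lattice",
    "build_honeycomb",
    "euler_characteristic",
    "cell_sides",
    "counted_cycle",
    "interior_cells",
    "interior_angles",
    "polygon_interior_angles",
    "junction_degrees",
    "validate",
    "canonicalize",
    "MeshError",
]

NEG_INF = float("-inf")


class MeshError(ValueError):
    """Raised when an operation would violate the tessellation contract."""


def _cycle_pairs(cycle: Sequence[int]) -> Iterator[tuple[int, int]]:
    n = len(cycle)
    for i in range(n):
        yield cycle[i], cycle[(i + 1) % n]


def shoelace_area(coords: np.ndarray) -> float:
    """Signed area of a polygon given as an (n, 2) vertex array (CCW > 0)."""
    x = coords[:, 0]
    y = coords[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_interior_angles(coords: np.ndarray) -> np.ndarray:
    """Interior angles (degrees) of a simple CCW polygon, one per vertex.

    Angles are measured on the interior side, so reflex vertices yield
    values above 180°.  The angle sum of an n-gon is (n − 2)·180°.
    """
    n = len(coords)
    if n < 3:
        raise MeshError(f"polygon needs >= 3 vertices, got {n}")
    prev = np.roll(coords, 1, axis=0)
    nxt = np.roll(coords, -1, axis=0)
    d1 = nxt - coords
    d2 = prev - coords
    ang = np.degrees(np.arctan2(d2[:, 1], d2[:, 0]) - np.arctan2(d1[:, 1], d1[:, 0]))
    return ang % 360.0


@dataclass
class Incidence:
    """Adjacency maps derived from the cell cycles (rebuilt lazily)."""

    wall_cells: dict[int, list[int]]
    junction_walls: dict[int, list[int]]
    junction_cells: dict[int, set[int]]
    junction_neighbors: dict[int, list[int]]
    boundary_walls: set[int]
    boundary_junctions: set[int]


class Tessellation:
    """Gap-free planar tiling of polygonal cells sharing junctions and walls.

    Parameters
    ----------
    periodic:
        When true the mesh lives on a torus: cycles wrap around, geometric
        invariants (planarity, gap-free tiling, Euler characteristic) do not
        apply and geometric queries raise.  Periodic meshes exist to probe
        the uniform-degree limits of the tiling laws.
    meta:
        Free-form metadata carried through serialization (units, seed, ...).
    """

    def __init__(self, periodic: bool = False, meta: Mapping | None = None):
        self.junctions: dict[int, tuple[float, float]] = {}
        self.cells: dict[int, list[int]] = {}
        self.walls: dict[int, tuple[int, int]] = {}
        self.junction_birth: dict[int, float] = {}
        self.periodic = bool(periodic)
        self.meta: dict = dict(meta or {})
        self._pair2wall: dict[frozenset[int], int] = {}
        self._next = {"j": 0, "w": 0, "c": 0}
        self._topo_rev = 0
        self._inc_rev = -1
        self._inc: Incidence | None = None

    # ------------------------------------------------------------------
    # construction / mutation
    # ------------------------------------------------------------------
    def _bump(self) -> None:
        self._topo_rev += 1

    def add_junction(self, x: float, y: float, jid: int | None = None,
                     birth: float = NEG_INF) -> int:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise MeshError(f"junction position must be finite, got ({x}, {y})")
        if jid is None:
            jid = self._next["j"]
        elif jid in self.junctions:
            raise MeshError(f"junction id {jid} already exists")
        self._next["j"] = max(self._next["j"], jid + 1)
        self.junctions[jid] = (float(x), float(y))
        self.junction_birth[jid] = birth
        self._bump()
        return jid

    def move_junction(self, jid: int, x: float, y: float) -> None:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise MeshError(f"junction position must be finite, got ({x}, {y})")
        self.junctions[jid] = (float(x), float(y))
        # geometry-only change: incidence cache stays valid

    def remove_junction(self, jid: int) -> None:
        del self.junctions[jid]
        self.junction_birth.pop(jid, None)
        self._bump()

    def _ensure_wall(self, a: int, b: int, wid: int | None = None) -> int:
        key = frozenset((a, b))
        if len(key) != 2:
            raise MeshError(f"degenerate wall ({a}, {b})")
        existing = self._pair2wall.get(key)
        if existing is not None:
            return existing
        if wid is None:
            wid = self._next["w"]
        elif wid in self.walls:
            raise MeshError(f"wall id {wid} already exists")
        self._next["w"] = max(self._next["w"], wid + 1)
        self.walls[wid] = (a, b)
        self._pair2wall[key] = wid
        self._bump()
        return wid

    def drop_wall(self, a: int, b: int) -> int:
        wid = self._pair2wall.pop(frozenset((a, b)), None)
        if wid is None:
            raise MeshError(f"no wall between junctions {a} and {b}")
        del self.walls[wid]
        self._bump()
        return wid

    def wall_between(self, a: int, b: int) -> int:
        wid = self._pair2wall.get(frozenset((a, b)))
        if wid is None:
            raise MeshError(f"no wall between junctions {a} and {b}")
        return wid

    def add_cell(self, cycle: Sequence[int], cid: int | None = None,
                 ensure_ccw: bool = True) -> int:
        cycle = [int(j) for j in cycle]
        if len(cycle) < 3:
            raise MeshError(f"cell needs >= 3 junctions, got {len(cycle)}")
        if len(set(cycle)) != len(cycle):
            raise MeshError(f"cell cycle repeats a junction: {cycle}")
        missing = [j for j in cycle if j not in self.junctions]
        if missing:
            raise MeshError(f"cell references unknown junctions {missing}")
        if ensure_ccw and not self.periodic:
            coords = np.array([self.junctions[j] for j in cycle])
            if shoelace_area(coords) < 0:
                cycle = cycle[::-1]
        if cid is None:
            cid = self._next["c"]
        elif cid in self.cells:
            raise MeshError(f"cell id {cid} already exists")
        self._next["c"] = max(self._next["c"], cid + 1)
        self.cells[cid] = cycle
        for a, b in _cycle_pairs(cycle):
            self._ensure_wall(a, b)
        self._bump()
        return cid

    def remove_cell(self, cid: int) -> None:
        del self.cells[cid]
        self._bump()

    def copy(self) -> "Tessellation":
        t = Tessellation(periodic=self.periodic, meta=dict(self.meta))
        t.junctions = dict(self.junctions)
        t.cells = {c: list(cyc) for c, cyc in self.cells.items()}
        t.walls = dict(self.walls)
        t.junction_birth = dict(self.junction_birth)
        t._pair2wall = dict(self._pair2wall)
        t._next = dict(self._next)
        return t

    # ------------------------------------------------------------------
    # derived structure
    # ------------------------------------------------------------------
    @property
    def inc(self) -> Incidence:
        if self._inc is None or self._inc_rev != self._topo_rev:
            self._inc = self._build_incidence()
            self._inc_rev = self._topo_rev
        return self._inc

    def _build_incidence(self) -> Incidence:
        wall_cells: dict[int, list[int]] = defaultdict(list)
        for cid, cyc in self.cells.items():
            for a, b in _cycle_pairs(cyc):
                wid = self._pair2wall.get(frozenset((a, b)))
                if wid is None:
                    raise MeshError(f"cell {cid} uses unregistered wall ({a}, {b})")
                wall_cells[wid].append(cid)
        junction_walls: dict[int, list[int]] = defaultdict(list)
        junction_neighbors: dict[int, list[int]] = defaultdict(list)
        for wid, (a, b) in self.walls.items():
            junction_walls[a].append(wid)
            junction_walls[b].append(wid)
            junction_neighbors[a].append(b)
            junction_neighbors[b].append(a)
        junction_cells: dict[int, set[int]] = defaultdict(set)
        for cid, cyc in self.cells.items():
            for j in cyc:
                junction_cells[j].add(cid)
        boundary_walls = {w for w in self.walls if len(wall_cells[w]) < 2}
        boundary_junctions: set[int] = set()
        for w in boundary_walls:
            a, b = self.walls[w]
            boundary_junctions.add(a)
            boundary_junctions.add(b)
        return Incidence(dict(wall_cells), dict(junction_walls),
                         dict(junction_cells), dict(junction_neighbors),
                         boundary_walls, boundary_junctions)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(F, E, V) = number of cells, walls, junctions."""
        return len(self.cells), len(self.walls), len(self.junctions)

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def _geometry_guard(self) -> None:
        if self.periodic:
            raise MeshError("geometric queries are undefined on a periodic mesh")

    def position(self, jid: int) -> np.ndarray:
        return np.asarray(self.junctions[jid], dtype=float)

    def cell_coords(self, cid: int) -> np.ndarray:
        self._geometry_guard()
        return np.array([self.junctions[j] for j in self.cells[cid]], dtype=float)

    def cell_area(self, cid: int) -> float:
        return shoelace_area(self.cell_coords(cid))

    def cell_centroid(self, cid: int) -> np.ndarray:
        return np.asarray(self.cell_polygon(cid).centroid.coords[0])

    def cell_polygon(self, cid: int) -> Polygon:
        return Polygon(self.cell_coords(cid))

    def wall_length(self, wid: int) -> float:
        self._geometry_guard()
        a, b = self.walls[wid]
        return float(np.hypot(*(self.position(a) - self.position(b))))

    def hull_area(self) -> float:
        """Area of the union of all cell polygons (the patch outline)."""
        self._geometry_guard()
        return float(unary_union([self.cell_polygon(c) for c in self.cells]).area)


# ----------------------------------------------------------------------
# lattice generators
# ----------------------------------------------------------------------
def build_lattice(kind: str, rows: int, cols: int, periodic: bool = False,
                  side_length: float = 10.0) -> Tessellation:
    """Build a regular lattice of cells.

    ``kind`` is one of ``hexagonal`` (junction degree 3), ``square``
    (degree 4) or ``triangular`` (degree 6).  With ``periodic`` the lattice
    wraps into a torus and every junction has the uniform degree above, so
    the mean side number per cell equals 2z/(z−2): 6, 4 and 3 respectively.
    """
    if rows < 1 or cols < 1:
        raise MeshError(f"rows and cols must be >= 1, got {rows}x{cols}")
    if periodic and (rows < 3 or cols < 3):
        raise MeshError("periodic lattices need rows, cols >= 3 "
                        "(smaller tori collapse distinct walls)")
    if kind == "hexagonal":
        return _hex_lattice(rows, cols, side_length, periodic)
    if kind == "square":
        return _square_lattice(rows, cols, side_length, periodic)
    if kind == "triangular":
        return _triangular_lattice(rows, cols, side_length, periodic)
    raise MeshError(f"unknown lattice kind {kind!r}; "
                    "expected hexagonal, square or triangular")


def _hex_corner_keys(q: int, r: int) -> list[tuple[int, int]]:
    # Pointy-top hexagon corners on the integer corner lattice
    # (x, y) = (sqrt(3)/2 * a, 1/2 * b) in units of the side length.
    a0, b0 = 2 * q + r, 3 * r
    return [(a0, b0 + 2), (a0 - 1, b0 + 1), (a0 - 1, b0 - 1),
            (a0, b0 - 2), (a0 + 1, b0 - 1), (a0 + 1, b0 + 1)]


def _hex_lattice(rows: int, cols: int, s: float, periodic: bool) -> Tessellation:
    t = Tessellation(periodic=periodic, meta={"units": "um", "lattice": "hexagonal"})
    jid_of: dict[tuple[int, int], int] = {}

    def wrap(a: int, b: int) -> tuple[int, int]:
        if not periodic:
            return (a, b)
        k2 = b // (3 * rows)          # r-translation: (a, b) -> (a + rows, b + 3 rows)
        a, b = a - k2 * rows, b - k2 * 3 * rows
        return (a % (2 * cols), b)    # q-translation: (a, b) -> (a + 2 cols, b)

    def jid(key: tuple[int, int]) -> int:
        key = wrap(*key)
        if key not in jid_of:
            jid_of[key] = t.add_junction(s * math.sqrt(3) / 2 * key[0], s * 0.5 * key[1])
        return jid_of[key]

    for r in range(rows):
        for q in range(cols):
            t.add_cell([jid(k) for k in _hex_corner_keys(q, r)],
                       ensure_ccw=not periodic)
    return t


def build_honeycomb(rings: int = 1, side_length: float = 10.0) -> Tessellation:
    """Hexagonal patch of 1 + 3·rings·(rings+1) cells around a central cell.

    ``rings=1`` gives the 7-cell honeycomb with F=7, E=30, V=24.
    """
    if rings < 0:
        raise MeshError("rings must be >= 0")
    t = Tessellation(meta={"units": "um", "lattice": "honeycomb"})
    jid_of: dict[tuple[int, int], int] = {}
    s = side_length

    def jid(key: tuple[int, int]) -> int:
        if key not in jid_of:
            jid_of[key] = t.add_junction(s * math.sqrt(3) / 2 * key[0], s * 0.5 * key[1])
        return jid_of[key]

    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) > rings:
                continue
            t.add_cell([jid(k) for k in _hex_corner_keys(q, r)])
    return t


def _square_lattice(rows: int, cols: int, s: float, periodic: bool) -> Tessellation:
    t = Tessellation(periodic=periodic, meta={"units": "um", "lattice": "square"})
    jid_of: dict[tuple[int, int], int] = {}

    def jid(i: int, j: int) -> int:
        key = (i % cols, j % rows) if periodic else (i, j)
        if key not in jid_of:
            jid_of[key] = t.add_junction(s * key[0], s * key[1])
        return jid_of[key]

    for j in range(rows):
        for i in range(cols):
            t.add_cell([jid(i, j), jid(i + 1, j), jid(i + 1, j + 1), jid(i, j + 1)],
                       ensure_ccw=not periodic)
    return t


def _triangular_lattice(rows: int, cols: int, s: float, periodic: bool) -> Tessellation:
    t = Tessellation(periodic=periodic, meta={"units": "um", "lattice": "triangular"})
    jid_of: dict[tuple[int, int], int] = {}
    h = s * math.sqrt(3) / 2

    def jid(i: int, j: int) -> int:
        key = (i % cols, j % rows) if periodic else (i, j)
        if key not in jid_of:
            jid_of[key] = t.add_junction(s * (key[0] + key[1] / 2), h * key[1])
        return jid_of[key]

    for j in range(rows):
        for i in range(cols):
            t.add_cell([jid(i, j), jid(i + 1, j), jid(i, j + 1)],
                       ensure_ccw=not periodic)
            t.add_cell([jid(i + 1, j), jid(i + 1, j + 1), jid(i, j + 1)],
                       ensure_ccw=not periodic)
    return t


# ----------------------------------------------------------------------
# topological / geometric queries
# ----------------------------------------------------------------------
def _components(t: Tessellation) -> list[set[int]]:
    seen: set[int] = set()
    comps: list[set[int]] = []
    nbrs = t.inc.junction_neighbors
    for start in t.junctions:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            j = queue.popleft()
            for k in nbrs.get(j, ()):
                if k not in comp:
                    comp.add(k)
                    queue.append(k)
        seen |= comp
        comps.append(comp)
    return comps


def euler_characteristic(t: Tessellation) -> int:
    """F − E + V counting cell faces only (outer face excluded).

    Equals 1 for every connected, non-periodic planar patch.
    """
    if t.periodic:
        raise MeshError("Euler characteristic of the planar patch is undefined "
                        "on a periodic mesh")
    comps = _components(t)
    if len(comps) > 1:
        sizes = sorted(len(c) for c in comps)
        raise MeshError(f"mesh is disconnected: {len(comps)} components "
                        f"of sizes {sizes}")
    f, e, v = t.counts
    return f - e + v


def counted_cycle(t: Tessellation, cid: int, min_side_length: float = 1.0) -> list[int]:
    """Junction cycle of the counted-side polygon of a cell.

    Walls not exceeding ``min_side_length`` are merged into the following
    (counterclockwise) side, so the counted polygon keeps only the endpoint
    of each counted wall.  A threshold of 0 returns the raw cycle.
    """
    cyc = t.cells[cid]
    if t.periodic or min_side_length <= 0:
        return list(cyc)
    n = len(cyc)
    pos = t.junctions
    kept = []
    for i in range(n):
        a, b = pos[cyc[i]], pos[cyc[(i + 1) % n]]
        if math.hypot(a[0] - b[0], a[1] - b[1]) > min_side_length:
            kept.append(cyc[(i + 1) % n])
    return kept


def cell_sides(t: Tessellation, cid: int, min_side_length: float = 1.0) -> int:
    """Number of counted sides of a cell (walls longer than the threshold)."""
    return len(counted_cycle(t, cid, min_side_length))


def interior_cells(t: Tessellation) -> set[int]:
    """Cells completely surrounded by other cells (no boundary wall)."""
    if t.periodic:
        return set(t.cells)
    inc = t.inc
    out = set()
    for cid, cyc in t.cells.items():
        if all(t.wall_between(a, b) not in inc.boundary_walls
               for a, b in _cycle_pairs(cyc)):
            out.add(cid)
    return out


def interior_angles(t: Tessellation, cid: int, min_side_length: float = 1.0) -> np.ndarray:
    """Interior angles (degrees) of the counted-side polygon of a cell."""
    t._geometry_guard()
    cyc = counted_cycle(t, cid, min_side_length)
    if len(cyc) < 3:
        raise MeshError(f"cell {cid} has fewer than 3 counted sides "
                        f"at threshold {min_side_length}")
    coords = np.array([t.junctions[j] for j in cyc], dtype=float)
    if abs(shoelace_area(coords)) < 1e-12:
        raise MeshError(f"cell {cid} has a degenerate (zero-area) counted polygon")
    if shoelace_area(coords) < 0:
        coords = coords[::-1]
    return polygon_interior_angles(coords)


def junction_degrees(t: Tessellation, interior_only: bool = False) -> dict[int, int]:
    """Histogram degree → number of junctions (optionally interior only)."""
    inc = t.inc
    hist: dict[int, int] = defaultdict(int)
    for j in t.junctions:
        if interior_only and j in inc.boundary_junctions:
            continue
        hist[len(inc.junction_walls.get(j, ()))] += 1
    return dict(hist)


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------
@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def __getitem__(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)

    def summary(self) -> str:
        return "\n".join(f"[{'ok' if c.passed else 'FAIL'}] {c.name}"
                         + (f": {c.detail}" if c.detail else "")
                         for c in self.checks)


def validate(t: Tessellation, rel_tol: float = 1e-6) -> ValidationReport:
    """Check every tessellation invariant; reporting only, never raises."""
    rep = ValidationReport()
    add = rep.checks.append

    bad_pos = [j for j, (x, y) in t.junctions.items()
               if not (math.isfinite(x) and math.isfinite(y))]
    add(CheckResult("finite_positions", not bad_pos, f"junctions {bad_pos[:5]}" if bad_pos else ""))

    missing = [(cid, (a, b)) for cid, cyc in t.cells.items()
               for a, b in _cycle_pairs(cyc)
               if frozenset((a, b)) not in t._pair2wall or a not in t.junctions or b not in t.junctions]
    add(CheckResult("references_resolve", not missing, str(missing[:5]) if missing else ""))
    if missing:
        return rep

    inc = t.inc
    bad_inc = [w for w, cs in inc.wall_cells.items() if not 1 <= len(cs) <= 2]
    orphan = [w for w in t.walls if w not in inc.wall_cells]
    add(CheckResult("wall_incidence", not bad_inc and not orphan,
                    f"bad {bad_inc[:5]} orphan {orphan[:5]}" if bad_inc or orphan else ""))

    degs = {j: len(inc.junction_walls.get(j, ())) for j in t.junctions}
    low = [j for j, d in degs.items() if d < 2]
    low_int = [j for j, d in degs.items()
               if d < 3 and j not in inc.boundary_junctions]
    add(CheckResult("junction_degree_min2", not low, f"junctions {low[:5]}" if low else ""))
    add(CheckResult("interior_junction_degree_min3", not low_int,
                    f"junctions {low_int[:5]}" if low_int else ""))

    if t.periodic:
        return rep

    zero_walls = [w for w in t.walls if t.wall_length(w) <= 0]
    add(CheckResult("wall_length_positive", not zero_walls,
                    f"walls {zero_walls[:5]}" if zero_walls else ""))

    bad_cells = []
    bad_sum = []
    for cid in t.cells:
        coords = t.cell_coords(cid)
        poly = Polygon(coords)
        if shoelace_area(coords) <= 0 or not poly.is_valid:
            bad_cells.append(cid)
            continue
        ang = polygon_interior_angles(coords)
        if abs(ang.sum() - (len(coords) - 2) * 180.0) > 1e-6 * (len(coords) - 2) * 180.0:
            bad_sum.append(cid)
    add(CheckResult("cells_simple_ccw_positive", not bad_cells,
                    f"cells {bad_cells[:5]}" if bad_cells else ""))
    add(CheckResult("angle_sums", not bad_sum, f"cells {bad_sum[:5]}" if bad_sum else ""))

    add(_check_planarity(t))
    add(_check_gap_free(t, rel_tol, skip=bool(bad_cells)))

    comps = _components(t)
    add(CheckResult("connected", len(comps) <= 1,
                    f"{len(comps)} components" if len(comps) > 1 else ""))
    if len(comps) <= 1 and not bad_cells:
        f, e, v = t.counts
        add(CheckResult("euler", f - e + v == 1, f"F-E+V = {f - e + v}"))
    return rep


def _check_planarity(t: Tessellation) -> CheckResult:
    wids = list(t.walls)
    segs = [LineString([t.junctions[a], t.junctions[b]]) for a, b in
            (t.walls[w] for w in wids)]
    tree = STRtree(segs)
    offending: list[tuple[int, int]] = []
    for i, seg in enumerate(segs):
        for k in tree.query(seg):
            k = int(k)
            if k <= i:
                continue
            a1, b1 = t.walls[wids[i]]
            a2, b2 = t.walls[wids[k]]
            shared = {a1, b1} & {a2, b2}
            inter = seg.intersection(segs[k])
            if inter.is_empty:
                continue
            if shared:
                ok = (inter.geom_type == "Point"
                      and inter.distance(Point(t.junctions[next(iter(shared))])) < 1e-9)
            else:
                ok = False
            if not ok:
                offending.append((wids[i], wids[k]))
    return CheckResult("planarity", not offending,
                       f"crossing wall pairs {offending[:5]}" if offending else "")


def _check_gap_free(t: Tessellation, rel_tol: float, skip: bool) -> CheckResult:
    if skip:
        return CheckResult("gap_free", False, "skipped: invalid cell polygons")
    if not t.cells:
        return CheckResult("gap_free", True)
    polys = [t.cell_polygon(c) for c in t.cells]
    total = sum(p.area for p in polys)
    union = unary_union(polys)
    if union.geom_type != "Polygon":
        return CheckResult("gap_free", False, f"union is {union.geom_type}")
    if union.interiors:
        return CheckResult("gap_free", False, f"{len(union.interiors)} hole(s)")
    mismatch = abs(union.area - total) / max(total, 1e-12)
    return CheckResult("gap_free", mismatch < rel_tol,
                       f"relative area mismatch {mismatch:.2e}" if mismatch >= rel_tol else "")


def canonicalize(t: Tessellation) -> Tessellation:
    """Merge interior degree-2 junctions into a single wall (in place).

    Junctions of the sheet are at least 3-fold by definition; degree-2
    interior junctions only arise transiently (e.g. after noise injection on
    an imported outline) and are removed here.  Boundary corners of a patch
    legitimately have degree 2 and are kept.
    """
    while True:
        inc = t.inc
        target = None
        for j in sorted(t.junctions):
            walls = inc.junction_walls.get(j, [])
            if len(walls) == 2 and j not in inc.boundary_junctions:
                (a1, b1), (a2, b2) = t.walls[walls[0]], t.walls[walls[1]]
                u = a1 if b1 == j else b1
                w = a2 if b2 == j else b2
                if frozenset((u, w)) not in t._pair2wall:
                    target = (j, u, w)
                    break
        if target is None:
            return t
        j, u, w = target
        for cid in list(inc.junction_cells.get(j, ())):
            t.cells[cid] = [x for x in t.cells[cid] if x != j]
        t.drop_wall(u, j)
        t.drop_wall(j, w)
        t._ensure_wall(u, w)
        t.remove_junction(j)
        t._bump()
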