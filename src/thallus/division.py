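"""Cleavage-plane selection and execution on the tessellation.

The measured division behaviour of the thallus sheet is operationalized as
a three-part rule:

* the cleavage plane transects a *pair of sides* of the mother cell,
  almost always an unconnected pair (the observed exception rate is 0.6%);
* among unconnected pairs, the chosen pair is the one whose
  midpoint-to-midpoint cut best equalizes the daughter areas
  ("equal division");
* each transected side is cut near its midpoint, with a truncated-normal
  jitter on the cut fraction, and the two cut points are joined by a new
  straight wall shared by the daughters, creating two 3-fold junctions.

Division bookkeeping follows the side-accounting of a tricellular cut: one
extra cell, three extra shared walls, six extra counted sides in total
(each neighbour across a cut wall gains exactly one side).

Summary statistics of a division use the microscopy definitions: the
division section DS = |S1/(S1+S2) − 0.5| of the two flanking daughter-side
lengths, and the size ratio SR = As/Ab of smaller over larger daughter
area.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .mesh import MeshError, Tessellation, shoelace_area

__all__ = [
    "DivisionRule",
    "DivisionEvent",
    "DivisionError",
    "interval_sides",
    "division_section",
    "size_ratio",
    "select_division_pair",
    "divide_cell",
    "random_cleavage_null",
    "iur_chord_connected_prob",
    "iur_chord_connected_prob_mc",
    "sides_before_division",
]


class DivisionError(MeshError):
    """Raised when a cell cannot be divided under the given rule."""


@dataclass
class DivisionRule:
    """Parameters of the cleavage-plane rule.

    ``pair_selection``: ``paper`` (area-balancing unconnected pair with a
    small connected-pair probability), ``uniform_pair`` (uniform over all
    side pairs) or ``fixed`` (use ``fixed_pair`` wall ids, e.g. for the
    transverse divisions of the linear stage).

    The cleavage plane starts as the chord joining the midpoints of the
    selected wall pair and is then jittered as a rigid line: rotated about
    its centre by a normal angle of sd ``cut_tilt_sd_deg`` (degrees) and
    translated perpendicular to itself by a normal offset of sd
    ``cut_shift_frac``·sqrt(cell area).  A tilt moves both cut points
    off-middle while conserving the area balance; only the small shift
    component unbalances the daughters.  This reconciles an off-middle
    division section (mean DS near 0.13) with near-equal daughter sizes
    (mean SR near 0.86), and keeps cuts near-perpendicular on elongated
    cells so aspect ratios self-correct.  ``cut_tilt_sd_deg = 0`` and
    ``cut_shift_frac = 0`` give exact midpoint-to-midpoint cuts.

    ``junction_mode``: ``tricellular`` places both cut points in side
    interiors (3-fold junctions); ``fourfold_at_vertex`` anchors the first
    cut point on an existing junction instead, raising its degree to 4
    (variant experiments only; its side accounting is reported, not
    asserted).

    ``area_balance_band``: cuts whose daughter-area difference is within
    this fraction of the mother area of the best cut count as equally
    balanced; among them the shortest new wall wins (Errera's rule for
    walled cells), which keeps aspect ratios self-regulating.

    ``min_wall_length``: a cut point cannot land closer than this (µm) to
    an existing junction — the wall itself is about this thick — so every
    wall fragment a division creates remains a countable side.
    """

    pair_selection: str = "paper"
    cut_tilt_sd_deg: float = 12.0
    cut_shift_frac: float = 0.03
    connected_pair_prob: float = 0.006
    junction_mode: str = "tricellular"
    fixed_pair: tuple[int, int] | None = None
    max_retries: int = 12
    area_balance_band: float = 0.02
    min_wall_length: float = 1.0

    def __post_init__(self) -> None:
        if self.pair_selection not in ("paper", "uniform_pair", "fixed"):
            raise DivisionError(f"unknown pair_selection {self.pair_selection!r}")
        if self.junction_mode not in ("tricellular", "fourfold_at_vertex"):
            raise DivisionError(f"unknown junction_mode {self.junction_mode!r}")
        if not 0.0 <= self.connected_pair_prob <= 1.0:
            raise DivisionError("connected_pair_prob must be in [0, 1]")
        if self.cut_tilt_sd_deg < 0 or self.cut_shift_frac < 0:
            raise DivisionError("jitter sds must be >= 0")


@dataclass
class DivisionEvent:
    """Record of one mitosis on the mesh."""

    mother: int
    pair: tuple[int, int]                    # wall ids transected
    interval_sides: int
    cut_fractions: tuple[float, float]
    ds_values: tuple[float, ...]
    daughters: tuple[int, int]
    sr: float
    new_wall: int
    new_junctions: tuple[int, ...]
    n_sides_before: int                      # counted sides (1 µm threshold)
    n_walls_before: int                      # raw wall count
    mother_area: float
    time: float = 0.0


# ----------------------------------------------------------------------
# elementary statistics
# ----------------------------------------------------------------------
def division_section(s1: float, s2: float) -> float:
    """DS = |S1/(S1+S2) − 0.5| for the two flanking daughter-side lengths."""
    if s1 <= 0 or s2 <= 0:
        raise DivisionError(f"side lengths must be positive, got ({s1}, {s2})")
    return abs(s1 / (s1 + s2) - 0.5)


def size_ratio(area_1: float, area_2: float) -> float:
    """SR = As/Ab, smaller daughter area over larger; 1 means equal division."""
    if area_1 <= 0 or area_2 <= 0:
        raise DivisionError(f"areas must be positive, got ({area_1}, {area_2})")
    return min(area_1, area_2) / max(area_1, area_2)


def interval_sides(t: Tessellation, cid: int, wall_a: int, wall_b: int) -> int:
    """Sides between a pair of sides, the smaller of the two way-around counts.

    0 means the pair is connected (adjacent sides sharing a junction).
    """
    if wall_a == wall_b:
        raise DivisionError("the two sides must differ")
    cyc = t.cells[cid]
    idx = _wall_indices(t, cid, (wall_a, wall_b))
    ia, ib = idx
    n = len(cyc)
    k1 = (ib - ia - 1) % n
    k2 = (ia - ib - 1) % n
    return min(k1, k2)


def _wall_indices(t: Tessellation, cid: int, wids: tuple[int, int]) -> list[int]:
    cyc = t.cells[cid]
    n = len(cyc)
    pos: dict[int, int] = {}
    for i in range(n):
        w = t.wall_between(cyc[i], cyc[(i + 1) % n])
        pos[w] = i
    out = []
    for w in wids:
        if w not in pos:
            raise DivisionError(f"wall {w} is not on the boundary of cell {cid}")
        out.append(pos[w])
    return out


# ----------------------------------------------------------------------
# pair selection
# ----------------------------------------------------------------------
def _daughter_coord_split(coords: np.ndarray, ia: int, ib: int,
                          f1: float, f2: float) -> tuple[np.ndarray, np.ndarray]:
    """Vertex arrays of the two daughters for a cut of walls ia and ib."""
    n = len(coords)
    p = coords[ia] + f1 * (coords[(ia + 1) % n] - coords[ia])
    q = coords[ib] + f2 * (coords[(ib + 1) % n] - coords[ib])
    span1 = [coords[i % n] for i in range(ia + 1, ia + 1 + (ib - ia) % n)]
    span2 = [coords[i % n] for i in range(ib + 1, ib + 1 + (ia - ib) % n)]
    d1 = np.array([p] + span1 + [q])
    d2 = np.array([q] + span2 + [p])
    return d1, d2


def _cut_is_valid(d1: np.ndarray, d2: np.ndarray, mother_area: float) -> bool:
    a1, a2 = shoelace_area(d1), shoelace_area(d2)
    if a1 <= 1e-9 or a2 <= 1e-9:
        return False
    if abs(a1 + a2 - mother_area) > 1e-6 * mother_area:
        return False
    return Polygon(d1).is_valid and Polygon(d2).is_valid


def select_division_pair(t: Tessellation, cid: int, rule: DivisionRule,
                         rng: np.random.Generator) -> tuple[int, int]:
    """Choose the pair of walls the cleavage plane will transect.

    ``paper`` mode: with probability 1 − connected_pair_prob, the
    unconnected pair whose midpoint-to-midpoint cut minimizes the daughter
    area difference (ties broken uniformly); otherwise a uniformly chosen
    connected pair.  ``uniform_pair``: uniform over all wall pairs.
    """
    cyc = t.cells[cid]
    n = len(cyc)
    if n < 3:
        raise DivisionError(f"cell {cid} has fewer than 3 sides")
    wids = [t.wall_between(cyc[i], cyc[(i + 1) % n]) for i in range(n)]

    if rule.pair_selection == "fixed":
        if rule.fixed_pair is None:
            raise DivisionError("fixed pair selection requires rule.fixed_pair")
        return rule.fixed_pair

    if rule.pair_selection == "uniform_pair":
        i, j = map(int, rng.choice(n, size=2, replace=False))
        return (wids[i], wids[j])

    # paper rule
    from .mesh import cell_sides
    counted = cell_sides(t, cid) if not t.periodic else n
    if counted < 4:
        raise DivisionError(
            f"cell {cid} has {counted} counted sides; the equal-division rule "
            "requires >= 4")

    if rule.connected_pair_prob > 0 and rng.random() < rule.connected_pair_prob:
        i = int(rng.integers(n))
        return (wids[i], wids[(i + 1) % n])

    coords = t.cell_coords(cid)
    area0 = shoelace_area(coords)
    lengths = [float(np.hypot(*(coords[(i + 1) % n] - coords[i])))
               for i in range(n)]
    cuttable = [i for i in range(n)
                if lengths[i] > 2 * rule.min_wall_length]
    scored: list[tuple[float, float, int, int]] = []
    for ia in cuttable:
        for ib in cuttable:
            if ib <= ia or (ib - ia) % n in (1, n - 1):   # connected pair
                continue
            d1, d2 = _daughter_coord_split(coords, ia, ib, 0.5, 0.5)
            a1, a2 = shoelace_area(d1), shoelace_area(d2)
            if a1 <= 0 or a2 <= 0:
                continue
            chord = float(np.hypot(*(d1[0] - d1[-1])))
            if chord <= rule.min_wall_length:
                continue
            scored.append((abs(a1 - a2), chord, ia, ib))
    if not scored:
        raise DivisionError(f"cell {cid} admits no unconnected cut")
    # Equal division first: keep cuts within the area-balance band, then
    # prefer the shortest new wall among them (walled cells build the
    # cheapest partition — Errera's rule); exact ties break uniformly.
    scored.sort()
    while scored:
        # equal division: within the area-balance band prefer the cut that
        # also splits the boundary sides evenly between the daughters, then
        # the shortest new wall (Errera); exact ties break uniformly
        band = [s for s in scored
                if s[0] <= scored[0][0] + rule.area_balance_band * area0]
        def k_imbalance(s) -> int:
            k1 = (s[3] - s[2] - 1) % n
            return abs((n - 2 - k1) - k1)
        band.sort(key=lambda s: (k_imbalance(s), s[1]))
        best_k, best_chord = k_imbalance(band[0]), band[0][1]
        tied = [s for s in band
                if k_imbalance(s) == best_k and s[1] <= best_chord * (1 + 1e-9)]
        _, _, ia, ib = tied[int(rng.integers(len(tied)))]
        d1, d2 = _daughter_coord_split(coords, ia, ib, 0.5, 0.5)
        if _cut_is_valid(d1, d2, area0):
            return (wids[ia], wids[ib])
        scored = [s for s in scored if (s[2], s[3]) != (ia, ib)]
    raise DivisionError(f"cell {cid} admits no geometrically valid unconnected cut")


# ----------------------------------------------------------------------
# executing a division
# ----------------------------------------------------------------------
def _jittered_plane_cut(coords: np.ndarray, ia: int, ib: int,
                        rule: DivisionRule, rng: np.random.Generator,
                        area: float) -> tuple[int, int, float, float] | None:
    """One draw of the jittered cleavage plane.

    The plane through the midpoints of walls ia and ib is rotated about
    its centre by a normal angle and shifted perpendicular to itself by a
    normal offset scaled with the cell size, then intersected with the
    cell boundary.  Returns the two crossed wall indices and the cut
    fractions along them, or None when the draw is degenerate.
    """
    n = len(coords)
    m1 = 0.5 * (coords[ia] + coords[(ia + 1) % n])
    m2 = 0.5 * (coords[ib] + coords[(ib + 1) % n])
    center = 0.5 * (m1 + m2)
    u = m2 - m1
    norm = float(np.hypot(*u))
    if norm < 1e-12:
        return None
    u = u / norm
    if rule.cut_tilt_sd_deg > 0:
        th = math.radians(rule.cut_tilt_sd_deg) * rng.standard_normal()
        c, s = math.cos(th), math.sin(th)
        u = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
    nvec = np.array([-u[1], u[0]])
    if rule.cut_shift_frac > 0:
        center = center + (rule.cut_shift_frac * math.sqrt(area)
                           * rng.standard_normal()) * nvec
    d = (coords - center) @ nvec                  # signed distance per vertex
    if np.any(d == 0):
        return None
    crossing = [i for i in range(n) if d[i] * d[(i + 1) % n] < 0]
    if len(crossing) != 2:
        return None
    ja, jb = crossing
    fa = float(d[ja] / (d[ja] - d[(ja + 1) % n]))
    fb = float(d[jb] / (d[jb] - d[(jb + 1) % n]))
    return ja, jb, fa, fb


def divide_cell(t: Tessellation, cid: int, rule: DivisionRule | None = None,
                rng: np.random.Generator | None = None,
                pair: tuple[int, int] | None = None,
                time: float = 0.0) -> tuple[Tessellation, DivisionEvent]:
    """Divide a cell in place; returns the mesh and the division record.

    Tricellular mode splits each transected wall at a jittered fraction,
    joins the cut points by a new wall and replaces the mother by two
    daughters.  The neighbour across each cut wall gains one (counted)
    side; cells +1, walls +3, junctions +2, so the Euler characteristic is
    conserved.  In ``fourfold_at_vertex`` mode the first cut point lands on
    an existing junction of the first wall, creating a 4-fold junction.
    """
    from .mesh import cell_sides
    rule = rule or DivisionRule()
    rng = rng or np.random.default_rng()
    if cid not in t.cells:
        raise DivisionError(f"no cell {cid}")
    pair_given = pair is not None
    if pair is None:
        pair = select_division_pair(t, cid, rule, rng)
    wa, wb = pair
    ia, ib = _wall_indices(t, cid, (wa, wb))
    cyc = list(t.cells[cid])
    n = len(cyc)
    coords = t.cell_coords(cid)
    area0 = shoelace_area(coords)
    fourfold = rule.junction_mode == "fourfold_at_vertex"

    mwl = rule.min_wall_length
    seg_len = [float(np.hypot(*(coords[(i + 1) % n] - coords[i])))
               for i in range(n)]
    sel_connected = (ib - ia) % n in (1, n - 1)
    # an explicitly requested pair (e.g. a transverse filament cut) is
    # binding: the jittered plane must cross exactly those walls
    strict_pair = pair_given or sel_connected
    result = None
    for attempt in range(rule.max_retries):
        if fourfold:
            f2 = 0.5 + 0.163 * rng.standard_normal()
            if not 0.05 < f2 < 0.95 or min(f2, 1 - f2) * seg_len[ib] <= mwl:
                continue
            d1, d2 = _daughter_coord_split(coords, ia, ib, 1e-12, f2)
            if (float(np.hypot(*(d1[0] - d1[-1]))) > mwl
                    and _cut_is_valid(d1, d2, area0)):
                result = (ia, ib, 0.0, f2, d1, d2)
                break
            continue
        cand = _jittered_plane_cut(coords, ia, ib, rule, rng, area0)
        if cand is None:
            continue
        ja, jb, f1, f2 = cand
        # the jittered plane may cross different walls than selected;
        # keep the cut class (connected vs unconnected) of the selection
        cand_connected = (jb - ja) % n in (1, n - 1)
        if strict_pair and (ja, jb) != (ia, ib):
            continue
        if not sel_connected and cand_connected:
            continue
        if (min(f1, 1 - f1) * seg_len[ja] <= mwl
                or min(f2, 1 - f2) * seg_len[jb] <= mwl):
            continue
        d1, d2 = _daughter_coord_split(coords, ja, jb, f1, f2)
        if (float(np.hypot(*(d1[0] - d1[-1]))) > mwl
                and _cut_is_valid(d1, d2, area0)):
            result = (ja, jb, f1, f2, d1, d2)
            break
    if result is None:
        # last resort: the exact midpoint-to-midpoint cut of the selection
        d1, d2 = _daughter_coord_split(coords, ia, ib, 0.5, 0.5)
        if (not fourfold and 0.5 * seg_len[ia] > mwl
                and 0.5 * seg_len[ib] > mwl
                and float(np.hypot(*(d1[0] - d1[-1]))) > mwl
                and _cut_is_valid(d1, d2, area0)):
            result = (ia, ib, 0.5, 0.5, d1, d2)
        else:
            raise DivisionError(
                f"cell {cid}: no valid cut of walls ({wa}, {wb}) after "
                f"{rule.max_retries} jitter draws")
    ia, ib, f1, f2, _, _ = result
    wa = t.wall_between(cyc[ia], cyc[(ia + 1) % n])
    wb = t.wall_between(cyc[ib], cyc[(ib + 1) % n])

    a1, a2n = cyc[ia], cyc[(ia + 1) % n]
    b1, b2n = cyc[ib], cyc[(ib + 1) % n]
    inc = t.inc
    neigh_a = next((c for c in inc.wall_cells.get(wa, []) if c != cid), None)
    neigh_b = next((c for c in inc.wall_cells.get(wb, []) if c != cid), None)

    pa = coords[ia] + f1 * (coords[(ia + 1) % n] - coords[ia])
    pb = coords[ib] + f2 * (coords[(ib + 1) % n] - coords[ib])

    if fourfold:
        jp = a1                                  # reuse the existing junction
        new_junctions: list[int] = []
    else:
        jp = t.add_junction(pa[0], pa[1], birth=time)
        new_junctions = [jp]
        t.drop_wall(a1, a2n)
        t._ensure_wall(a1, jp)
        t._ensure_wall(jp, a2n)
        if neigh_a is not None:
            _insert_between(t, neigh_a, a2n, a1, jp)
    jq = t.add_junction(pb[0], pb[1], birth=time)
    new_junctions.append(jq)
    t.drop_wall(b1, b2n)
    t._ensure_wall(b1, jq)
    t._ensure_wall(jq, b2n)
    if neigh_b is not None:
        _insert_between(t, neigh_b, b2n, b1, jq)

    n_sides_before = _counted_sides_of_cycle(t, cyc)
    span1 = [cyc[i % n] for i in range(ia + 1, ia + 1 + (ib - ia) % n)]
    span2 = [cyc[i % n] for i in range(ib + 1, ib + 1 + (ia - ib) % n)]
    t.remove_cell(cid)
    if fourfold:
        cyc1 = [jp] + span1 + [jq]
        cyc2 = [jq] + [x for x in span2 if x != jp] + [jp]
    else:
        cyc1 = [jp] + span1 + [jq]
        cyc2 = [jq] + span2 + [jp]
    c1 = t.add_cell(cyc1, ensure_ccw=False)
    c2 = t.add_cell(cyc2, ensure_ccw=False)
    new_wall = t.wall_between(jp, jq)

    ar1, ar2 = t.cell_area(c1), t.cell_area(c2)
    k = min((ib - ia - 1) % n, (ia - ib - 1) % n)
    ds = ((abs(f2 - 0.5),) if fourfold
          else (abs(f1 - 0.5), abs(f2 - 0.5)))
    event = DivisionEvent(
        mother=cid, pair=(wa, wb), interval_sides=k,
        cut_fractions=(f1, f2), ds_values=ds,
        daughters=(c1, c2), sr=size_ratio(ar1, ar2),
        new_wall=new_wall, new_junctions=tuple(new_junctions),
        n_sides_before=n_sides_before, n_walls_before=n,
        mother_area=area0, time=time)
    return t, event


def _insert_between(t: Tessellation, cid: int, u: int, v: int, newj: int) -> None:
    """Insert ``newj`` between consecutive junctions u, v of a cell cycle."""
    cyc = t.cells[cid]
    n = len(cyc)
    for i in range(n):
        if cyc[i] == u and cyc[(i + 1) % n] == v:
            t.cells[cid] = cyc[:i + 1] + [newj] + cyc[i + 1:]
            t._bump()
            return
    raise DivisionError(f"junctions ({u}, {v}) are not consecutive in cell {cid}")


def _counted_sides_of_cycle(t: Tessellation, cyc: list[int],
                            min_side_length: float = 1.0) -> int:
    pos = t.junctions
    n = len(cyc)
    return sum(
        1 for i in range(n)
        if math.hypot(pos[cyc[i]][0] - pos[cyc[(i + 1) % n]][0],
                      pos[cyc[i]][1] - pos[cyc[(i + 1) % n]][1]) > min_side_length)


# ----------------------------------------------------------------------
# random-cleavage null models
# ----------------------------------------------------------------------
def _regular_polygon(n: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([np.cos(ang), np.sin(ang)])


def iur_chord_connected_prob(n_sides: int) -> float:
    """Closed-form probability that an IUR chord of a regular n-gon crosses
    two adjacent sides.

    By the integral-geometry measure of lines meeting two segments, the
    measure for an adjacent side pair (a, b) with far diagonal d is
    a + b − d, and the measure of all chords is the perimeter; summed over
    the n adjacent pairs of a regular n-gon this reduces to 2 − 2·cos(π/n).
    """
    verts = _regular_polygon(n_sides)
    per = n_sides * float(np.linalg.norm(verts[1] - verts[0]))
    total = 0.0
    for i in range(n_sides):
        a = np.linalg.norm(verts[(i + 1) % n_sides] - verts[i])
        b = np.linalg.norm(verts[(i + 2) % n_sides] - verts[(i + 1) % n_sides])
        d = np.linalg.norm(verts[(i + 2) % n_sides] - verts[i])
        total += a + b - d
    return total / per


def iur_chord_connected_prob_mc(n_sides: int, reps: int,
                                rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the same probability from uniform random
    lines (isotropic direction, uniform offset across the support)."""
    verts = _regular_polygon(n_sides)
    theta = rng.uniform(0, np.pi, size=reps)
    u = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = verts @ u.T                                  # (n, reps)
    # kinematic measure dp·dθ: offset uniform over a global range covering
    # the whole body, lines that miss are rejected (not renormalized per θ,
    # which would bias toward narrow-support orientations)
    p = rng.uniform(-1.001, 1.001, size=reps)
    side = proj - p                                     # sign per vertex
    crosses = (side * np.roll(side, -1, axis=0)) < 0    # side i = (v_i, v_i+1)
    hits = 0
    adj = 0
    for r in range(reps):
        idx = np.flatnonzero(crosses[:, r])
        if len(idx) != 2:
            continue
        hits += 1
        gap = (idx[1] - idx[0]) % n_sides
        if gap in (1, n_sides - 1):
            adj += 1
    if hits == 0:
        raise DivisionError("no valid chords sampled")
    return adj / hits


def random_cleavage_null(n_sides: int, model: str = "uniform_pair",
                         reps: int = 0,
                         rng: np.random.Generator | None = None) -> float:
    """Probability that a random cleavage transects a *connected* side pair
    of a regular n-gon, under one of three null models.

    ``uniform_pair``: every side pair equally likely; closed form
    n/C(n,2) = 2/(n−1).  ``perimeter_points``: the two cut points fall
    uniformly on the perimeter (Monte Carlo; ``reps`` required).
    ``iur_chord``: the cleavage is an isotropic uniform random line; the
    closed-form integral-geometry value is returned, and when ``reps`` > 0
    a Monte-Carlo run must agree with it within 3σ (self-check).
    """
    if n_sides < 3:
        raise DivisionError(f"n_sides must be >= 3, got {n_sides}")
    if model == "uniform_pair":
        return 2.0 / (n_sides - 1)
    if model == "perimeter_points":
        if reps < 1:
            raise DivisionError("perimeter_points is Monte-Carlo: reps >= 1")
        rng = rng or np.random.default_rng()
        s1 = rng.integers(n_sides, size=reps)           # equal sides: the side
        s2 = rng.integers(n_sides, size=reps)           # index is uniform
        distinct = s1 != s2
        gap = (s2[distinct] - s1[distinct]) % n_sides
        return float(np.mean((gap == 1) | (gap == n_sides - 1)))
    if model == "iur_chord":
        exact = iur_chord_connected_prob(n_sides)
        if reps >= 1:
            rng = rng or np.random.default_rng()
            mc = iur_chord_connected_prob_mc(n_sides, reps, rng)
            sigma = math.sqrt(exact * (1 - exact) / reps)
            if abs(mc - exact) > 3 * sigma + 1e-12:
                raise DivisionError(
                    f"iur_chord Monte-Carlo ({mc:.4f}) disagrees with the "
                    f"closed form ({exact:.4f}) beyond 3 sigma")
        return exact
    raise DivisionError(f"unknown null model {model!r}")


def sides_before_division(events: list[DivisionEvent]) -> Counter:
    """Histogram of mother counted-side numbers over a division log."""
    return Counter(e.n_sides_before for e in events)
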