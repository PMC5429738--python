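"""Post-division reorientation of cell walls.

Splitting a straight wall leaves a fresh 3-fold junction with a 180° angle
in the neighbouring cell and two complementary angles in the daughters.
Time-series microscopy shows these new angles are not static: the walls
around a new junction reorient so that the neighbour angle decreases at
about 20°/day for about two days after the division.

The rate is a kinematic observation, not a mechanism, so the dynamics here
are the simplest that reproduce it: junction positions descend the
angular-deviation energy

    E = Σ_junctions Σ_incident-angles (θ − 360°/degree)²

with the step length of each junction chosen so that its worst angle moves
toward the 360°/degree target at exactly ``rate`` degrees per day while
deviations persist.  Only junction positions move (walls stay straight
segments), topology never changes, and moves that would fold a cell are
halved and ultimately rejected, so the gap-free tiling is preserved.  By
default only junctions younger than the reorientation window experience
the relaxation (age gate), matching the observed two-day persistence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .mesh import MeshError, Tessellation, shoelace_area

__all__ = [
    "RelaxationParams",
    "TrackedAngle",
    "relax",
    "new_neighbor_angle",
    "angle_decrease_rate",
    "cell_angle_at_junction",
]


@dataclass
class RelaxationParams:
    """Wall-reorientation parameters.

    rate:      angular relaxation rate, degrees/day (measured: 20 ± 3).
    window:    days a junction keeps reorienting after its creation
               (measured persistence: about 2 days).
    timestep:  integration step, days.
    max_step:  cap on junction displacement per timestep, µm.
    age_gate:  when true (default) only junctions younger than ``window``
               move; when false the whole sheet relaxes.
    """

    rate: float = 20.0
    window: float = 2.0
    timestep: float = 0.1
    max_step: float = 1.0
    age_gate: bool = True
    min_wall_length: float = 1.0     # walls are rigid and ~1 µm thick

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise MeshError("rate must be >= 0")
        if not 0 < self.timestep <= self.window:
            raise MeshError("need 0 < timestep <= window")


@dataclass
class TrackedAngle:
    """Time series of one intracellular angle at one junction."""

    junction: int
    cell: int
    series: list[tuple[float, float]] = field(default_factory=list)

    def append(self, time: float, angle: float) -> None:
        if self.series and time <= self.series[-1][0]:
            raise MeshError("tracked times must be strictly increasing")
        self.series.append((time, angle))


def cell_angle_at_junction(t: Tessellation, cid: int, jid: int) -> float:
    """Interior angle (degrees) of a cell at one of its junctions."""
    cyc = t.cells[cid]
    if jid not in cyc:
        raise MeshError(f"junction {jid} is not on cell {cid}")
    n = len(cyc)
    i = cyc.index(jid)
    p = np.asarray(t.junctions[jid])
    prev = np.asarray(t.junctions[cyc[(i - 1) % n]])
    nxt = np.asarray(t.junctions[cyc[(i + 1) % n]])
    ang = math.degrees(math.atan2(*(prev - p)[::-1]) - math.atan2(*(nxt - p)[::-1]))
    return ang % 360.0


def new_neighbor_angle(t: Tessellation, event, which: int = 0) -> float:
    """Angle formed in the neighbour cell at a newly created junction.

    Immediately after a straight wall is split this is 180°; relaxation
    then carries it toward 120° at the configured rate.
    """
    if not event.new_junctions:
        raise MeshError("event created no junction (vertex-anchored cut)")
    jid = event.new_junctions[which]
    if jid not in t.junctions:
        raise MeshError(f"junction {jid} is not in the mesh")
    cells = t.inc.junction_cells.get(jid, set())
    neighbors = sorted(cells - set(event.daughters))
    if not neighbors:
        raise MeshError(f"junction {jid} has no neighbour cell "
                        "(the cut wall was on the sheet boundary)")
    return cell_angle_at_junction(t, neighbors[0], jid)


def angle_decrease_rate(series: TrackedAngle) -> float:
    """Magnitude of the least-squares slope of angle vs time, degrees/day."""
    pts = series.series if isinstance(series, TrackedAngle) else list(series)
    if len(pts) < 2:
        raise MeshError("need at least 2 time points")
    times = np.array([p[0] for p in pts], dtype=float)
    angles = np.array([p[1] for p in pts], dtype=float)
    slope = np.polyfit(times, angles, 1)[0]
    return abs(float(slope))


# ----------------------------------------------------------------------
# the relaxation step
# ----------------------------------------------------------------------
def _junction_angle_dev(t: Tessellation, inc, jid: int) -> tuple[float, float]:
    """(sum of squared deviations, max |deviation|) of the angles at jid."""
    x, y = t.junctions[jid]
    dirs = sorted(math.atan2(t.junctions[k][1] - y, t.junctions[k][0] - x)
                  for k in inc.junction_neighbors[jid])
    d = len(dirs)
    tgt = 2 * math.pi / d
    e = 0.0
    worst = 0.0
    for i in range(d):
        a = (dirs[(i + 1) % d] - dirs[i]) % (2 * math.pi)
        dev = a - tgt
        e += dev * dev
        worst = max(worst, abs(dev))
    return e, math.degrees(worst)


def _local_energy(t: Tessellation, inc, jids) -> float:
    e = 0.0
    for j in jids:
        if j in inc.boundary_junctions:
            continue
        e += _junction_angle_dev(t, inc, j)[0]
    return e


def relax(t: Tessellation, params: RelaxationParams, duration: float,
          tracked: list[TrackedAngle] | None = None,
          now: float = 0.0) -> Tessellation:
    """Relax junction positions for ``duration`` days (in place).

    Interior junctions (all incident walls shared by two cells) descend
    the angular-deviation energy; each junction's step is sized so its
    largest angular deviation shrinks by ``rate × timestep`` per step.
    """
    if duration <= 0:
        return t
    if params.rate == 0:
        if tracked:
            for tr in tracked:
                tr.append(now + duration,
                          cell_angle_at_junction(t, tr.cell, tr.junction))
        return t
    steps = max(1, round(duration / params.timestep))
    dt = duration / steps
    for _ in range(steps):
        now += dt
        inc = t.inc
        movable = []
        for j in sorted(t.junctions):
            if j in inc.boundary_junctions or len(inc.junction_walls.get(j, ())) < 3:
                continue
            if params.age_gate and now - t.junction_birth.get(j, -math.inf) > params.window:
                continue
            movable.append(j)
        for j in movable:
            _relax_junction(t, inc, j, params, dt)
        if tracked:
            for tr in tracked:
                if tr.series and now <= tr.series[-1][0]:
                    continue
                if tr.cell in t.cells and tr.junction in t.cells[tr.cell]:
                    tr.append(now, cell_angle_at_junction(t, tr.cell, tr.junction))
    return t


def _relax_junction(t: Tessellation, inc, j: int, params: RelaxationParams,
                    dt: float) -> None:
    hood = [j] + list(inc.junction_neighbors[j])
    e0 = _local_energy(t, inc, hood)
    _, dev0 = _junction_angle_dev(t, inc, j)
    if dev0 < 1e-7:
        return
    x0, y0 = t.junctions[j]
    old_len = {k: math.hypot(t.junctions[k][0] - x0, t.junctions[k][1] - y0)
               for k in inc.junction_neighbors[j]}
    scale = np.mean([math.hypot(t.junctions[k][0] - x0, t.junctions[k][1] - y0)
                     for k in inc.junction_neighbors[j]])
    h = max(1e-6, 1e-5 * scale)

    def energy_at(x: float, y: float) -> float:
        t.junctions[j] = (x, y)
        e = _local_energy(t, inc, hood)
        return e

    gx = (energy_at(x0 + h, y0) - energy_at(x0 - h, y0)) / (2 * h)
    gy = (energy_at(x0, y0 + h) - energy_at(x0, y0 - h)) / (2 * h)
    t.junctions[j] = (x0, y0)
    gnorm = math.hypot(gx, gy)
    if gnorm < 1e-14:
        return
    ux, uy = -gx / gnorm, -gy / gnorm

    target = max(0.0, dev0 - params.rate * dt)

    def dev_at(s: float) -> float:
        t.junctions[j] = (x0 + s * ux, y0 + s * uy)
        d = _junction_angle_dev(t, inc, j)[1]
        return d

    s_hi = params.max_step
    if dev_at(s_hi) > target:
        s = s_hi                      # cannot reach the target this step
    else:
        lo, hi = 0.0, s_hi
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if dev_at(mid) > target:
                lo = mid
            else:
                hi = mid
        s = hi
    t.junctions[j] = (x0, y0)

    for _ in range(8):
        xn, yn = x0 + s * ux, y0 + s * uy
        t.junctions[j] = (xn, yn)
        ok = _local_energy(t, inc, hood) <= e0 + 1e-12
        if ok:
            # rigid walls: a move may not squeeze any incident wall below
            # the wall thickness (pre-existing short walls may only grow)
            for k, lo in old_len.items():
                ln = math.hypot(t.junctions[k][0] - xn, t.junctions[k][1] - yn)
                if ln < lo and ln <= params.min_wall_length:
                    ok = False
                    break
        if ok:
            for cid in inc.junction_cells.get(j, ()):
                coords = t.cell_coords(cid)
                if shoelace_area(coords) <= 0 or not Polygon(coords).is_valid:
                    ok = False
                    break
        if ok:
            return                    # move accepted
        t.junctions[j] = (x0, y0)
        s *= 0.5
    t.junctions[j] = (x0, y0)         # give up: reject the move entirely
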