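"""Simulation driver for thallus development: point → line → plane.

Development is reproduced in three stages.  A single quadrilateral founder
cell (the germinated spore) first divides transversely — cuts perpendicular
to the apical–basal axis — building a linear file of 4–10 cells; the sheet
then proliferates in two dimensions under the cleavage-plane rule, with
uniform isotropic growth and post-division wall reorientation interleaved
at every timestep.  Divisions are restricted to the dark half of the day
by default, as observed.

Division scheduling is size-triggered: a cell becomes eligible when its
area exceeds ``division_area_threshold`` and the largest eligible cell
divides first, which keeps the area distribution homogeneous (growth and
proliferation are uniform across the sheet).  The sheet is a closed system
otherwise: no cell death, no rearrangement, neighbour relations change
only through division.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .division import DivisionError, DivisionEvent, DivisionRule, divide_cell
from .mesh import MeshError, Tessellation, cell_sides, interior_cells, shoelace_area
from .relaxation import RelaxationParams, TrackedAngle, relax

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "run_simulation",
    "grow_cells",
    "triangle_prevalence",
    "mature_config",
]


@dataclass
class SimulationConfig:
    """Seeded configuration of one in-silico thallus.

    growth_rate is the relative area increase per day; cells divide when
    their area exceeds ``division_area_threshold`` (µm²).  Exactly one stop
    condition must be set: a total-cell target, an interior-cell target, a
    division budget, or a duration in days.
    """

    seed: int = 0
    growth_rate: float = 0.4
    division_area_threshold: float = 150.0
    threshold_jitter: float = 0.1       # per-cell lognormal sd on the threshold
    growth_axis: str = "both"           # "both" (isotropic) or "y" (filament)
    founder_width: float = 10.0
    founder_height: float = 14.0
    linear_stage_cells: int | None = None      # sampled uniformly in [4, 10]
    rule: DivisionRule = field(default_factory=DivisionRule)
    relaxation: RelaxationParams = field(default_factory=RelaxationParams)
    relax_enabled: bool = True
    final_relax_days: float | None = None      # defaults to relaxation.window
    stop_cells: int | None = None
    stop_interior_cells: int | None = None
    stop_divisions: int | None = None
    stop_days: float | None = None
    night_division: bool = True
    cell_selection: str = "largest_area"       # or "uniform"
    timestep: float = 0.1
    snapshot_every_divisions: int | None = None
    track_new_angles: bool = False

    def validate(self) -> None:
        if self.growth_rate <= 0:
            raise MeshError("growth_rate must be > 0")
        if self.division_area_threshold <= 0:
            raise MeshError("division_area_threshold must be > 0")
        if self.linear_stage_cells is not None and not 4 <= self.linear_stage_cells <= 10:
            raise MeshError("linear_stage_cells must be in [4, 10]")
        stops = [self.stop_cells, self.stop_interior_cells,
                 self.stop_divisions, self.stop_days]
        if all(s is None for s in stops):
            raise MeshError("set at least one stop condition")
        if any(s is not None and s <= 0 for s in stops):
            raise MeshError("stop conditions must be > 0")
        if self.cell_selection not in ("largest_area", "uniform"):
            raise MeshError(f"unknown cell_selection {self.cell_selection!r}")
        if self.timestep <= 0:
            raise MeshError("timestep must be > 0")


@dataclass
class Trajectory:
    """Time-ordered record of one simulation run."""

    config: SimulationConfig
    snapshots: list[tuple[float, Tessellation]] = field(default_factory=list)
    events: list[DivisionEvent] = field(default_factory=list)
    tracked: list[TrackedAngle] = field(default_factory=list)
    euler_series: list[tuple[float, int, int, int]] = field(default_factory=list)

    @property
    def final(self) -> Tessellation:
        return self.snapshots[-1][1]

    @property
    def times(self) -> list[float]:
        return [s[0] for s in self.snapshots]


def grow_cells(t: Tessellation, dt: float, growth_rate: float,
               axis: str = "both") -> Tessellation:
    """Uniform growth: scale positions so every cell's area grows by the
    relative rate ``growth_rate·dt``.

    ``axis="both"`` is isotropic (shape-preserving, the sheet stage);
    ``axis="y"`` elongates along the apical–basal axis only (the filament
    stage, where the cell file extends lengthwise between transverse
    divisions).
    """
    if dt < 0:
        raise MeshError("dt must be >= 0")
    if axis not in ("both", "y"):
        raise MeshError(f"unknown growth axis {axis!r}")
    if dt == 0:
        return t
    g = 1.0 + growth_rate * dt
    sx, sy = (math.sqrt(g), math.sqrt(g)) if axis == "both" else (1.0, g)
    for j, (x, y) in t.junctions.items():
        t.junctions[j] = (x * sx, y * sy)
    return t


def mature_config(seed: int, stop_interior_cells: int = 500) -> SimulationConfig:
    """Study conditions for a mature sheet: the default cleavage rule with
    wall reorientation relaxed to steady state between divisions (the age
    gate off lets every junction keep reorienting, which is what "mature,
    relaxed" means for a sheet observed long after its divisions)."""
    return SimulationConfig(
        seed=seed,
        stop_interior_cells=stop_interior_cells,
        relax_enabled=True,
        relaxation=RelaxationParams(age_gate=False),
    )


def _is_night(time: float) -> bool:
    return (time % 1.0) >= 0.5


def _founder(cfg: SimulationConfig) -> Tessellation:
    t = Tessellation(meta={"units": "um", "seed": cfg.seed})
    w, h = cfg.founder_width, cfg.founder_height
    a = t.add_junction(0.0, 0.0)
    b = t.add_junction(w, 0.0)
    c = t.add_junction(w, h)
    d = t.add_junction(0.0, h)
    t.add_cell([a, b, c, d])
    return t


def _transverse_pair(t: Tessellation, cid: int) -> tuple[int, int]:
    """The two walls most parallel to the apical–basal (y) axis."""
    cyc = t.cells[cid]
    n = len(cyc)
    scored = []
    for i in range(n):
        (x1, y1), (x2, y2) = t.junctions[cyc[i]], t.junctions[cyc[(i + 1) % n]]
        dx, dy = x2 - x1, y2 - y1
        scored.append((abs(dy) / max(math.hypot(dx, dy), 1e-12),
                       t.wall_between(cyc[i], cyc[(i + 1) % n])))
    scored.sort(reverse=True)
    return (scored[0][1], scored[1][1])


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one seeded thallus simulation; deterministic given the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = _founder(config)
    traj = Trajectory(config=config)
    traj.snapshots.append((0.0, t.copy()))
    f, e, v = t.counts
    traj.euler_series.append((0.0, f, e, v))

    linear_target = (config.linear_stage_cells
                     if config.linear_stage_cells is not None
                     else int(rng.integers(4, 11)))
    areas: dict[int, float] = {cid: t.cell_area(cid) for cid in t.cells}

    def draw_threshold() -> float:
        # cell cycles are heterogeneous: each cell commits to division at
        # its own size, lognormal around the configured threshold
        if config.threshold_jitter <= 0:
            return config.division_area_threshold
        return config.division_area_threshold * math.exp(
            config.threshold_jitter * rng.standard_normal())

    thresholds: dict[int, float] = {cid: draw_threshold() for cid in t.cells}
    time = 0.0
    n_div = 0
    n_interior = 0

    def stopped() -> bool:
        if config.stop_cells is not None and len(t.cells) >= config.stop_cells:
            return True
        if (config.stop_interior_cells is not None
                and n_interior >= config.stop_interior_cells):
            return True
        if config.stop_divisions is not None and n_div >= config.stop_divisions:
            return True
        if config.stop_days is not None and time >= config.stop_days:
            return True
        return False

    if stopped():
        return traj

    dt = config.timestep
    while True:
        time += dt
        grow_cells(t, dt, config.growth_rate, axis=config.growth_axis)
        g2 = 1.0 + config.growth_rate * dt
        for cid in areas:
            areas[cid] *= g2

        if (not config.night_division) or _is_night(time):
            skip: set[int] = set()
            while not stopped():
                eligible = [cid for cid, a in areas.items()
                            if a > thresholds[cid] and cid not in skip]
                if not eligible:
                    break
                if config.cell_selection == "largest_area":
                    cid = max(eligible, key=lambda c: (areas[c], c))
                else:
                    cid = int(rng.choice(sorted(eligible)))
                linear = len(t.cells) < linear_target
                pair = _transverse_pair(t, cid) if linear else None
                try:
                    _, ev = divide_cell(t, cid, config.rule, rng,
                                        pair=pair, time=time)
                except DivisionError:
                    skip.add(cid)
                    continue
                traj.events.append(ev)
                n_div += 1
                del areas[cid]
                del thresholds[cid]
                for d in ev.daughters:
                    areas[d] = t.cell_area(d)
                    thresholds[d] = draw_threshold()
                f, e, v = t.counts
                traj.euler_series.append((time, f, e, v))
                n_interior = len(interior_cells(t))
                if config.track_new_angles and ev.new_junctions:
                    _track_event(t, traj, ev, time)
                if (config.snapshot_every_divisions
                        and n_div % config.snapshot_every_divisions == 0):
                    traj.snapshots.append((time, t.copy()))

        if config.relax_enabled:
            relax(t, config.relaxation, dt, traj.tracked, now=time - dt)
        if stopped():
            break

    if config.relax_enabled:
        cooldown = (config.final_relax_days
                    if config.final_relax_days is not None
                    else config.relaxation.window)
        if cooldown > 0:
            relax(t, config.relaxation, cooldown, traj.tracked, now=time)
            time += cooldown
    traj.snapshots.append((time, t.copy()))
    return traj


def _track_event(t: Tessellation, traj: Trajectory, ev: DivisionEvent,
                 time: float) -> None:
    from .relaxation import cell_angle_at_junction
    jid = ev.new_junctions[0]
    cells = t.inc.junction_cells.get(jid, set())
    neighbors = sorted(cells - set(ev.daughters))
    if not neighbors:
        return
    tr = TrackedAngle(junction=jid, cell=neighbors[0])
    tr.append(time, cell_angle_at_junction(t, neighbors[0], jid))
    traj.tracked.append(tr)


def triangle_prevalence(traj: Trajectory, min_side_length: float = 1.0) -> float:
    """Fraction of interior-cell observations with 3 counted sides,
    pooled over all stored snapshots."""
    seen = 0
    tri = 0
    for _, t in traj.snapshots:
        for cid in interior_cells(t):
            seen += 1
            if cell_sides(t, cid, min_side_length) == 3:
                tri += 1
    return tri / seen if seen else 0.0
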