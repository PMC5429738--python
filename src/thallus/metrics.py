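"""Quantification pipeline: distributions, summary statistics and
tessellation-law fits for a sheet or a whole trajectory.

All cell-level statistics are computed over *interior* cells only (cells
completely surrounded by other cells) with the 1 µm side-counting
threshold, mirroring how segmented micrographs are quantified.  The module
also evaluates the three classical tessellation laws — Euler's law
(F − E + V = 1), Lewis' law (mean area of n-sided cells linear in n) and
the Aboav–Weaire law (n·m(n) linear in n, with m(n) the mean side number
of the neighbours of n-sided cells) — and compares a report against the
benchmark intervals measured on real thalli.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .division import DivisionEvent
from .mesh import (MeshError, Tessellation, cell_sides, interior_angles,
                   interior_cells)

__all__ = [
    "MetricsReport",
    "AngleSummary",
    "LawFit",
    "DivisionStats",
    "PAPER_BENCHMARKS",
    "side_distribution",
    "angle_distribution",
    "mean_interior_angle_identity",
    "lewis_fit",
    "aboav_weaire_fit",
    "division_statistics",
    "report",
    "benchmarks_table",
]

# Benchmark intervals measured on mature (>= 0.08 cm) thalli: mean side
# number, mean intracellular angle (degrees), fraction of 5-7-sided cells,
# fraction of angles in [100, 140] degrees, fraction of 3-fold junctions.
PAPER_BENCHMARKS: dict[str, tuple[float, float]] = {
    "mean_sides": (5.72, 5.97),
    "mean_angle": (112.0, 119.0),
    "frac_sides_5_7": (0.90, 1.0),
    "frac_angles_100_140": (0.60, 1.0),
    "junction_3fold_frac": (0.99, 1.0),
}


@dataclass
class AngleSummary:
    histogram: dict[float, float]        # bin lower edge (deg) -> fraction
    mean: float
    frac_in: float
    lo: float
    hi: float
    n: int


@dataclass
class LawFit:
    slope: float
    intercept: float
    r2: float
    classes: dict[int, float]            # n -> class statistic fitted


@dataclass
class DivisionStats:
    n_events: int
    ds_mean: float
    ds_sd: float
    sr_mean: float
    sr_sd: float
    interval_histogram: dict[int, float]
    unconnected_frac: float
    sr_frac_07_1: float
    frac_interval_1_2: float


@dataclass
class MetricsReport:
    n_interior_cells: int
    side_histogram: dict[int, float]
    mean_sides: float
    angle_histogram: dict[float, float]
    mean_angle: float
    frac_angles_100_140: float
    frac_sides_5_7: float
    junction_3fold_frac: float
    lewis: LawFit | None
    aboav: LawFit | None
    division: DivisionStats | None
    length_class: str
    angle_identity_mean: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_interior_cells", self.n_interior_cells),
            ("mean_sides", self.mean_sides),
            ("frac_sides_5_7", self.frac_sides_5_7),
            ("mean_angle", self.mean_angle),
            ("frac_angles_100_140", self.frac_angles_100_140),
            ("junction_3fold_frac", self.junction_3fold_frac),
            ("length_class", self.length_class),
        ]
        if self.lewis is not None:
            rows += [("lewis_slope", self.lewis.slope),
                     ("lewis_r2", self.lewis.r2)]
        if self.aboav is not None:
            rows += [("aboav_slope", self.aboav.slope)]
        if self.division is not None:
            rows += [("ds_mean", self.division.ds_mean),
                     ("sr_mean", self.division.sr_mean),
                     ("unconnected_frac", self.division.unconnected_frac)]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _interior_or_raise(t: Tessellation) -> list[int]:
    cells = sorted(interior_cells(t))
    if not cells:
        raise MeshError(f"no interior cells (mesh has {len(t.cells)} cells, "
                        "all touching the boundary)")
    return cells


def side_distribution(t: Tessellation, min_side_length: float = 1.0
                      ) -> tuple[dict[int, float], float]:
    """Histogram (fractions) and mean of counted side numbers of interior
    cells.  On a periodic mesh every cell is interior and sides are raw."""
    cells = _interior_or_raise(t)
    if t.periodic:
        ns = [len(t.cells[c]) for c in cells]
    else:
        ns = [cell_sides(t, c, min_side_length) for c in cells]
    counts = Counter(ns)
    total = len(ns)
    return ({n: c / total for n, c in sorted(counts.items())},
            float(np.mean(ns)))


def angle_distribution(t: Tessellation, lo: float = 100.0, hi: float = 140.0,
                       bin_width: float = 10.0, bin_lo: float = 40.0,
                       bin_hi: float = 180.0,
                       min_side_length: float = 1.0) -> AngleSummary:
    """Per-vertex interior angles of interior cells, binned; the fraction
    within [lo, hi] is reported alongside the mean."""
    cells = _interior_or_raise(t)
    # cells whose counted polygon degenerates (< 3 counted sides) are
    # unmeasurable, like ambiguous outlines in a micrograph; skip them
    per_cell = []
    for c in cells:
        try:
            per_cell.append(interior_angles(t, c, min_side_length))
        except MeshError:
            continue
    if not per_cell:
        raise MeshError("no measurable interior cells")
    angles = np.concatenate(per_cell)
    edges = np.arange(bin_lo, bin_hi + bin_width, bin_width)
    hist, _ = np.histogram(np.clip(angles, bin_lo, bin_hi - 1e-9), bins=edges)
    frac = hist / hist.sum()
    return AngleSummary(
        histogram={float(edges[i]): float(frac[i]) for i in range(len(frac))},
        mean=float(np.mean(angles)),
        frac_in=float(np.mean((angles >= lo) & (angles <= hi))),
        lo=lo, hi=hi, n=len(angles))


def mean_interior_angle_identity(t: Tessellation,
                                 min_side_length: float = 1.0) -> float:
    """Mean interior angle via the polygon angle-sum identity.

    Every n-gon's angles sum to (n−2)·180°, so the tissue mean over
    interior cells is 180°·(1 − 2·F_int/Σn_int); it must equal direct
    averaging of all angles, providing a second computation route.
    """
    cells = _interior_or_raise(t)
    # same measurable set as angle_distribution: counted polygons with >= 3
    # sides (degenerate cells are unmeasurable either way)
    ns = [n for n in (cell_sides(t, c, min_side_length) for c in cells)
          if n >= 3]
    if not ns:
        raise MeshError("no measurable interior cells")
    return 180.0 * (1.0 - 2.0 * len(ns) / sum(ns))


def _class_means(t: Tessellation, min_side_length: float, min_cells: int
                 ) -> tuple[dict[int, list[int]], dict[int, float]]:
    cells = _interior_or_raise(t)
    by_n: dict[int, list[int]] = defaultdict(list)
    for c in cells:
        by_n[cell_sides(t, c, min_side_length)].append(c)
    kept = {n: cs for n, cs in by_n.items() if len(cs) >= min_cells}
    return by_n, {n: float(np.mean([t.cell_area(c) for c in cs]))
                  for n, cs in kept.items()}


def _fit_line(xs, ys) -> tuple[float, float, float]:
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def lewis_fit(t: Tessellation, min_side_length: float = 1.0,
              min_cells_per_class: int = 5) -> LawFit:
    """Least-squares line of class-mean cell area against side number n."""
    _, means = _class_means(t, min_side_length, min_cells_per_class)
    if len(means) < 3:
        raise MeshError(
            f"Lewis fit needs >= 3 side classes with >= {min_cells_per_class} "
            f"cells; got classes {sorted(means)}")
    ns = sorted(means)
    slope, intercept, r2 = _fit_line(ns, [means[n] for n in ns])
    return LawFit(slope, intercept, r2, means)


def neighbor_mean_sides(t: Tessellation, min_side_length: float = 1.0,
                        min_cells_per_class: int = 5) -> dict[int, float]:
    """m(n): mean counted sides of the neighbours of n-sided interior cells."""
    cells = _interior_or_raise(t)
    inc = t.inc
    sides_of = {c: cell_sides(t, c, min_side_length) for c in t.cells}
    by_n: dict[int, list[float]] = defaultdict(list)
    for c in cells:
        cyc = t.cells[c]
        nbrs = set()
        for i in range(len(cyc)):
            w = t.wall_between(cyc[i], cyc[(i + 1) % len(cyc)])
            for other in inc.wall_cells[w]:
                if other != c:
                    nbrs.add(other)
        by_n[sides_of[c]].append(float(np.mean([sides_of[x] for x in nbrs])))
    return {n: float(np.mean(v)) for n, v in by_n.items()
            if len(v) >= min_cells_per_class}


def aboav_weaire_fit(t: Tessellation, min_side_length: float = 1.0,
                     min_cells_per_class: int = 5) -> LawFit:
    """Least-squares line of n·m(n) against n."""
    m = neighbor_mean_sides(t, min_side_length, min_cells_per_class)
    if len(m) < 3:
        raise MeshError(
            f"Aboav-Weaire fit needs >= 3 side classes with >= "
            f"{min_cells_per_class} cells; got classes {sorted(m)}")
    ns = sorted(m)
    slope, intercept, r2 = _fit_line(ns, [n * m[n] for n in ns])
    return LawFit(slope, intercept, r2, m)


def division_statistics(events: list[DivisionEvent]) -> DivisionStats:
    """Pooled division-symmetry statistics over an event log."""
    if not events:
        raise MeshError("empty division log")
    ds = np.array([d for e in events for d in e.ds_values])
    sr = np.array([e.sr for e in events])
    intervals = Counter(e.interval_sides for e in events)
    total = len(events)
    return DivisionStats(
        n_events=total,
        ds_mean=float(ds.mean()), ds_sd=float(ds.std(ddof=1)) if len(ds) > 1 else 0.0,
        sr_mean=float(sr.mean()), sr_sd=float(sr.std(ddof=1)) if total > 1 else 0.0,
        interval_histogram={k: v / total for k, v in sorted(intervals.items())},
        unconnected_frac=sum(v for k, v in intervals.items() if k > 0) / total,
        sr_frac_07_1=float(np.mean((sr >= 0.7) & (sr <= 1.0))),
        frac_interval_1_2=sum(v for k, v in intervals.items() if k in (1, 2)) / total,
    )


def report(obj, length_class_split: int = 100,
           min_side_length: float = 1.0) -> MetricsReport:
    """Full metrics report for a Tessellation or a Trajectory.

    ``length_class_split`` maps interior-cell count to the two length
    classes ("short"/"long"), standing in for the thallus-length split
    used when binning micrographs.
    """
    events = None
    if hasattr(obj, "snapshots"):                 # Trajectory
        t = obj.final
        events = obj.events
    else:
        t = obj
    side_hist, mean_sides = side_distribution(t, min_side_length)
    n_int = len(interior_cells(t))
    if t.periodic:
        ang = AngleSummary({}, float("nan"), float("nan"), 100, 140, 0)
        j3 = float("nan")
        identity = float("nan")
    else:
        ang = angle_distribution(t, min_side_length=min_side_length)
        from .mesh import junction_degrees
        deg = junction_degrees(t, interior_only=True)
        tot = sum(deg.values())
        j3 = deg.get(3, 0) / tot if tot else float("nan")
        identity = mean_interior_angle_identity(t, min_side_length)
    try:
        lw = lewis_fit(t, min_side_length)
    except MeshError:
        lw = None
    try:
        ab = aboav_weaire_fit(t, min_side_length)
    except MeshError:
        ab = None
    div = division_statistics(events) if events else None
    return MetricsReport(
        n_interior_cells=n_int,
        side_histogram=side_hist,
        mean_sides=mean_sides,
        angle_histogram=ang.histogram,
        mean_angle=ang.mean,
        frac_angles_100_140=ang.frac_in,
        frac_sides_5_7=sum(f for n, f in side_hist.items() if 5 <= n <= 7),
        junction_3fold_frac=j3,
        lewis=lw, aboav=ab, division=div,
        length_class="long" if n_int >= length_class_split else "short",
        angle_identity_mean=identity)


def benchmarks_table(rep: MetricsReport) -> pd.DataFrame:
    """Compare a report against the measured benchmark intervals."""
    rows = []
    values = {
        "mean_sides": rep.mean_sides,
        "mean_angle": rep.mean_angle,
        "frac_sides_5_7": rep.frac_sides_5_7,
        "frac_angles_100_140": rep.frac_angles_100_140,
        "junction_3fold_frac": rep.junction_3fold_frac,
    }
    for name, (lo, hi) in PAPER_BENCHMARKS.items():
        v = values[name]
        rows.append((name, v, f"[{lo}, {hi}]",
                     bool(not math.isnan(v) and lo <= v <= hi)))
    return pd.DataFrame(rows, columns=["metric", "value",
                                       "paper_reference_interval", "pass"])
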