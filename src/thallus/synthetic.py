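"""Synthetic segmented-cell fixtures.

Real input to the quantification pipeline is a set of cell outlines traced
from light micrographs of a gap-free single-layer sheet.  This module
fabricates such datasets with known ground truth so that every pipeline
stage is testable without microscopy data: regular lattices, perturbed
Voronoi mosaics (jittered triangular seeds, the classical generator of
hexagon-dominated mosaics), and full growth-simulation outputs.
Measurement error is emulated by jittering *junction* positions — shared
vertices, as produced by a shared-boundary segmentation — so noisy
fixtures remain gap-free by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .mesh import (MeshError, Tessellation, build_honeycomb, cell_sides,
                   interior_angles, interior_cells, shoelace_area, validate)

__all__ = ["FixtureSpec", "make_fixture", "add_measurement_noise"]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic segmented-cell dataset.

    ``noise_sd`` is the measurement jitter (µm) applied to junction
    positions; ``seed_jitter`` (fraction of the seed spacing) controls how
    irregular a perturbed-Voronoi mosaic is, 0 giving exact hexagons.
    """

    source: str = "perturbed_voronoi"     # simulation | perturbed_voronoi | lattice
    n_cells: int = 100
    noise_sd: float = 0.0
    seed: int = 0
    include_boundary: bool = True
    planted: dict | None = None
    cell_size: float = 10.0               # characteristic cell scale, µm
    seed_jitter: float = 0.15

    def validate(self) -> None:
        if self.source not in ("simulation", "perturbed_voronoi", "lattice"):
            raise MeshError(f"unknown fixture source {self.source!r}")
        if self.n_cells < 1:
            raise MeshError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise MeshError("noise_sd must be >= 0")
        if self.planted:
            unknown = set(self.planted) - {"mean_sides"}
            if "lewis_slope" in self.planted:
                raise MeshError(
                    "planted lewis_slope is infeasible: no closed construction "
                    "yields a gap-free tiling with prescribed class-mean areas")
            if unknown:
                raise MeshError(f"unknown planted keys {sorted(unknown)}")
            if self.planted.get("mean_sides") not in (None, 6):
                raise MeshError("only mean_sides = 6 (hexagonal lattice) "
                                "can be planted exactly")


def make_fixture(spec: FixtureSpec) -> tuple[Tessellation, dict]:
    """Build a fixture tessellation plus its ground-truth record.

    Ground truth (side counts, angle mean, interior count) is measured on
    the noise-free mesh before measurement jitter is applied.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.source == "lattice" or (spec.planted or {}).get("mean_sides") == 6:
        rings = 0
        while 1 + 3 * rings * (rings + 1) < spec.n_cells:
            rings += 1
        t = build_honeycomb(rings, side_length=spec.cell_size)
    elif spec.source == "perturbed_voronoi":
        t = _voronoi_sheet(spec, rng)
    else:
        from .growth import SimulationConfig, run_simulation
        cfg = SimulationConfig(seed=spec.seed, stop_cells=spec.n_cells,
                               snapshot_every_divisions=None)
        t = run_simulation(cfg).final
    truth = _ground_truth(t, spec)
    if spec.noise_sd > 0:
        add_measurement_noise(t, spec.noise_sd, rng)
    t.meta.update({"seed": spec.seed, "source": spec.source,
                   "noise_sd": spec.noise_sd})
    return t, truth


def _ground_truth(t: Tessellation, spec: FixtureSpec) -> dict:
    interior = sorted(interior_cells(t))
    sides = {c: cell_sides(t, c) for c in interior}
    angles = (np.concatenate([interior_angles(t, c) for c in interior])
              if interior else np.array([]))
    return {
        "spec": asdict(spec),
        "n_cells": len(t.cells),
        "n_interior": len(interior),
        "sides": sides,
        "mean_sides": float(np.mean(list(sides.values()))) if sides else float("nan"),
        "mean_angle": float(angles.mean()) if len(angles) else float("nan"),
    }


def _voronoi_sheet(spec: FixtureSpec, rng: np.random.Generator) -> Tessellation:
    """Voronoi mosaic of a jittered triangular seed grid, keeping only the
    cells of an interior core so every kept region is finite and bounded."""
    s = spec.cell_size
    # core size: a core of m x m seeds yields ~m^2 cells
    m = max(1, math.isqrt(spec.n_cells - 1) + 1)
    pad = 3                                   # guard rows so core regions close
    pts = []
    core_idx = []
    h = s * math.sqrt(3) / 2
    for j in range(-pad, m + pad):
        for i in range(-pad, m + pad):
            x = s * (i + 0.5 * (j % 2))
            y = h * j
            jitter = spec.seed_jitter * s * rng.standard_normal(2)
            pts.append((x + jitter[0], y + jitter[1]))
            if 0 <= i < m and 0 <= j < m:
                core_idx.append(len(pts) - 1)
    vor = Voronoi(np.array(pts))
    t = Tessellation(meta={"units": "um", "source": "perturbed_voronoi"})
    vid_map: dict[int, int] = {}

    def jid(v: int) -> int:
        if v not in vid_map:
            vid_map[v] = t.add_junction(*vor.vertices[v])
        return vid_map[v]

    for p in core_idx:
        region = vor.regions[vor.point_region[p]]
        if -1 in region or not region:
            continue
        # order region vertices counterclockwise around the seed
        seed = vor.points[p]
        region = sorted(region, key=lambda v: math.atan2(
            vor.vertices[v][1] - seed[1], vor.vertices[v][0] - seed[0]))
        t.add_cell([jid(v) for v in region])
    if not t.cells:
        raise MeshError("Voronoi fixture produced no bounded core cells")
    return t


def add_measurement_noise(t: Tessellation, noise_sd: float,
                          rng: np.random.Generator,
                          side_threshold: float = 1.0) -> Tessellation:
    """Jitter junction positions by isotropic Gaussian noise (in place).

    Noise applies to shared junctions, so the tiling stays gap-free; a
    draw that would fold one of the incident cells, or flip a wall across
    the side-counting threshold (digitization error does not create or
    destroy sides), is re-drawn (bounded), then dropped.
    """
    if noise_sd < 0:
        raise MeshError("noise_sd must be >= 0")
    if noise_sd == 0:
        return t
    inc = t.inc

    def wall_len(a: int, b: int) -> float:
        (xa, ya), (xb, yb) = t.junctions[a], t.junctions[b]
        return math.hypot(xa - xb, ya - yb)

    for j in sorted(t.junctions):
        x0, y0 = t.junctions[j]
        nbrs = inc.junction_neighbors.get(j, [])
        was_side = {k: wall_len(j, k) > side_threshold for k in nbrs}
        for _ in range(8):
            dx, dy = noise_sd * rng.standard_normal(2)
            t.junctions[j] = (x0 + dx, y0 + dy)
            ok = all((wall_len(j, k) > side_threshold) == was_side[k]
                     for k in nbrs)
            if ok:
                for cid in inc.junction_cells.get(j, ()):
                    coords = t.cell_coords(cid)
                    if shoelace_area(coords) <= 0 or not Polygon(coords).is_valid:
                        ok = False
                        break
            if ok:
                break
            t.junctions[j] = (x0, y0)
        else:
            t.junctions[j] = (x0, y0)
    return t
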