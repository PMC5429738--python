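"""File formats: tessellation JSON, GeoJSON export, CSV logs, TOML config.

The tessellation JSON schema is::

    {"junctions": [{"id", "x", "y", "birth"?}],
     "walls":     [{"id", "j1", "j2"}],
     "cells":     [{"id", "walls": [ordered wall ids]}],
     "meta":      {"units": "um", "periodic": bool, ...}}

Round-tripping write ∘ read is the identity on the data model.  Schema
violations are reported with a JSON-pointer-style path to the offending
element.  GeoJSON export emits one Polygon feature per cell with side
count, area, interior flag and angle list, ready for GIS-style viewers.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import sys
import tomllib
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .division import DivisionEvent, DivisionRule
from .growth import SimulationConfig
from .mesh import MeshError, Tessellation, cell_sides, interior_angles, interior_cells
from .relaxation import RelaxationParams, TrackedAngle

__all__ = [
    "SchemaError",
    "tessellation_to_dict", "tessellation_from_dict",
    "write_tessellation", "read_tessellation",
    "to_geojson", "write_geojson",
    "events_to_frame", "write_events_csv",
    "angles_to_frame", "write_angles_csv",
    "load_config", "config_to_dict",
    "write_manifest",
]


class SchemaError(MeshError):
    """Schema violation in an input file, with a JSON-pointer location."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


# ----------------------------------------------------------------------
# tessellation JSON
# ----------------------------------------------------------------------
def tessellation_to_dict(t: Tessellation) -> dict:
    junctions = []
    for j in sorted(t.junctions):
        x, y = t.junctions[j]
        rec = {"id": j, "x": x, "y": y}
        birth = t.junction_birth.get(j, float("-inf"))
        if math.isfinite(birth):
            rec["birth"] = birth
        junctions.append(rec)
    walls = [{"id": w, "j1": t.walls[w][0], "j2": t.walls[w][1]}
             for w in sorted(t.walls)]
    cells = []
    for c in sorted(t.cells):
        cyc = t.cells[c]
        n = len(cyc)
        wids = [t.wall_between(cyc[i], cyc[(i + 1) % n]) for i in range(n)]
        cells.append({"id": c, "walls": wids})
    meta = dict(t.meta)
    meta["periodic"] = t.periodic
    return {"junctions": junctions, "walls": walls, "cells": cells, "meta": meta}


def tessellation_from_dict(d: dict) -> Tessellation:
    for key in ("junctions", "walls", "cells"):
        if key not in d:
            raise SchemaError(f"/{key}", "missing required array")
    meta = dict(d.get("meta", {}))
    periodic = bool(meta.pop("periodic", False))
    t = Tessellation(periodic=periodic, meta=meta)
    for i, rec in enumerate(d["junctions"]):
        for f in ("id", "x", "y"):
            if f not in rec:
                raise SchemaError(f"/junctions/{i}/{f}", "missing field")
        try:
            t.add_junction(float(rec["x"]), float(rec["y"]), jid=int(rec["id"]),
                           birth=float(rec.get("birth", float("-inf"))))
        except MeshError as err:
            raise SchemaError(f"/junctions/{i}", str(err)) from err
    wall_ends: dict[int, tuple[int, int]] = {}
    for i, rec in enumerate(d["walls"]):
        for f in ("id", "j1", "j2"):
            if f not in rec:
                raise SchemaError(f"/walls/{i}/{f}", "missing field")
        j1, j2 = int(rec["j1"]), int(rec["j2"])
        for f, j in (("j1", j1), ("j2", j2)):
            if j not in t.junctions:
                raise SchemaError(f"/walls/{i}/{f}",
                                  f"wall {rec['id']} references unknown junction {j}")
        try:
            t._ensure_wall(j1, j2, wid=int(rec["id"]))
        except MeshError as err:
            raise SchemaError(f"/walls/{i}", str(err)) from err
        wall_ends[int(rec["id"])] = (j1, j2)
    for i, rec in enumerate(d["cells"]):
        for f in ("id", "walls"):
            if f not in rec:
                raise SchemaError(f"/cells/{i}/{f}", "missing field")
        wids = [int(w) for w in rec["walls"]]
        if len(wids) < 3:
            raise SchemaError(f"/cells/{i}/walls", "cell needs >= 3 walls")
        for k, w in enumerate(wids):
            if w not in wall_ends:
                raise SchemaError(f"/cells/{i}/walls/{k}",
                                  f"cell {rec['id']} references unknown wall {w}")
        cyc = _chain_walls(wids, wall_ends, f"/cells/{i}/walls")
        try:
            t.add_cell(cyc, cid=int(rec["id"]), ensure_ccw=not periodic)
        except MeshError as err:
            raise SchemaError(f"/cells/{i}", str(err)) from err
    return t


def _chain_walls(wids: list[int], ends: dict[int, tuple[int, int]],
                 pointer: str) -> list[int]:
    """Recover the junction cycle from an ordered wall list."""
    first, second = set(ends[wids[0]]), set(ends[wids[1]])
    shared = first & second
    if len(shared) != 1:
        raise SchemaError(pointer, "first two walls do not chain")
    start = (first - shared).pop()
    cyc = [start]
    cur = start
    for k, w in enumerate(wids):
        a, b = ends[w]
        if cur == a:
            cur = b
        elif cur == b:
            cur = a
        else:
            raise SchemaError(f"{pointer}/{k}",
                              f"wall {w} does not continue the cycle at junction {cur}")
        if k < len(wids) - 1:
            cyc.append(cur)
    if cur != start:
        raise SchemaError(pointer, "wall cycle does not close")
    return cyc


def write_tessellation(t: Tessellation, path) -> None:
    Path(path).write_text(json.dumps(tessellation_to_dict(t), indent=1))


def read_tessellation(path) -> Tessellation:
    return tessellation_from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# GeoJSON
# ----------------------------------------------------------------------
def to_geojson(t: Tessellation, min_side_length: float = 1.0) -> dict:
    interior = interior_cells(t)
    features = []
    for c in sorted(t.cells):
        coords = t.cell_coords(c)
        ring = [[float(x), float(y)] for x, y in coords] + [[float(coords[0][0]),
                                                             float(coords[0][1])]]
        try:
            angles = [float(a) for a in interior_angles(t, c, min_side_length)]
        except MeshError:
            angles = []
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "cell_id": c,
                "sides": cell_sides(t, c, min_side_length),
                "area_um2": t.cell_area(c),
                "interior": c in interior,
                "angles_deg": angles,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(t: Tessellation, path) -> None:
    Path(path).write_text(json.dumps(to_geojson(t)))


# ----------------------------------------------------------------------
# CSV logs
# ----------------------------------------------------------------------
def events_to_frame(events: list[DivisionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        ds = list(e.ds_values)
        rows.append({
            "mother_id": e.mother,
            "n_sides_before": e.n_sides_before,
            "interval_sides": e.interval_sides,
            "f1": e.cut_fractions[0], "f2": e.cut_fractions[1],
            "ds1": ds[0], "ds2": ds[1] if len(ds) > 1 else float("nan"),
            "sr": e.sr, "time": e.time,
        })
    return pd.DataFrame(rows, columns=["mother_id", "n_sides_before",
                                       "interval_sides", "f1", "f2",
                                       "ds1", "ds2", "sr", "time"])


def write_events_csv(events: list[DivisionEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def angles_to_frame(tracked: list[TrackedAngle]) -> pd.DataFrame:
    rows = [{"junction_id": tr.junction, "cell_id": tr.cell,
             "time_days": tm, "angle_deg": ang}
            for tr in tracked for tm, ang in tr.series]
    return pd.DataFrame(rows, columns=["junction_id", "cell_id",
                                       "time_days", "angle_deg"])


def write_angles_csv(tracked: list[TrackedAngle], path) -> None:
    angles_to_frame(tracked).to_csv(path, index=False)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
_RULE_FIELDS = {f.name for f in dataclasses.fields(DivisionRule)}
_RELAX_FIELDS = {f.name for f in dataclasses.fields(RelaxationParams)}
_CFG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from TOML.  Top-level keys mirror the
    config fields; [rule] and [relaxation] tables hold the sub-configs.
    Unknown keys are errors (fail fast)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    rule_kw = data.pop("rule", {})
    relax_kw = data.pop("relaxation", {})
    for name, got, allowed in (("", data, _CFG_FIELDS - {"rule", "relaxation"}),
                               ("rule.", rule_kw, _RULE_FIELDS),
                               ("relaxation.", relax_kw, _RELAX_FIELDS)):
        unknown = set(got) - allowed
        if unknown:
            raise MeshError(f"unknown config key(s): "
                            f"{', '.join(name + k for k in sorted(unknown))}")
    if "fixed_pair" in rule_kw and rule_kw["fixed_pair"] is not None:
        rule_kw["fixed_pair"] = tuple(rule_kw["fixed_pair"])
    return SimulationConfig(rule=DivisionRule(**rule_kw),
                            relaxation=RelaxationParams(**relax_kw), **data)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return dataclasses.asdict(cfg)


def write_manifest(out_dir, seed, config: dict | None = None,
                   inputs: list | None = None, outputs: list | None = None) -> Path:
    """Write the run manifest recording seed, config hash and paths."""
    cfg = config or {}
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "tool": "thallus",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "config": cfg,
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "argv": sys.argv,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
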