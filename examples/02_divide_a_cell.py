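"""Divide the centre cell of a honeycomb and audit the bookkeeping.

A tricellular division adds one cell, three walls and two 3-fold
junctions, and raises the total per-cell side count by exactly six: each
daughter keeps part of the mother's boundary plus the new shared wall,
and the two neighbours across the cut walls each gain one side.
"""
import numpy as np

import thallus as th

t = th.build_honeycomb(2)
center = min(t.cells, key=lambda c: float(np.hypot(*t.cell_centroid(c))))
rng = np.random.default_rng(0)

f0, e0, v0 = t.counts
sides0 = sum(len(cyc) for cyc in t.cells.values())
t, event = th.divide_cell(t, center, th.DivisionRule(), rng)
f1, e1, v1 = t.counts

print(f"cells   {f0} -> {f1}  (+{f1 - f0})")
print(f"walls   {e0} -> {e1}  (+{e1 - e0})")
print(f"junctions {v0} -> {v1}  (+{v1 - v0})")
print(f"sum of per-cell sides: +{sum(len(c) for c in t.cells.values()) - sides0}")
print(f"interval sides between the cut pair: {event.interval_sides} "
      f"(0 would mean a connected pair)")
print(f"division sections: {[round(d, 3) for d in event.ds_values]} "
      f"(0 = exact midpoint cut)")
print(f"size ratio of daughters: {event.sr:.3f} (1 = equal areas)")
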