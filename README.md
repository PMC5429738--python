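# thallus

Growth simulation and packing-geometry metrics for flat, single-cell-layer
sheets of walled cells.

Bladed red algae such as *Pyropia* build their thallus from one layer of
polygonal cells that tile the plane with no gaps.  Because the cells are
caged by rigid walls, neighbour relations change only through division, so
the whole tessellation is shaped by two controls: where the mitotic
cleavage plane goes, and how walls reorient around the new junctions
afterwards.  `thallus` implements both as a simulation, plus the full
quantification pipeline used on segmented micrographs, so that measured
and simulated sheets can be compared statistic by statistic.

The core objects and statistics, in the field's notation:

- a **tessellation** of junctions (V), walls (E) and cells (F) obeying
  Euler's planar-patch law F − E + V = 1; a tiling whose junctions all
  have degree z averages 2z/(z−2) sides per cell, hence the hexagonal
  limit n̄ → 6 for 3-fold junctions;
- **division section** DS = |S1/(S1+S2) − 1/2| (0 = midpoint cut) and
  **size ratio** SR = As/Ab (1 = equal daughters), the two cleavage
  symmetry statistics, plus the **interval sides** separating the
  transected pair (0 = connected pair);
- a division rule that transects unconnected paired sides so as to halve
  the cell (with the observed 0.6% connected-pair exception), each
  tricellular division adding +1 cell, +3 walls and +6 counted sides;
- **wall reorientation** relaxing new 180° angles at 20°/day over ~2 days
  toward the 120° of regular hexagonal packing;
- the tessellation laws: Lewis (mean area of n-sided cells linear in n)
  and Aboav–Weaire (n·m(n) linear in n, m(n) the mean sides of the
  neighbours of n-sided cells), and the random-cleavage null models
  (uniform pair 2/(n−1); IUR chord 2 − 2cos(π/n)).

## A worked example

```python
import thallus as th
from thallus.growth import mature_config
from thallus.metrics import benchmarks_table, report

traj = th.run_simulation(mature_config(seed=1, stop_interior_cells=300))
rep = report(traj)
print(f"mean sides {rep.mean_sides:.2f}, mean angle {rep.mean_angle:.1f}")
print(benchmarks_table(rep).to_string(index=False))
```

prints (exact numbers are seed-dependent but deterministic per seed):

```
mean sides 5.93, mean angle 119.3
             metric      value paper_reference_interval  pass
         mean_sides   5.933333             [5.72, 5.97]  True
         mean_angle 119.325843           [112.0, 119.0] False
     frac_sides_5_7   0.813333               [0.9, 1.0] False
frac_angles_100_140   0.729775               [0.6, 1.0]  True
junction_3fold_frac   1.000000              [0.99, 1.0]  True
```

Reading it: a sheet grown from a single cell to 300 interior cells under
the equal-division rule with wall reorientation ends with a mean side
number of 5.93 — the hexagonal limit forced by Euler's law once all
junctions are 3-fold — and a mean interior angle within half a degree of
the 120° hexagon angle.  The benchmark column shows the intervals
measured on real mature thalli: angle concentration and junction folds
are reproduced; the simulated 5–7-sided fraction (81%) stays below the
90% counted in real tissue, a known gap of division-only models that the
methods note discusses.

More narrative scripts live in `examples/` (lattices and laws, a single
audited division, a full simulation, null models, noisy-fixture
recovery).  A thin CLI wraps the same library:

```sh
thallus simulate --config cfg.toml --out run/
thallus analyze --in run/snapshot_0001.json --out report.csv
thallus null-model --n 6 --model iur_chord
thallus fixtures --spec spec.toml --out fixtures/
thallus laws --in run/snapshot_0001.json
```

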