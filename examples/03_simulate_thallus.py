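"""Simulate thallus development from a single cell and report the
packing geometry of the mature sheet.

The run goes point -> line (a transversely dividing file of 4-10 cells)
-> plane (2D proliferation under the equal-division cleavage rule with
nightly divisions and wall reorientation at 20 degrees/day).  The mature
sheet is then quantified the way segmented micrographs are: interior
cells only, sides counted with the 1 µm threshold.
"""
import thallus as th
from thallus.growth import mature_config
from thallus.metrics import benchmarks_table, report

traj = th.run_simulation(mature_config(seed=1, stop_interior_cells=300))
t = traj.final

print(f"{len(traj.events)} divisions -> {len(t.cells)} cells "
      f"({len(th.interior_cells(t))} interior)")
rep = report(traj)
print(f"mean sides {rep.mean_sides:.2f}, mean angle {rep.mean_angle:.1f} deg "
      f"(identity route: {rep.angle_identity_mean:.1f})")
print("\nbenchmark comparison (intervals measured on real mature thalli):")
print(benchmarks_table(rep).to_string(index=False))
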