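"""Generate a synthetic segmented-cell dataset and recover its ground
truth through the metrics pipeline under measurement noise.

The fixture is a perturbed Voronoi mosaic (jittered triangular seeds) —
a stand-in for cell outlines traced from a micrograph.  Gaussian jitter
on the shared junctions emulates digitization error; because junctions
are shared, the tiling stays gap-free, and side counts survive exactly.
"""
import thallus as th
from thallus.synthetic import FixtureSpec, make_fixture

for noise in (0.0, 0.1, 0.5):
    t, truth = make_fixture(FixtureSpec(source="perturbed_voronoi",
                                        n_cells=80, seed=7, noise_sd=noise))
    rep = th.report(t)
    print(f"noise {noise:.1f} µm: mean sides {rep.mean_sides:.3f} "
          f"(truth {truth['mean_sides']:.3f}), "
          f"mean angle {rep.mean_angle:.2f} (truth {truth['mean_angle']:.2f}), "
          f"angles in [100,140]: {rep.frac_angles_100_140:.1%}")

print("\nNote: the tissue-mean angle is exactly 180·(1 − 2F/Σn) by the "
      "angle-sum identity,\nso it is invariant under any noise that "
      "preserves side counts — only the spread moves.")
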