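"""Build reference lattices and check the tessellation laws on them.

Euler's law for a planar patch (outer face excluded) says
cells − walls + junctions = 1, and a lattice whose junctions all have
degree z must average 2z/(z−2) sides per cell: 6, 4 and 3 for the
hexagonal, square and triangular tilings.
"""
import thallus as th

patch = th.build_honeycomb(1)
f, e, v = patch.counts
print(f"7-cell honeycomb: F={f} E={e} V={v} -> F-E+V = {th.euler_characteristic(patch)}")

for kind in ("hexagonal", "square", "triangular"):
    torus = th.build_lattice(kind, 4, 4, periodic=True)
    (z,) = th.junction_degrees(torus)
    _, mean = th.side_distribution(torus)
    print(f"{kind:11s} torus: junction degree {z}, mean sides {mean:.1f} "
          f"(uniform-degree limit 2z/(z-2) = {2 * z / (z - 2):.1f})")
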