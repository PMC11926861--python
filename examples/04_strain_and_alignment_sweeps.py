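"""The two diagnostic sweeps: molecular strain vs molecular alignment.

Generates a synthetic per-strain tensor table for the Gly/Pro/Hyp
carbonyls, then computes composite (1:1:1) sideband intensity ratios
(i) across strain at fixed alignment c/a = 10 and (ii) across alignment
at fixed tensors, and prints the monotone-trend diagnostic for each.
"""

import numpy as np

from orimas import (
    CompositeSpec,
    SpectrometerConfig,
    SyntheticSpec,
    alignment_sweep,
    force_to_stress,
    make_strain_tensor_table,
    strain_sweep,
)

cfg = SpectrometerConfig()
points = make_strain_tensor_table(SyntheticSpec())

print("force -> stress on a 1.5 nm triple helix:")
for p in points:
    print(f"  {p.force_pN:6.0f} pN -> {force_to_stress(p.force_pN):7.1f} MPa "
          f"(molecular strain {p.strain_pct:4.1f} %)")

sw_strain = strain_sweep(points, CompositeSpec(), cfg, grid_n=2000, seed=1)
sw_align = alignment_sweep(points[0].tensors, [1, 2, 5, 10], CompositeSpec(),
                           cfg, grid_n=2000, seed=1)

print("\nstrain sweep (c/a = 10 fixed), ratios vs 0% strain:")
print("  strain%  " + "  ".join(f"N={n:+d}" for n in (-3, -2, -1, 1, 2, 3)))
for i, s in enumerate(sw_strain.sweep_values):
    row = [sw_strain.ratios[i, sw_strain.indices == n][0] for n in (-3, -2, -1, 1, 2, 3)]
    print(f"  {s:6.1f}  " + "  ".join(f"{r:4.2f}" for r in row))

print("\nalignment sweep (tensors fixed), ratios vs c/a = 1:")
print("  c/a      " + "  ".join(f"N={n:+d}" for n in (-3, -2, -1, 1, 2, 3)))
for i, c in enumerate(sw_align.sweep_values):
    row = [sw_align.ratios[i, sw_align.indices == n][0] for n in (-3, -2, -1, 1, 2, 3)]
    print(f"  {c:6.1f}  " + "  ".join(f"{r:4.2f}" for r in row))

print(f"\nmonotone fraction (|N| <= 3): strain sweep "
      f"{sw_strain.monotone_fraction(3):.2f}, alignment sweep "
      f"{sw_align.monotone_fraction(3):.2f}")
print(f"<P2> across alignment sweep: "
      + ", ".join(f"{p:.3f}" for p in sw_align.order_parameters))
# Increasing alignment moves the sideband/centerband ratios smoothly and
# monotonically, whereas strain-driven tensor changes move some sidebands
# up and others down - the signature that separates the two mechanisms.
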