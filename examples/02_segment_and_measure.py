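"""Segment a phantom's wall layers and quantify the morphometry.

Runs the full protocol — axial bilateral filter, lumen spline, unwrapping,
wall threshold, vertical opening, Gaussian-mixture edge model, weighted
geodesic boundary, 3D surface smoothing, re-wrapping — and compares the
recovered layers against the known ground truth.
"""

import numpy as np

from vesselseg import (PhantomSpec, build_morphometry_table,
                       make_vessel_phantom, segment_volume)

spec = PhantomSpec(image_shape=(16, 256, 256), seed=7)
tomogram, truth = make_vessel_phantom(spec)
seg = segment_volume(tomogram)

pred, true = seg.labels, truth.labels
true_adv = (true == 3) | (true == 4)  # pores belong to the adventitial layer
for name, a, b in [("media", pred == 2, true == 2), ("adventitia", pred == 3, true_adv)]:
    d = 2 * (a & b).sum() / (a.sum() + b.sum())
    print(f"{name} Dice vs ground truth: {d:.3f}")

table, meta = build_morphometry_table(seg, tomogram)
print(f"\nper-slice means over {meta['slice_count']} slices "
      f"(axial length {meta['axial_length_um']} um):")
print(f"  media thickness  {table.media_thickness_um.mean():6.2f} um "
      f"(truth {truth.true_metrics.media_thickness_um[0]:.2f})")
print(f"  advent. thickness {table.adventitia_thickness_um.mean():5.2f} um "
      f"(truth {truth.true_metrics.adventitia_thickness_um[0]:.2f})")
print(f"  lumen CSA        {table.lumen_csa_um2.mean():8.0f} um^2 "
      f"(truth {truth.true_metrics.lumen_csa_um2[0]:.0f})")
print(f"  pores: {meta['pore_count']} found, {meta['pore_total_volume_um3']:.0f} um^3 "
      f"(truth {truth.total_pore_volume_um3:.0f})")
# Dice near 1 and thickness/CSA agreement within a few percent show the
# texture-based boundary extraction is recovering the true layer geometry.
# With noise present the pore threshold (paraffin mean - 3 SD) is
# deliberately conservative, so recovered pore volume underestimates the
# truth; on noiseless data it is accurate to a few percent.
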