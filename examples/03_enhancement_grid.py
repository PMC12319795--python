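"""Forward model: how much does MT preparation boost the VAPER contrast?

Maps functional CBF/CBV changes to the fractional change of the
steady-state MT/DANTE ratio, with MT preparation on versus off (the
original VAPER), over the typical activation ranges.
"""

import numpy as np

import mtvaper as mv
from mtvaper.contrast import condition_signal_changes

model = mv.default_model()
protocol = mv.AcquisitionProtocol()

change = mv.FunctionalChange(d_cbf=0.75, d_cbv=0.4)
parts = condition_signal_changes(model, protocol, change)
print("Functional change: CBF +75%, CBV +40%")
print(f"  DANTE-volume signal change: {parts['dante']:+.2%}  (CBV pushes the "
      "blood-nulled signal down)")
print(f"  MT-volume signal change:    {parts['mt']:+.2%}  (inflow and "
      "volume push the tissue-suppressed signal up)")
print(f"  MT-VAPER contrast:          {parts['vaper']:+.2%}  (unified direction)")

e = mv.mt_enhancement(model, protocol, change)
print(f"  enhancement over MT-off VAPER: {e:+.1%}")

cbf = [0.50, 0.625, 0.75, 0.875, 1.0]
cbv = [0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60]
grid = mv.enhancement_grid(model, protocol, cbf, cbv) * 100

print("\nMT enhancement (%) over CBF (rows) x CBV (columns):")
print("        " + "  ".join(f"{v:5.0%}" for v in cbv))
for f, row in zip(cbf, grid):
    print(f"CBF {f:4.0%} " + "  ".join(f"{x:5.1f}" for x in row))
print(f"\ngrid minimum {grid.min():.1f}%, maximum {grid.max():.1f}% "
      "(the predicted 15-35% boost; largest where CBV dominates)")
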