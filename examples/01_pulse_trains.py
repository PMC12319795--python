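"""Preparation pulse trains: blood nulling by DANTE, tissue saturation by MT.

Propagates both trains pulse by pulse on the four-compartment gray-matter
voxel and prints the compartment magnetizations, the number of pulses DANTE
needs to stabilize flowing blood, the velocity response, and the saturation
band of the binomial MT train.
"""

import numpy as np

import mtvaper as mv
from mtvaper.physiology import VoxelState
from mtvaper.prep_trains import (
    dante_propagate,
    dante_steady_state_pulses,
    dante_velocity_response,
    mt_frequency_response,
    mt_propagate,
)

model = mv.default_model()
dante = mv.default_dante_train()
mt = mv.default_mt_train()

res = dante_propagate(VoxelState(), model, dante, 1780)
print("After 1780 DANTE pulses (one volume TR):")
for name, v in res.final.mz.items():
    print(f"  mz[{name:9s}] = {v:6.3f}")
print("  -> flowing blood is crushed to a few percent, tissue is spared,")
print("     capillary sits in between (diluted by nulled arteriolar inflow)")

n = dante_steady_state_pulses(model, dante, tol_fraction=0.05)
print(f"\nDANTE pulses to stabilize flowing blood within 5%: {n} "
      "(expected in the 200-300 range)")

print("\nDANTE steady-state attenuation vs blood velocity (26 mT/m, 1 ms):")
for v in (0.0, 0.5, 1.0, 2.0, 5.0):
    att = dante_velocity_response(v, model, dante)
    print(f"  v = {v:4.1f} mm/s -> attenuation {att:5.1%}")

res_mt = mt_propagate(VoxelState(), model, mt, 3060)
print("\nAfter 3060 binomial MT pulses (one volume TR):")
for name, v in res_mt.final.mz.items():
    print(f"  mz[{name:9s}] = {v:6.3f}")
print(f"  mz[mp pool  ] = {res_mt.final.mz_mp:6.3f}")
print("  -> the macromolecular pool is saturated and drags tissue water")
print("     down through exchange; arteriolar blood is barely touched")

offsets = np.arange(0.0, 5001.0, 10.0)
att = mt_frequency_response(offsets, mt)
print(f"\nMT train saturation band: attenuation at 0 Hz = {att[0]:.2e}, "
      f"maximal at {offsets[np.argmax(att)]:.0f} Hz "
      "(the 1/(2 tau) sideband of the 0.2 ms alternating train)")
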