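"""The interleaved DANTE/MT 3D-EPI acquisition at voxel level.

Simulates a gray-matter voxel through alternating DANTE (blood-nulled) and
MT (tissue-suppressed) volumes to the periodic steady state and prints the
per-condition signals and compartment magnetizations at each k-space
center.  The MT/DANTE signal ratio is the quantity the VAPER contrast is
built from.
"""

import mtvaper as mv

model = mv.default_model()
protocol = mv.AcquisitionProtocol(n_volume_pairs=6)

print(f"volume TR {protocol.volume_tr} s, effective TR "
      f"{mv.effective_tr(protocol)} s, {protocol.n_segments} EPI segments, "
      f"{protocol.dante_pulses_per_volume()} DANTE / "
      f"{protocol.mt_pulses_per_volume()} MT pulses per volume")

series = mv.simulate_series(model, protocol)
print("\npair   DANTE signal   MT signal   MT/DANTE")
for k, (sd, sm) in enumerate(zip(series.dante_signal, series.mt_signal)):
    print(f"{k:4d}   {sd:.6f}      {sm:.6f}   {sm / sd:.4f}")
print(f"steady state reached: {series.converged}")

n = protocol.n_segments
center = n // 2
for name in ("arteriole", "capillary", "venule", "tissue"):
    tr = series.compartment_traces[name]
    print(f"mz[{name:9s}]  DANTE k-center {tr[-2 * n + center]:6.3f}   "
          f"MT k-center {tr[-n + center]:6.3f}")
print("-> arteriolar blood is dark in the DANTE volume and bright in the MT")
print("   volume (fresh inflow after the arterial transit time), while")
print("   tissue is darker under MT: the two contrasts move oppositely.")

s_d, s_m = mv.steady_state_pair(model, protocol)
print(f"\nsteady-state signals: DANTE {s_d:.6f}, MT {s_m:.6f} "
      f"(a GM voxel is dominated by suppressed tissue, so S_MT < S_DANTE)")
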