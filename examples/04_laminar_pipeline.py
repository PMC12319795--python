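"""Laminar analysis pipeline on a ground-truthed synthetic dataset.

Generates an interleaved block-design acquisition on a curved cortical
ribbon with a planted double-peak VAPER response (superficial input + deep
output) and a surface-weighted BOLD-like response, then runs the full
pipeline: censoring, VAPER series, percent-change GLM, equi-volume
layering, and depth profiles with Gaussian peak fits.
"""

import numpy as np

from mtvaper.contrast import vaper_series
from mtvaper.laminar import (
    build_design,
    censor_mask,
    compute_depth,
    depth_profile,
    pair_keep_mask,
    percent_change_glm,
    profile_peak,
    split_interleaved,
)
from mtvaper.synth import SynthSpec, make_interleaved_dataset

spec = SynthSpec(seed=7, noise_sd=0.5, motion_spike_volumes=(21,))
ds = make_interleaved_dataset(spec)
print(f"synthetic run: {ds.data.shape[-1]} volumes, planted VAPER peaks at "
      f"depths {spec.vaper_peak_depths}, BOLD-like surface ramp, "
      f"{spec.noise_sd}% noise, motion spike at volume 21")

inter = split_interleaved(ds.data, ds.labels)
keep = pair_keep_mask(censor_mask(ds.motion))
print(f"censoring kept {keep.sum()}/{keep.size} VAPER time points")

X = build_design(ds.pair_boxcar, ds.effective_tr, convolve=False)
vap = vaper_series(inter)
beta, tstat = percent_change_glm(vap.reshape(vap.shape[0], -1), X, keep)
vaper_map = beta.reshape(vap.shape[1:])[..., 0]

beta_mt, _ = percent_change_glm(inter.mt.reshape(inter.mt.shape[0], -1), X,
                                keep & censor_mask(ds.motion)[1::2])
mt_map = beta_mt.reshape(vap.shape[1:])[..., 0]

layers = compute_depth(ds.rim, n_layers=18)
vprof = depth_profile(vaper_map, layers)
mprof = depth_profile(mt_map, layers)

print("\nlayer  depth   VAPER %   MT-BOLD %")
for k in range(18):
    print(f"{k + 1:4d}   {vprof.centers[k]:.3f}   {vprof.mean[k]:7.2f}   "
          f"{mprof.mean[k]:7.2f}")

m = vprof.mean
peaks = sorted((k for k in range(1, 17)
                if m[k] > m[k - 1] and m[k] > m[k + 1]), key=lambda k: -m[k])[:2]
found = sorted(round(float(vprof.centers[k]), 3) for k in peaks)
print(f"\nVAPER profile local maxima at depths {found} "
      f"(planted: {sorted(spec.vaper_peak_depths)})")
print(f"MT-BOLD Gaussian peak depth: {profile_peak(mprof):.3f} "
      "(surface-biased, as for a draining-vein-dominated contrast)")
print("-> the VAPER profile resolves both planted laminar responses while")
print("   the MT-only (BOLD-dominated) profile ramps toward the surface.")
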