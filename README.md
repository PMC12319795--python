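# mtvaper

Bloch simulation and laminar fMRI analysis for **MT-enhanced VAPER** contrast
— the integrated VASO (blood-volume) + perfusion contrast in which a
magnetization-transfer (MT) tissue-suppressed condition replaces the control
condition of the original VAPER acquisition.

## The problem and who this is for

Laminar (cortical-depth-resolved) fMRI needs contrasts that localize to the
activated parenchyma rather than to draining veins.  CBV- and CBF-weighted
contrasts do this, but with low sensitivity.  The MT–VAPER scheme alternates
two preparations around a segmented 3D-EPI readout at 7 T:

- **DANTE volumes** — trains of low-flip (9°) hard pulses with interleaved
  gradients crush spins moving faster than ~2 mm/s, nulling arteriolar and
  venular blood while sparing static tissue (a VASO-like, CBV-sensitive
  state);
- **MT volumes** — long alternating binomial trains (±11°, 0.2 ms spacing,
  gradients off) saturate macromolecular protons, which suppresses tissue
  water through two-pool exchange while fresh inflowing blood is spared (an
  inverse-VASO state that is CBV- *and* CBF-sensitive).

The contrast time series divides each MT volume by the mean of its two
neighbouring DANTE volumes,

&nbsp;&nbsp;&nbsp;&nbsp;VAPER\_k = MT\_k / mean(DANTE\_k, DANTE\_{k+1}),

which cancels the shared BOLD T2\* weighting and any static multiplicative
field.  A CBV increase moves the DANTE signal down and the MT signal up; a
CBF increase moves the MT signal up — all three effects add in the ratio.

This package is for imaging physicists and layer-fMRI methodologists who
want to (1) simulate the preparation trains and the interleaved acquisition
on a four-compartment vascular model (arteriole, capillary, venule, tissue
plus a macromolecular pool), (2) forward-model how functional ΔCBF/ΔCBV map
to VAPER signal change and how much MT boosts it, and (3) run the laminar
analysis pipeline (motion censoring, percent-change GLM, equi-volume
layering into 18 depths, profile extraction, Gaussian peak fitting) —
validated end to end on ground-truthed synthetic data.

## Worked example

```python
import mtvaper as mv

model = mv.default_model()                  # 7 T GM voxel, 5.5 mL/100 g blood
protocol = mv.AcquisitionProtocol()         # 9°/1 ms DANTE, ±11°/0.2 ms MT,
                                            # TE 18.3 ms, volume TR 4.27 s

s_dante, s_mt = mv.steady_state_pair(model, protocol)
change = mv.FunctionalChange(d_cbf=0.75, d_cbv=0.4)
contrast = mv.vaper_contrast(model, protocol, change)
boost = mv.mt_enhancement(model, protocol, change)
print(f"{s_dante:.4f} {s_mt:.4f} {contrast:.4f} {boost:.3f}")
```

prints

```
0.0636 0.0521 0.0588 0.285
```

i.e. at the periodic steady state the blood-nulled volume reads 0.0636 and
the tissue-suppressed volume 0.0521 (arbitrary units; tissue dominates a GM
voxel, so the MT volume is darker); a +75% CBF / +40% CBV activation changes
the MT/DANTE ratio by +5.9%; and switching the MT preparation on boosts that
contrast by 28.5% over the original (MT-off) VAPER — inside the predicted
15–35% band.  The `examples/` scripts walk through each capability (pulse
trains, interleaved acquisition, enhancement grid, laminar pipeline) and
print annotated output; a thin CLI (`mtvaper simulate|contrast|grid|
pipeline|synth`) wraps the same functions for shell use.

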