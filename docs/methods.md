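# Methods

## The voxel model

A gray-matter parenchyma voxel is modeled as four water compartments —
arteriole, capillary, venule, extravascular tissue — plus a macromolecular
proton (MP) pool coupled to tissue water.  Longitudinal magnetization is
normalized per compartment (equilibrium M0 = 1 for each pool); volume
fractions enter only at readout, where the voxel signal is

S = Σ_c f_c · mz_c · sin(α_exc) · exp(−TE / T2*_c).

Between instantaneous pulse events the five-pool state obeys a linear ODE
combining:

- T1 recovery of every pool toward 1;
- arteriole → capillary → venule turnover (incoming blood carries the
  upstream compartment's current magnetization) at first-order rates;
- capillary ↔ tissue water exchange at a permeability rate, with the
  back-reaction on tissue scaled by the capillary/tissue volume ratio;
- tissue ↔ MP exchange with MP→water rate k and water→MP rate
  k·F, F = mp_fraction / (1 − mp_fraction) (detailed balance);
- optionally, replacement of arteriolar blood by fresh (fully relaxed)
  blood at the refresh rate.

Every inter-event interval is integrated exactly with the matrix
exponential of the homogeneous 6×6 affine system, and a train of n
identical pulses is composed into a single matrix power, so whole-series
simulations are exact (to machine precision, given the model) and fast.

## Preparation trains

**DANTE.** Each pulse multiplies the longitudinal magnetization of flowing
compartments (velocity above the crushing cutoff, gradients on) by
cos α; the transverse magnetization is assumed fully spoiled by the
inter-pulse gradients.  Static tissue is ideally preserved (the
alternating-polarity train refocuses static spins); an optional per-pulse
tissue saturation factor (default 1) can reproduce slow residual decay.
The capillary is below the cutoff and escapes direct crushing; it is
suppressed indirectly because the arteriolar blood flowing into it is
nulled.  The flowing-compartment trajectory has the closed form
M_ss + (M0 − M_ss)(E1 cos α)^n with M_ss = (1 − E1)/(1 − E1 cos α),
E1 = exp(−τ/T1); tests require agreement to 1e−9.  With the defaults
(9°, τ = 1 ms, blood T1 = 2.1 s) the first pulse count within 0.05 of M_ss
is 230, in the expected 200–300 stabilization range.

The velocity response maps velocity to a per-pulse attenuation
interpolating linearly between 1 (zero accumulated inter-pulse phase) and
cos α (phase ≥ π/2), with the full-crushing cutoff calibrated to 2 mm/s at
the default 26 mT/m gradient and scaling inversely with gradient
amplitude.  This is a phenomenological transition shape: the underlying
physics fixes the endpoints and monotonicity, not the curve.

**Binomial MT.** Each pulse multiplies the MP pool by a per-pulse
saturation factor and leaves on-resonance water unrotated (the
ramped, alternating-polarity design cancels the net rotation); venules
additionally suffer a small configurable direct loss through their short
T2.  Tissue water is then dragged down between pulses through the
two-pool exchange — the cumulative mechanism that builds tissue
suppression over thousands of pulses while inflow-refreshed arteriolar
blood is spared.

The off-resonance response simulates full 3D rotations of an isolated
water spin: each 90 µs hard pulse is a rotation about the tilted effective
axis (ω1, 0, Δω), followed by free precession over the rest of the 0.2 ms
interval.  Attenuation is zero on resonance and maximal at 1/(2τ) =
2500 Hz.  The finite pulse width matters: with idealized instantaneous
rotations the response is double-horned around the sideband and its
maximum sits away from 2500 Hz, so the pulse duration is modeled
explicitly.  The strict 1/τ periodicity of the instantaneous-pulse picture
then holds only approximately (exactly at the nulls, e.g. 5000 Hz ≈ 0 Hz).

## Sequence scheduling

One volume TR holds one condition.  Every EPI segment occupies one period
of a uniform excitation grid, ordered [free gap, preparation train,
excitation]; a train longer than the period (the 100-pulse first DANTE
train) stretches its own segment, and the default spacing is chosen so one
DANTE + one MT volume span exactly 2 × volume TR — the protocol's 4.27 s
is the *average* volume TR, and the effective (pair) TR is exactly 8.54 s.
This layout makes an inert preparation literally equal to free evolution:
with DANTE gradients off and MT power zero both conditions produce
identical signals (exactly so when the DANTE train is segment-uniform;
within ~0.2% with the stretched first segment).

Signals are recorded at each volume's k-space center, taken as the middle
segment's excitation (centric-ordering assumption).  Excitation is an
instantaneous cos-factor on all water pools.

The arterial transit time (ATT, default 1.2 s) is measured from the end of
the preceding DANTE train; from that moment plus ATT, fresh blood refreshes
the arteriole exponentially at the CBF-scaled rate — but only while DANTE
is actually crushing (gradients on).  With gradients off nothing upstream
is ever nulled, so the refresh runs continuously in both conditions.  At
the defaults the DANTE-end→MT-k-center interval is ≈2.1 s; a warning (not
an error) is raised if the effective ATT reaches it, since perfusion
weighting then vanishes.

Steady state is detected when pair-to-pair signals change by less than a
relative tolerance (default 1e−10); convergence is independent of the
starting state to 1e−8 and typically takes ~10 pairs.

## Functional forward model and MT enhancement

A functional change (ΔCBF up to +200%, ΔCBV up to +60%, the
simulation-validated ranges) maps onto the model as: blood volume grows by
ΔCBV × baseline blood fraction at the expense of tissue volume (assigned
to the arteriole by default, configurable split with the capillary,
reflecting the arterial/arteriolar origin of activation CBV changes); all
turnover/refresh rates scale by (1 + ΔCBF); and the ATT divides by
(1 + ΔCBF) (on by default, switchable — the grid calibration below was
verified under the default setting).

The VAPER contrast of a change is the fractional change of the
steady-state MT/DANTE ratio between baseline and active states; it is zero
at the null change, positive for both ΔCBV and ΔCBF, and strictly
increasing in ΔCBV.  MT enhancement is contrast(MT on)/contrast(MT power
zero) − 1, where "MT power zero" sets the per-pulse MP saturation to 1 and
the venule direct loss to 0 (the original VAPER).

## Parameter choices and calibration

Compartment defaults (7 T): total blood 5.5 mL/100 g split 20/40/40 over
arteriole/capillary/venule; blood T1 2.1 s; T2* 22/18/7 ms for
arteriole/capillary/venule and 28 ms for tissue (venous T2* is short
enough that the venule contributes <10% of its TE = 0 signal at
TE = 18.3 ms); tissue T1 1.8 s.  Flow defaults: arteriole refresh 2 /s,
capillary turnover 0.8 /s, venule turnover 0.6 /s, capillary–tissue
permeability 1 /s — first-order rates of the order of mean velocity over
segment length for 50–200 µm vessels.  All are exposed in config.

Two-pool defaults: exchange rate k = 1.45 /s, MP R1 = 1 /s (within the
0.4–2 /s range), MP fraction 0.20, per-pulse MP saturation 0.99.  The last
two are the calibration pair of the MT preparation: the pulse power is
specified as a flip angle, not an absorbed-power lineshape, so the
per-pulse MP saturation cannot be derived from first principles.  They
were set once so that (a) tissue magnetization after one volume TR of MT
preparation falls at ~0.70 of equilibrium (within the intended 0.5–0.7
suppression window), and (b) the MT enhancement over the typical
activation grid (ΔCBF +50…100% × ΔCBV +25…60%) lies inside the predicted
15–35% band.  With these defaults the grid spans 27.5–29.3%, minimum in
the CBF-dominated corner and maximum in the CBV-dominated corner — the
expected orientation, though flatter than the full predicted band: the
model's enhancement is dominated by the tissue-suppression depth, which is
state-independent, while the CBF/CBV mix modulates it only weakly.

## Laminar pipeline

- **Censoring**: a volume is censored when the Euclidean norm of the
  backward difference of its six rigid-body parameters (rotations
  converted to mm on a 50 mm-radius sphere) exceeds 0.4 mm, or when ≥10%
  of voxels are outliers.  The first volume's derivative is zero.
  Censoring a DANTE or MT volume removes every VAPER point that uses it
  (MT_k, DANTE_k, DANTE_{k+1}).
- **GLM**: each voxel series is divided by its own temporal mean and
  scaled by 100, so the task beta reads in percent signal change.  The
  task boxcar is optionally convolved with a gamma-variate response
  (shape 6, scale 0.9 s, unit peak; toggleable to the raw boxcar);
  Legendre drift terms are included at order 1 + duration/150 s.  The fit
  is ordinary least squares, vectorized over voxels, with censored time
  points excluded; the t statistic uses the standard OLS variance.  A
  statsmodels fit serves as the independent oracle in tests, and on null
  data the empirical type-I rate matches the nominal α.
- **Equi-volume layering**: from a rim volume labeling the CSF border (1),
  WM border (2) and GM interior (3), equidistant depth is
  d_CSF/(d_CSF + d_WM) from Euclidean distance transforms.  The
  equi-volume correction estimates the local column curvature
  κ = −div(∇x/|∇x|) from the smoothed equidistant field (smoothing scale
  ≈ thickness/12, which suppresses distance-transform faceting), forms the
  relative boundary areas a_CSF = 1 + κ·d_CSF and a_WM = 1 − κ·d_WM, and
  reparameterizes depth as (2·a_CSF·x − (a_CSF − a_WM)·x²)/(a_CSF + a_WM)
  — the exact equal-volume map when the column cross-section varies
  linearly, which is exact for an annulus and reduces to equidistant depth
  for parallel planar boundaries.  On a 400×400 annulus the interior
  layers are equal-volume within 2% (equidistant binning errs by >10%);
  the outermost and innermost layers are truncated by the one-voxel rims
  and are excluded from that comparison.  Depth runs 0 (CSF) to 1 (WM);
  18 layers by default.
- **Profiles and peaks**: per-layer means over all ROI voxels without
  statistical thresholding, with across-voxel SEM; peak depth from a
  least-squares Gaussian + constant fit, mean clamped to [0, 1]; flat
  profiles raise instead of returning an arbitrary depth.

## Synthetic data

The generator emulates the block-design study conditions: rest 6 / active
8 volume TRs per trial (25.62 s / 34.16 s at the 4.27 s volume TR), 8
trials, alternating DANTE/MT volumes on a ribbon (flat slab or annulus)
with analytically known depth.  The default ribbon is a 64×64 annulus of
thickness 16 voxels, giving roughly one voxel per layer at 18 layers.  The
planted VAPER response is a double Gaussian across depth (peaks at 0.2 and
0.7, 2% amplitude, the motor-cortex input/output testbed pattern); the
BOLD-like response ramps from 4% at the surface to 0.5% at WM and
multiplies both volumes of a pair equally, so it cancels in the dynamic
division (exactly so wherever neighbouring pairs share the block state).
The task factor is the mean-centred pair boxcar, applied multiplicatively
and split between conditions — DANTE down, MT up — such that the MT/DANTE
ratio changes by exactly the planted percent amplitude; with the whole
modulation assigned to MT the planted amplitude equals the GLM beta
exactly on noiseless data, which is the closed-loop identity the tests
pin.  Noise is white Gaussian per volume (percent of baseline); motion is
a small random walk with scheduled spikes written directly into the motion
table (the images are not moved — the censoring logic, not registration,
is under test).

What passing these tests does *not* show about real data: no physiological
noise autocorrelation, no EPI artifacts or B0 distortion, no actual head
motion in the images, no partial-volume mixing beyond voxel binning, and a
BOLD nuisance that is exactly pair-synchronous — real BOLD fluctuates
within the 8.54 s effective TR, leaving residual BOLD in the VAPER series.

## Numerical notes and limitations

- Exact matrix exponentials make results step-size-free; the only
  integration tolerance in the package is the steady-state detection
  threshold.
- The spec of transverse coherence pathways during preparation (EPG),
  slice profiles, B1+/B0 inhomogeneity, and BOLD ΔT2* during activation
  are out of scope; B1 enters only as an optional flip-angle multiplier.
- The per-pulse MP saturation lumps lineshape, pulse power and duty cycle
  into one calibrated number; absolute tissue-suppression depths are
  therefore calibrated, not predicted.
- The equi-volume correction is first-order in curvature × thickness;
  strongly folded geometries (κ·T approaching 1) rely on the clipping of
  the area factors.
- Degenerate inputs: zero blood fraction, zero MT power and zero gradient
  amplitude are all valid limits and covered by tests; a flat depth
  profile or an all-censored run raises a descriptive error.
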