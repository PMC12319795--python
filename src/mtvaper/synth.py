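"""Ground-truthed synthetic interleaved DANTE/MT fMRI datasets.

The generator emulates a two-condition block-design acquisition on a small
cortical ribbon (flat slab or annulus) with analytically known depth:
alternating DANTE/MT volumes whose ratio carries a planted depth-dependent
VAPER response, a shared multiplicative BOLD-like modulation that is
identical within each pair (and therefore cancels in the dynamic division),
white Gaussian noise, and a motion table with scheduled spikes for the
censoring logic.  Every planted quantity is returned as ground truth so the
full pipeline can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import Field

from .laminar import MOTION_COLUMNS, RIM_CSF, RIM_GM, RIM_WM
from .physiology import _StrictModel

__all__ = ["SynthSpec", "SynthRibbon", "SynthDataset", "make_ribbon",
           "make_interleaved_dataset", "double_peak_curve", "surface_ramp_curve"]


def double_peak_curve(
    depths: np.ndarray,
    superficial_depth: float = 0.2,
    deep_depth: float = 0.7,
    amplitude: float = 2.0,
    width: float = 0.08,
) -> np.ndarray:
    """Two-peaked laminar response (percent): superficial input plus deep
    output, the motor-cortex testbed pattern."""
    d = np.asarray(depths, dtype=float)
    return amplitude * (
        np.exp(-0.5 * ((d - superficial_depth) / width) ** 2)
        + np.exp(-0.5 * ((d - deep_depth) / width) ** 2)
    )


def surface_ramp_curve(
    depths: np.ndarray, surface_amplitude: float = 4.0, floor: float = 0.5
) -> np.ndarray:
    """Draining-vein-like BOLD laminar response (percent): largest at the
    cortical surface (depth 0), decreasing linearly toward WM."""
    d = np.asarray(depths, dtype=float)
    return floor + (surface_amplitude - floor) * (1.0 - d)


class SynthSpec(_StrictModel):
    """Specification of one synthetic interleaved dataset."""

    grid_size: int = Field(default=64, ge=8)
    ribbon: str = Field(default="annulus", pattern="^(slab|annulus)$")
    thickness: int = Field(default=16, ge=3)

    #: block design in volume TRs (rest first); one DANTE/MT pair per 2 TRs
    rest_trs: int = Field(default=6, ge=2)
    active_trs: int = Field(default=8, ge=2)
    n_trials: int = Field(default=8, ge=1)
    volume_tr: float = Field(default=4.27, gt=0.0)

    #: baseline intensities (arbitrary units); DANTE below MT
    dante_baseline: float = Field(default=90.0, gt=0.0)
    mt_baseline: float = Field(default=110.0, gt=0.0)

    #: peak VAPER ratio amplitude (percent) and laminar peak positions
    vaper_amplitude: float = Field(default=2.0, ge=0.0)
    vaper_peak_depths: tuple[float, float] = (0.2, 0.7)
    vaper_peak_width: float = Field(default=0.08, gt=0.0)
    #: fraction of the (log-)ratio modulation carried by the MT condition
    #: (the rest is carried, inverted, by DANTE: task moves DANTE down, MT up;
    #: 1.0 puts the whole modulation in MT, making the VAPER series exact)
    mt_share: float = Field(default=0.25, gt=0.0, le=1.0)

    #: shared BOLD-like modulation (percent at the surface, floor at WM)
    bold_surface_amplitude: float = Field(default=4.0, ge=0.0)
    bold_floor: float = Field(default=0.5, ge=0.0)

    noise_sd: float = Field(default=0.5, ge=0.0)  # percent of baseline
    motion_spike_volumes: tuple[int, ...] = ()
    motion_spike_mm: float = Field(default=0.6, gt=0.0)
    seed: int = 0

    @property
    def trs_per_trial(self) -> int:
        return self.rest_trs + self.active_trs

    @property
    def n_pairs(self) -> int:
        total_trs = self.trs_per_trial * self.n_trials
        if total_trs % 2:
            raise ValueError(
                "rest_trs + active_trs must be even so blocks align with "
                "DANTE/MT pairs"
            )
        return total_trs // 2

    def pair_boxcar(self) -> np.ndarray:
        """Task regressor on the effective-TR (pair) grid: 0 rest, 1 active."""
        if self.rest_trs % 2 or self.active_trs % 2:
            raise ValueError("rest_trs and active_trs must both be even")
        trial = np.concatenate(
            [np.zeros(self.rest_trs // 2), np.ones(self.active_trs // 2)]
        )
        return np.tile(trial, self.n_trials)


@dataclass
class SynthRibbon:
    """Rim labels plus analytically known depth (NaN outside the ribbon)."""

    rim: np.ndarray
    depth: np.ndarray


def make_ribbon(spec: SynthSpec) -> SynthRibbon:
    """Build the slab or annulus ribbon with 1-voxel-thick borders.

    Slab: depth linear along one axis (CSF border at low index).  Annulus:
    CSF border on the outer radius, WM on the inner, depth = outward-area
    fraction (the exact equi-volume depth for an annulus).
    """
    n = spec.grid_size
    t = spec.thickness
    rim = np.zeros((n, n), dtype=np.int16)
    depth = np.full((n, n), np.nan)
    if spec.ribbon == "slab":
        j0 = (n - t) // 2
        rows = np.arange(n)
        for j in range(j0, j0 + t):
            if j == j0:
                rim[:, j] = RIM_CSF
            elif j == j0 + t - 1:
                rim[:, j] = RIM_WM
            else:
                rim[:, j] = RIM_GM
            depth[:, j] = (j - j0) / (t - 1)
        _ = rows
    else:
        c = (n - 1) / 2.0
        r_out = n / 2.0 - 2.0
        r_in = r_out - t + 1
        if r_in < 2:
            raise ValueError("grid too small for the requested thickness")
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - c, xx - c)
        ring = (r >= r_in - 0.5) & (r < r_out + 0.5)
        outer = ring & (r >= r_out - 0.5)
        inner = ring & (r < r_in + 0.5)
        rim[ring] = RIM_GM
        rim[outer] = RIM_CSF
        rim[inner] = RIM_WM
        # equi-volume ground truth: fraction of annulus area outside radius r
        depth[ring] = (r_out ** 2 - r[ring] ** 2) / (r_out ** 2 - r_in ** 2)
        depth[ring] = np.clip(depth[ring], 0.0, 1.0)
    return SynthRibbon(rim=rim, depth=depth)


@dataclass
class SynthDataset:
    """A synthetic interleaved acquisition plus its ground truth."""

    data: np.ndarray          # (x, y, 1, 2*n_pairs)
    labels: list
    motion: pd.DataFrame
    rim: np.ndarray
    truth_depth: np.ndarray
    truth_vaper: np.ndarray   # planted VAPER percent amplitude per voxel
    truth_bold: np.ndarray    # planted BOLD-like percent amplitude per voxel
    pair_boxcar: np.ndarray
    effective_tr: float

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), affine=np.eye(4))


def make_interleaved_dataset(spec: SynthSpec) -> SynthDataset:
    """Generate the interleaved 4D dataset with planted laminar responses.

    The task multiplies the MT volumes by (1 + a g(t)/100)^w and divides the
    DANTE volumes by (1 + a g(t)/100)^(1-w), where a is the planted percent
    amplitude at the voxel's depth, w = ``mt_share`` and g(t) is the
    mean-centred pair boxcar — so the MT/DANTE ratio changes by exactly a
    percent (per unit boxcar) while DANTE moves down and MT up.  The
    BOLD-like modulation multiplies both volumes of a pair equally and
    cancels in the ratio.  Gaussian noise is percent-of-baseline, white.
    """
    ribbon = make_ribbon(spec)
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_pairs
    boxcar = spec.pair_boxcar()
    g = boxcar - boxcar.mean()

    depth = ribbon.depth
    inside = np.isfinite(depth)
    d = np.where(inside, depth, 0.0)

    truth_vaper = np.where(
        inside,
        double_peak_curve(
            d, spec.vaper_peak_depths[0], spec.vaper_peak_depths[1],
            spec.vaper_amplitude, spec.vaper_peak_width,
        ),
        0.0,
    )
    truth_bold = np.where(
        inside,
        surface_ramp_curve(d, spec.bold_surface_amplitude, spec.bold_floor),
        0.0,
    )

    shape = depth.shape
    nx, ny = shape
    data = np.zeros((nx, ny, 1, 2 * n_pairs), dtype=float)
    w = spec.mt_share
    for k in range(n_pairs):
        task = 1.0 + truth_vaper / 100.0 * g[k]
        bold = 1.0 + truth_bold / 100.0 * g[k]
        dante = spec.dante_baseline * bold * np.power(task, -(1.0 - w))
        mt = spec.mt_baseline * bold * np.power(task, w)
        data[:, :, 0, 2 * k] = dante
        data[:, :, 0, 2 * k + 1] = mt
    if spec.noise_sd > 0:
        data[..., 0::2] += rng.normal(
            0.0, spec.noise_sd / 100.0 * spec.dante_baseline,
            size=data[..., 0::2].shape,
        )
        data[..., 1::2] += rng.normal(
            0.0, spec.noise_sd / 100.0 * spec.mt_baseline,
            size=data[..., 1::2].shape,
        )

    n_vols = 2 * n_pairs
    labels = ["DANTE", "MT"] * n_pairs
    motion = pd.DataFrame(
        rng.normal(0.0, 0.01, size=(n_vols, 6)), columns=MOTION_COLUMNS
    )
    motion.insert(0, "volume", np.arange(n_vols))
    motion["condition"] = labels
    for v in spec.motion_spike_volumes:
        if not 0 <= v < n_vols:
            raise ValueError(f"motion spike volume {v} outside run of {n_vols}")
        motion.loc[v, "trans_z"] = (
            motion.loc[v - 1 if v else v, "trans_z"] + spec.motion_spike_mm
        )

    return SynthDataset(
        data=data,
        labels=labels,
        motion=motion,
        rim=ribbon.rim,
        truth_depth=ribbon.depth,
        truth_vaper=truth_vaper,
        truth_bold=truth_bold,
        pair_boxcar=boxcar,
        effective_tr=2.0 * spec.volume_tr,
    )
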