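"""Laminar fMRI analysis: censoring, percent-change GLM, equi-volume
layering, cortical depth profiles, and Gaussian peak fitting.

The pipeline turns an interleaved DANTE/MT 4D series into voxelwise VAPER
percent-signal-change maps and 18-layer cortical depth profiles.  Depth runs
from 0 at the CSF/GM boundary to 1 at the GM/WM boundary; layers are
equi-volume: bin edges are chosen so that, along each local cortical column,
layers enclose equal tissue volume after curvature correction (reducing to
equidistant depth where the boundaries are parallel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .contrast import InterleavedSeries

__all__ = [
    "MOTION_COLUMNS",
    "LayerModel",
    "DepthProfile",
    "censor_mask",
    "pair_keep_mask",
    "percent_change_glm",
    "gamma_hrf",
    "build_design",
    "compute_depth",
    "depth_profile",
    "profile_peak",
    "split_interleaved",
    "RIM_CSF",
    "RIM_WM",
    "RIM_GM",
]

#: rim label conventions: border voxels of the two boundaries and GM interior
RIM_CSF = 1
RIM_WM = 2
RIM_GM = 3

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

#: radius (mm) of the sphere used to convert rotations (deg) to mm
ROTATION_SPHERE_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------


def motion_enorm(motion: pd.DataFrame) -> np.ndarray:
    """Euclidean norm of the backward difference of the 6 rigid-body
    parameters, rotations (deg) converted to mm on a 50 mm sphere.  The
    first volume's derivative is zero by convention."""
    missing = [c for c in MOTION_COLUMNS if c not in motion.columns]
    if missing:
        raise ValueError(f"motion table missing columns {missing}")
    params = motion[MOTION_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters must be finite")
    scale = np.array([1.0] * 3 + [np.pi / 180.0 * ROTATION_SPHERE_RADIUS_MM] * 3)
    d = np.diff(params * scale, axis=0, prepend=params[:1] * scale)
    return np.linalg.norm(d, axis=1)


def censor_mask(
    motion: pd.DataFrame,
    outlier_fraction: np.ndarray | None = None,
    enorm_threshold: float = 0.4,
    outlier_threshold: float = 0.10,
) -> np.ndarray:
    """Boolean keep-mask over volumes: censor when the motion-derivative
    Euclidean norm exceeds 0.4 mm or when at least 10% of voxels are outliers.
    """
    if "volume" in motion.columns:
        vols = motion["volume"].to_numpy()
        if not np.array_equal(vols, np.arange(len(vols))):
            raise ValueError("motion table must contain every volume 0..N-1 in order")
    enorm = motion_enorm(motion)
    keep = enorm <= enorm_threshold
    if outlier_fraction is not None:
        outlier_fraction = np.asarray(outlier_fraction, dtype=float)
        if outlier_fraction.shape != (len(motion),):
            raise ValueError("outlier_fraction must have one value per volume")
        keep &= outlier_fraction < outlier_threshold
    return keep


def pair_keep_mask(volume_keep: np.ndarray) -> np.ndarray:
    """Keep-mask on the VAPER (pair) grid from a per-volume keep-mask.

    VAPER_k divides MT_k by the mean of DANTE_k and DANTE_{k+1}, so censoring
    any of those volumes removes point k.  Volumes alternate DANTE, MT, ...
    """
    volume_keep = np.asarray(volume_keep, dtype=bool)
    if volume_keep.size % 2:
        raise ValueError("expected an even number of volumes (DANTE/MT pairs)")
    d = volume_keep[0::2]
    m = volume_keep[1::2]
    nxt = np.append(d[1:], d[-1])  # edge rule: last point uses DANTE_N only
    return m & d & nxt


# ---------------------------------------------------------------------------
# Percent-signal-change GLM
# ---------------------------------------------------------------------------


def gamma_hrf(t: np.ndarray, shape: float = 6.0, scale: float = 0.9) -> np.ndarray:
    """Canonical gamma-variate haemodynamic response (peak ~(shape-1)*scale s),
    normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    h = np.where(t > 0, np.power(np.maximum(t, 0) / scale, shape - 1)
                 * np.exp(-np.maximum(t, 0) / scale), 0.0)
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design(
    task: np.ndarray,
    tr: float,
    convolve: bool = True,
    drift_seconds: float = 150.0,
) -> np.ndarray:
    """Design matrix: [task regressor, Legendre drift terms (incl. constant)].

    The task boxcar is optionally convolved with the canonical gamma response
    sampled at ``tr``; drift uses Legendre polynomials up to order
    1 + run_duration // drift_seconds.
    """
    task = np.asarray(task, dtype=float)
    n = task.size
    if convolve:
        t = np.arange(0, 32.0, tr)
        h = gamma_hrf(t)
        reg = np.convolve(task, h)[:n]
        m = reg.max()
        if m > 0:
            reg = reg / m
    else:
        reg = task
    order = 1 + int((n * tr) // drift_seconds)
    x = np.linspace(-1.0, 1.0, n)
    drift = np.polynomial.legendre.legvander(x, order)
    return np.column_stack([reg, drift])


def percent_change_glm(
    series: np.ndarray,
    design: np.ndarray,
    keep: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Task beta (percent signal change) and t-statistic per voxel.

    ``series`` is (n_timepoints,) or (n_timepoints, n_voxels); each voxel is
    normalized by its own temporal mean (over kept volumes) and scaled by
    100 before the ordinary-least-squares fit, so the task beta reads
    directly in percent.  Censored time points are excluded from the fit.
    ``design`` is a full design matrix whose first column is the task
    regressor (see :func:`build_design`).
    """
    series = np.asarray(series, dtype=float)
    squeeze = series.ndim == 1
    if squeeze:
        series = series[:, None]
    n = series.shape[0]
    design = np.asarray(design, dtype=float)
    if design.shape[0] != n:
        raise ValueError("design and series lengths differ")
    if keep is None:
        keep = np.ones(n, dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    y = series[keep]
    X = design[keep]
    if y.shape[0] == 0:
        raise ValueError("all volumes censored")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design after censoring (rank {rank} < {X.shape[1]})"
        )
    dof = y.shape[0] - X.shape[1]
    if dof < 1:
        raise ValueError("not enough uncensored volumes for the design")

    mean = y.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("voxel with zero temporal mean")
    y = 100.0 * y / mean

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    task_beta = beta[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, task_beta / se, 0.0)
    if squeeze:
        return float(task_beta[0]), float(tstat[0])
    return task_beta, tstat


# ---------------------------------------------------------------------------
# Equi-volume layering
# ---------------------------------------------------------------------------


@dataclass
class LayerModel:
    """Per-voxel normalized cortical depth and layer assignment.

    ``depth`` is defined on GM voxels (0 = CSF/GM boundary, 1 = GM/WM
    boundary; rim voxels are pinned to 0/1); ``layer_index`` is 1..n_layers
    on GM-interior voxels and 0 elsewhere.
    """

    depth: np.ndarray
    layer_index: np.ndarray
    n_layers: int

    @property
    def layer_centers(self) -> np.ndarray:
        return (np.arange(self.n_layers) + 0.5) / self.n_layers


def compute_depth(
    rim: np.ndarray,
    n_layers: int = 18,
    equivolume: bool = True,
    spacing: tuple | None = None,
    curvature_sigma: float | None = None,
) -> LayerModel:
    """Equi-volume cortical depth from a rim label volume.

    ``rim`` labels the CSF border (1), WM border (2) and GM interior (3).
    Equidistant depth is d_csf / (d_csf + d_wm) from Euclidean distance
    transforms; the equi-volume reparameterization rescales it per voxel
    using the local boundary-area ratio estimated from the curvature of the
    depth level sets, so that equal depth increments enclose equal volume
    along curved cortex.  With parallel planar boundaries it reduces to
    equidistant depth exactly.
    """
    rim_in = np.asarray(rim)
    # singleton axes (e.g. a single-slice NIfTI) carry no geometry
    full_shape = rim_in.shape
    keep_axes = tuple(i for i, s in enumerate(full_shape) if s > 1)
    rim = rim_in.squeeze()
    if spacing is not None and len(spacing) == rim_in.ndim:
        spacing = tuple(spacing[i] for i in keep_axes)
    if not np.any(rim == RIM_CSF) or not np.any(rim == RIM_WM):
        raise ValueError("rim volume must contain both CSF (1) and WM (2) borders")
    gm = rim == RIM_GM
    if spacing is None:
        spacing = (1.0,) * rim.ndim

    d_csf = ndimage.distance_transform_edt(rim != RIM_CSF, sampling=spacing)
    d_wm = ndimage.distance_transform_edt(rim != RIM_WM, sampling=spacing)
    thickness = d_csf + d_wm
    bad = gm & ~(thickness > 0)
    if np.any(bad):
        raise ValueError(
            f"GM voxels with no path to both boundaries: {np.argwhere(bad)[:10]}"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(thickness > 0, d_csf / thickness, 0.0)

    if equivolume:
        # normal field of the depth level sets, from the smoothed equidistant
        # ratio; kappa = -div(n) > 0 where the column cross-section shrinks
        # toward WM.  The smoothing scale follows the ribbon thickness (it
        # suppresses distance-transform faceting, whose curvature artifacts
        # otherwise dominate the area-ratio estimate).
        if curvature_sigma is None:
            mean_thick = float(thickness[gm].mean()) if np.any(gm) else 1.0
            curvature_sigma = max(2.0, mean_thick / 12.0)
        u = ndimage.gaussian_filter(x, curvature_sigma)
        grads = np.gradient(u, *spacing)
        norm = np.sqrt(sum(g ** 2 for g in grads))
        norm = np.where(norm > 0, norm, 1.0)
        nfield = [g / norm for g in grads]
        div = sum(
            np.gradient(nf, spacing[i], axis=i) for i, nf in enumerate(nfield)
        )
        kappa = -div
        a_csf = np.clip(1.0 + kappa * d_csf, 0.05, 20.0)
        a_wm = np.clip(1.0 - kappa * d_wm, 0.05, 20.0)
        depth = (2.0 * a_csf * x - (a_csf - a_wm) * x ** 2) / (a_csf + a_wm)
    else:
        depth = x

    depth = np.clip(depth, 0.0, 1.0)
    depth[rim == RIM_CSF] = 0.0
    depth[rim == RIM_WM] = 1.0

    layer_index = np.zeros(rim.shape, dtype=int)
    layer_index[gm] = np.clip(
        np.ceil(depth[gm] * n_layers).astype(int), 1, n_layers
    )
    depth_out = np.full(rim.shape, np.nan)
    mask = gm | (rim == RIM_CSF) | (rim == RIM_WM)
    depth_out[mask] = depth[mask]
    return LayerModel(depth=depth_out.reshape(full_shape),
                      layer_index=layer_index.reshape(full_shape),
                      n_layers=n_layers)


# ---------------------------------------------------------------------------
# Depth profiles and peak fitting
# ---------------------------------------------------------------------------


@dataclass
class DepthProfile:
    """Per-layer mean signal change with dispersion across voxels."""

    mean: np.ndarray
    sem: np.ndarray
    centers: np.ndarray
    n_voxels: np.ndarray

    @property
    def empty_layers(self) -> np.ndarray:
        return self.n_voxels == 0


def depth_profile(
    stat_map: np.ndarray, layers: LayerModel, roi: np.ndarray | None = None
) -> DepthProfile:
    """Mean statistic per layer over all ROI voxels, without thresholding."""
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.shape != layers.layer_index.shape:
        raise ValueError("stat map and layer volume shapes differ")
    if roi is None:
        roi = np.ones(stat_map.shape, dtype=bool)
    elif roi.shape != stat_map.shape:
        raise ValueError("ROI and stat map shapes differ")
    n = layers.n_layers
    mean = np.full(n, np.nan)
    sem = np.full(n, np.nan)
    count = np.zeros(n, dtype=int)
    for k in range(1, n + 1):
        sel = roi & (layers.layer_index == k)
        vals = stat_map[sel]
        vals = vals[np.isfinite(vals)]
        count[k - 1] = vals.size
        if vals.size:
            mean[k - 1] = vals.mean()
            sem[k - 1] = (vals.std(ddof=1) / np.sqrt(vals.size)
                          if vals.size > 1 else 0.0)
    return DepthProfile(mean=mean, sem=sem, centers=layers.layer_centers,
                        n_voxels=count)


class PeakFitError(RuntimeError):
    """Gaussian peak fit failed (non-convergence or degenerate profile)."""


def profile_peak(profile: DepthProfile, min_layers: int = 5) -> float:
    """Depth of the profile peak from a Gaussian + constant-offset fit.

    Returns the fitted Gaussian mean clamped to [0, 1]; monotone profiles
    peaking at a boundary therefore report ~0 or ~1.  A flat profile (no
    resolvable amplitude) raises :class:`PeakFitError`.
    """
    ok = np.isfinite(profile.mean)
    if ok.sum() < min_layers:
        raise PeakFitError(f"need >= {min_layers} non-empty layers, got {ok.sum()}")
    xd = profile.centers[ok]
    yd = profile.mean[ok]
    spread = yd.max() - yd.min()
    if spread <= 1e-12 * max(1.0, abs(yd).max()):
        raise PeakFitError("flat profile: zero-amplitude peak")

    def model(x, amp, mu, sigma, off):
        return off + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    p0 = [spread, float(xd[np.argmax(yd)]), 0.15, float(yd.min())]
    try:
        popt, _ = curve_fit(
            model, xd, yd, p0=p0,
            bounds=([0.0, -0.5, 0.02, -np.inf], [np.inf, 1.5, 2.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = yd - model(xd, *p0)
        raise PeakFitError(
            f"Gaussian fit did not converge (initial residual rms "
            f"{np.sqrt(np.mean(resid ** 2)):.4g})"
        ) from exc
    if popt[0] <= 1e-12:
        raise PeakFitError("zero-amplitude fit")
    return float(np.clip(popt[1], 0.0, 1.0))


# ---------------------------------------------------------------------------
# Interleaved series handling
# ---------------------------------------------------------------------------


def split_interleaved(data, labels, effective_tr: float = 8.54) -> InterleavedSeries:
    """Split a 4D series (or a nibabel image) into aligned DANTE/MT series.

    ``labels`` is one condition label per volume, alternating and starting
    with DANTE.  Time is moved to the first axis of each output series.
    """
    if hasattr(data, "get_fdata"):
        data = data.get_fdata()
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    labels = [str(l).upper() for l in labels]
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} volumes")
    if n % 2:
        raise ValueError("expected an even number of volumes")
    expected = ["DANTE", "MT"] * (n // 2)
    if labels != expected:
        bad = next(i for i, (a, b) in enumerate(zip(labels, expected)) if a != b)
        raise ValueError(
            f"labels must alternate DANTE, MT, ... starting with DANTE "
            f"(first mismatch at volume {bad}: {labels[bad]!r})"
        )
    series = np.moveaxis(data, -1, 0)
    return InterleavedSeries(
        dante=series[0::2], mt=series[1::2], effective_tr=effective_tr
    )
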