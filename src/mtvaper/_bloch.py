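"""Internal affine propagators for the longitudinal five-pool system.

Between instantaneous pulse events the state y = (Ma, Mc, Mv, Mt, Mmp)
obeys a linear ODE dy/dt = A y + b (T1 recovery, arteriolar->capillary->
venular turnover, capillary-tissue permeability, tissue-macromolecule
exchange, optional fresh-blood refresh of the arteriole).  Each interval is
integrated exactly with a matrix exponential of the homogeneous 6x6 system;
instantaneous events (prep pulses, excitations) are diagonal maps.  Affine
maps compose, so a segment of n identical pulses is a single cached 6x6
matrix power.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from .physiology import COMPARTMENTS, PulseTrainParams, VascularModel

ART, CAP, VEN, TIS, MP = range(5)


def free_generator(model: VascularModel, *, arteriole_refresh: bool = False):
    """(A, b) of the inter-pulse longitudinal ODE dy/dt = A y + b."""
    A = np.zeros((5, 5))
    b = np.zeros(5)
    tp = model.two_pool
    fl = model.flow

    for i, name in enumerate(COMPARTMENTS):
        r1 = 1.0 / model.compartment(name).T1
        A[i, i] -= r1
        b[i] += r1
    A[MP, MP] -= tp.mp_R1
    b[MP] += tp.mp_R1

    # tissue <-> macromolecular pool exchange (detailed balance)
    k = tp.exchange_rate_k
    kf = k * tp.pool_ratio  # water-side rate
    A[TIS, TIS] -= kf
    A[TIS, MP] += kf
    A[MP, MP] -= k
    A[MP, TIS] += k

    # arteriole -> capillary -> venule turnover (incoming blood carries the
    # upstream compartment's current magnetization)
    A[CAP, CAP] -= fl.capillary_turnover
    A[CAP, ART] += fl.capillary_turnover
    A[VEN, VEN] -= fl.venule_turnover
    A[VEN, CAP] += fl.venule_turnover

    # capillary <-> tissue water permeability (volume-weighted back-reaction)
    pw = tp.permeability_rate
    if pw > 0:
        A[CAP, CAP] -= pw
        A[CAP, TIS] += pw
        f_cap = model.compartment("capillary").volume_fraction
        f_tis = model.compartment("tissue").volume_fraction
        if f_tis > 0:
            back = pw * f_cap / f_tis
            A[TIS, TIS] -= back
            A[TIS, CAP] += back

    if arteriole_refresh:
        # fresh (fully relaxed) blood replaces arteriolar blood
        A[ART, ART] -= fl.arteriole_refresh_rate
        b[ART] += fl.arteriole_refresh_rate

    return A, b


def _homogeneous(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    H = np.zeros((6, 6))
    H[:5, :5] = A
    H[:5, 5] = b
    return H


def free_step(model: VascularModel, dt: float, *, arteriole_refresh: bool = False):
    """Exact 6x6 affine map of free evolution over ``dt`` seconds."""
    if dt == 0:
        return np.eye(6)
    A, b = free_generator(model, arteriole_refresh=arteriole_refresh)
    return expm(_homogeneous(A, b) * dt)


def diag_event(factors) -> np.ndarray:
    """6x6 map multiplying each pool by a factor (last slot is the constant 1)."""
    return np.diag(list(factors) + [1.0])


def dante_pulse_event(model: VascularModel, train: PulseTrainParams,
                      tissue_sat: float = 1.0) -> np.ndarray:
    """One DANTE pulse: flowing pools lose cos(alpha) (spoiled transverse);
    static capillary and tissue are preserved (optional tissue_sat factor);
    the macromolecular pool is untouched."""
    ca = math.cos(train.flip_rad)
    factors = []
    for name in COMPARTMENTS:
        c = model.compartment(name)
        if c.is_flowing and train.gradient_amplitude > 0:
            factors.append(ca)
        elif name == "tissue":
            factors.append(tissue_sat)
        else:
            factors.append(1.0)
    factors.append(1.0)  # MP pool
    return diag_event(factors)


def mt_pulse_event(model: VascularModel, train: PulseTrainParams) -> np.ndarray:
    """One binomial MT pulse: macromolecular pool multiplied by the per-pulse
    saturation factor; venule suffers a small short-T2 direct loss; free water
    of the other pools receives zero net rotation (ramped alternating train)."""
    tp = model.two_pool
    venule_loss = math.exp(
        -tp.venule_sat_scale * train.pulse_duration / model.compartment("venule").T2
    )
    factors = [1.0, 1.0, venule_loss, 1.0, tp.mp_sat_per_pulse]
    return diag_event(factors)


def excitation_event(flip_deg: float) -> np.ndarray:
    """Water excitation: all four water pools lose cos(flip); MP untouched."""
    c = math.cos(math.radians(flip_deg))
    return diag_event([c, c, c, c, 1.0])


def compose_train(pulse: np.ndarray, free: np.ndarray, n: int) -> np.ndarray:
    """Affine map of n repetitions of (pulse, then inter-pulse interval)."""
    return np.linalg.matrix_power(free @ pulse, n)


def apply(step: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Apply a 6x6 affine map to a 5-vector state."""
    return (step @ np.append(y, 1.0))[:5]
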