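"""Four-compartment vascular model, pulse-train constants, and voxel state.

A gray-matter parenchyma voxel is modeled as four water compartments —
arteriole, capillary, venule, and extravascular tissue — plus a macromolecular
proton pool coupled to tissue water by two-pool exchange.  Volume fractions
sum to one; magnetization is normalized per compartment (equilibrium M0 = 1
for each pool), so volume weighting enters only at readout.

All parameters are plain pydantic models, serializable to/from JSON (and
readable from TOML), so every default can be pinned or overridden in tests
and configs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

COMPARTMENTS = ("arteriole", "capillary", "venule", "tissue")

#: index of each water compartment in the internal state vector
COMPARTMENT_INDEX = {name: i for i, name in enumerate(COMPARTMENTS)}

#: total blood volume fraction equivalent to 5.5 mL / 100 g
DEFAULT_BLOOD_FRACTION = 0.055


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CompartmentParams(_StrictModel):
    """Physiological and relaxation parameters of one voxel compartment.

    Relaxation times are in seconds (7 T defaults), ``mean_velocity`` in mm/s.
    ``is_flowing`` marks compartments whose blood moves faster than the DANTE
    velocity cutoff (2 mm/s) and is therefore crushed per pulse.
    """

    name: Literal["arteriole", "capillary", "venule", "tissue"]
    volume_fraction: float = Field(ge=0.0, le=1.0)
    T1: float = Field(gt=0.0)
    T2: float = Field(gt=0.0)
    T2star: float = Field(gt=0.0)
    mean_velocity: float = Field(ge=0.0)
    is_flowing: bool

    @model_validator(mode="after")
    def _relaxation_ordering(self) -> "CompartmentParams":
        if not (self.T2star <= self.T2 <= self.T1):
            raise ValueError(
                f"compartment {self.name!r}: require T2star <= T2 <= T1, "
                f"got T2star={self.T2star}, T2={self.T2}, T1={self.T1}"
            )
        return self


class TwoPoolParams(_StrictModel):
    """Macromolecular-pool and water-exchange parameters.

    ``exchange_rate_k`` is the macromolecular->water magnetization transfer
    rate (1/s); the reverse rate is scaled by the pool-size ratio
    ``mp_fraction / (1 - mp_fraction)`` (detailed balance).
    ``mp_sat_per_pulse`` is the per-pulse macromolecular saturation factor of
    one binomial MT pulse; it is the free calibration parameter of the MT
    preparation (see docs/methods.md).  ``permeability_rate`` limits
    capillary<->tissue water exchange.
    """

    mp_fraction: float = Field(default=0.20, gt=0.0, lt=0.3)
    exchange_rate_k: float = Field(default=1.45, ge=0.0)
    mp_R1: float = Field(default=1.0, ge=0.4, le=2.0)
    mp_sat_per_pulse: float = Field(default=0.99, gt=0.0, le=1.0)
    permeability_rate: float = Field(default=1.0, ge=0.0)
    #: extra per-pulse venule loss scale (direct saturation through short T2);
    #: per-pulse factor is exp(-scale * pulse_duration / T2_venule)
    venule_sat_scale: float = Field(default=0.05, ge=0.0)

    @property
    def pool_ratio(self) -> float:
        """Macromolecular / water pool-size ratio."""
        return self.mp_fraction / (1.0 - self.mp_fraction)


class PulseTrainParams(_StrictModel):
    """Parameters of one preparation pulse train (DANTE or binomial MT)."""

    kind: Literal["DANTE", "MT"]
    flip_deg: float = Field(gt=0.0, lt=90.0)
    pulse_interval: float = Field(gt=0.0)
    pulse_duration: float = Field(default=90e-6, gt=0.0)
    n_pulses_first_segment: int = Field(ge=0)
    n_pulses_later_segment: int = Field(ge=0)
    gradient_amplitude: float = Field(ge=0.0)  # mT/m
    ramp_length: int = Field(default=0, ge=0)
    #: B1 scaling multiplier on the nominal flip angle (1 = nominal)
    b1_scale: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _interval_covers_pulse(self) -> "PulseTrainParams":
        if self.pulse_interval <= self.pulse_duration:
            raise ValueError(
                f"pulse_interval ({self.pulse_interval}) must exceed "
                f"pulse_duration ({self.pulse_duration})"
            )
        return self

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg * self.b1_scale)


class FlowParams(_StrictModel):
    """First-order turnover rates of the microvascular tree (1/s).

    Rates are derived from mean velocity over segment length and scale
    linearly with CBF; ``apply_functional_change`` multiplies all three by
    (1 + d_cbf) and records the matching arterial-transit-time rescale in
    ``att_scale``.
    """

    arteriole_refresh_rate: float = Field(default=2.0, ge=0.0)
    capillary_turnover: float = Field(default=0.8, ge=0.0)
    venule_turnover: float = Field(default=0.6, ge=0.0)
    #: multiplier applied to the protocol's arterial transit time
    att_scale: float = Field(default=1.0, gt=0.0)


class VascularModel(_StrictModel):
    """Complete voxel model: four compartments + two-pool MT + flow rates."""

    compartments: list[CompartmentParams]
    two_pool: TwoPoolParams = Field(default_factory=TwoPoolParams)
    flow: FlowParams = Field(default_factory=FlowParams)

    @model_validator(mode="after")
    def _check_compartments(self) -> "VascularModel":
        names = [c.name for c in self.compartments]
        if sorted(names) != sorted(COMPARTMENTS):
            raise ValueError(
                f"model requires exactly the compartments {COMPARTMENTS}, got {names}"
            )
        total = sum(c.volume_fraction for c in self.compartments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volume fractions must sum to 1 (got {total!r})")
        return self

    def compartment(self, name: str) -> CompartmentParams:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def blood_fraction(self) -> float:
        return sum(
            c.volume_fraction for c in self.compartments if c.name != "tissue"
        )


@dataclass
class VoxelState:
    """Longitudinal magnetization of the four water pools + macromolecular pool.

    Each entry of ``mz`` is normalized to that compartment's own equilibrium
    (M0 = 1); ``mz_mp`` is the macromolecular pool; ``t`` is elapsed time (s).
    """

    mz: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in COMPARTMENTS}
    )
    mz_mp: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        # tolerate (and clamp) sub-1e-9 overshoot from exact matrix exponentials
        eps = 1e-9
        for name, v in self.mz.items():
            if not -1.0 - eps <= v <= 1.0 + eps:
                raise ValueError(f"mz[{name!r}] = {v} outside [-1, 1]")
            self.mz[name] = min(1.0, max(-1.0, v))
        if not -eps <= self.mz_mp <= 1.0 + eps:
            raise ValueError(f"mz_mp = {self.mz_mp} outside [0, 1]")
        self.mz_mp = min(1.0, max(0.0, self.mz_mp))

    def as_vector(self):
        import numpy as np

        return np.array(
            [self.mz[name] for name in COMPARTMENTS] + [self.mz_mp], dtype=float
        )

    @classmethod
    def from_vector(cls, vec, t: float = 0.0) -> "VoxelState":
        mz = {name: float(vec[i]) for i, name in enumerate(COMPARTMENTS)}
        return cls(mz=mz, mz_mp=float(vec[4]), t=t)


def default_model(
    blood_fraction: float = DEFAULT_BLOOD_FRACTION,
    **overrides,
) -> VascularModel:
    """Build the default four-compartment 7 T gray-matter model.

    Blood (default 5.5 mL/100 g -> fraction 0.055) is split 20/40/40 over
    arteriole/capillary/venule; the remainder is extravascular tissue.
    ``overrides`` may contain ``two_pool`` and/or ``flow`` dicts merged over
    the defaults.  Setting ``blood_fraction=0`` yields a pure-tissue voxel.
    """
    fa, fc, fv = 0.2 * blood_fraction, 0.4 * blood_fraction, 0.4 * blood_fraction
    compartments = [
        CompartmentParams(
            name="arteriole", volume_fraction=fa, T1=2.1, T2=0.040,
            T2star=0.022, mean_velocity=5.0, is_flowing=True,
        ),
        CompartmentParams(
            name="capillary", volume_fraction=fc, T1=2.1, T2=0.030,
            T2star=0.018, mean_velocity=0.8, is_flowing=False,
        ),
        CompartmentParams(
            name="venule", volume_fraction=fv, T1=2.1, T2=0.012,
            T2star=0.007, mean_velocity=4.0, is_flowing=True,
        ),
        CompartmentParams(
            name="tissue", volume_fraction=1.0 - blood_fraction, T1=1.8,
            T2=0.050, T2star=0.028, mean_velocity=0.0, is_flowing=False,
        ),
    ]
    two_pool = TwoPoolParams(**overrides.pop("two_pool", {}))
    flow = FlowParams(**overrides.pop("flow", {}))
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    return VascularModel(compartments=compartments, two_pool=two_pool, flow=flow)


def default_dante_train(**overrides) -> PulseTrainParams:
    """DANTE blood-nulling train: 9 deg, 1 ms interval, 26 mT/m, 100/20 pulses."""
    params = dict(
        kind="DANTE", flip_deg=9.0, pulse_interval=1e-3, pulse_duration=90e-6,
        n_pulses_first_segment=100, n_pulses_later_segment=20,
        gradient_amplitude=26.0, ramp_length=0,
    )
    params.update(overrides)
    return PulseTrainParams(**params)


def default_mt_train(**overrides) -> PulseTrainParams:
    """Binomial MT train: 11 deg alternating, 0.2 ms interval, 36 pulses/segment."""
    params = dict(
        kind="MT", flip_deg=11.0, pulse_interval=2e-4, pulse_duration=90e-6,
        n_pulses_first_segment=36, n_pulses_later_segment=36,
        gradient_amplitude=0.0, ramp_length=8,
    )
    params.update(overrides)
    return PulseTrainParams(**params)


def equilibrium_state(model: VascularModel) -> VoxelState:
    """Fully relaxed state: every pool at its own equilibrium, t = 0."""
    return VoxelState()


# ---------------------------------------------------------------------------
# Config serialization (JSON write; JSON or TOML read; unknown keys rejected)
# ---------------------------------------------------------------------------


class SimulationConfig(_StrictModel):
    """On-disk configuration: nested sections, all optional with defaults."""

    compartments: list[CompartmentParams] | None = None
    two_pool: TwoPoolParams = Field(default_factory=TwoPoolParams)
    flow: FlowParams = Field(default_factory=FlowParams)
    dante: PulseTrainParams = Field(default_factory=default_dante_train)
    mt: PulseTrainParams = Field(default_factory=default_mt_train)
    epi: dict = Field(default_factory=dict)
    timing: dict = Field(default_factory=dict)

    def to_model(self) -> VascularModel:
        if self.compartments is None:
            base = default_model()
            return VascularModel(
                compartments=base.compartments,
                two_pool=self.two_pool,
                flow=self.flow,
            )
        return VascularModel(
            compartments=self.compartments, two_pool=self.two_pool, flow=self.flow
        )

    def to_protocol(self):
        from .sequence_sim import AcquisitionProtocol

        return AcquisitionProtocol(
            dante=self.dante, mt=self.mt, **self.epi, **self.timing
        )


def load_config(path: str | Path) -> SimulationConfig:
    """Read a JSON or TOML config file into a validated SimulationConfig."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return SimulationConfig(**data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as JSON (floats round-trip bit-exactly via repr)."""
    Path(path).write_text(config.model_dump_json(indent=2))
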