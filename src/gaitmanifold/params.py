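"""Parameter containers for the biped model, contact law and controllers.

All containers are plain dataclasses with physical units documented per
field, loadable from YAML/JSON mappings.  ``to_array`` methods pack values
into flat ``float64`` arrays consumed by the compiled kernels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "BodyParameters",
    "ContactParams",
    "GainSet",
    "IntermittentGains",
    "Schedule",
    "SimConfig",
]


def _from_mapping(cls, data):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


class _ConfigIO:
    @classmethod
    def from_dict(cls, data: dict):
        return _from_mapping(cls, data)

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BodyParameters(_ConfigIO):
    """Segment masses, lengths, centre-of-mass offsets and inertias.

    Index 0 is the HAT (head-arms-trunk) link, 1 the foot, 2 the shank and
    3 the thigh; both legs share the same segment parameters.  Defaults are
    the anthropometric set of the reference biped model.

    Units: masses kg, lengths m, inertias kg m^2 (about segment CoM),
    g m s^-2.  ``l0`` is the distance from the hip joint to the HAT CoM,
    ``l1``..``l3`` the distances from the proximal joint to the segment CoM.
    """

    m0: float = 40.548
    m1: float = 0.682
    m2: float = 3.162
    m3: float = 6.882
    L0: float = 0.536
    L1: float = 0.122
    L2: float = 0.379
    L3: float = 0.420
    l0: float = 0.332
    l1: float = 0.050
    l2: float = 0.154
    l3: float = 0.200
    I0: float = 1.09933
    I1: float = 0.00014
    I2: float = 0.03001
    I3: float = 0.09485
    g: float = 9.8

    def __post_init__(self):
        for i in range(4):
            m = getattr(self, f"m{i}")
            L = getattr(self, f"L{i}")
            li = getattr(self, f"l{i}")
            I = getattr(self, f"I{i}")
            if not (m > 0 and L > 0 and I > 0):
                raise ValueError("masses, lengths and inertias must be positive")
            if li > L:
                raise ValueError(f"l{i} must not exceed L{i}")

    @property
    def total_mass(self) -> float:
        return self.m0 + 2.0 * (self.m1 + self.m2 + self.m3)

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.g,
                self.m0, self.m1, self.m2, self.m3,
                self.L1, self.L2, self.L3,
                self.l0, self.l1, self.l2, self.l3,
                self.I0, self.I1, self.I2, self.I3,
            ],
            dtype=np.float64,
        )


@dataclass
class ContactParams(_ConfigIO):
    """Nonlinear spring-damper ground contact, two points per foot.

    Vertical force on a penetrating point is the Hunt-Crossley form
    ``k_v * d**e * (1 + c_v * d_dot)`` clamped at zero (unilateral).
    The horizontal force is a viscous drag ``-c_h * ramp(d) * vx`` with a
    C1 smoothstep engagement ``ramp(d)`` saturating at ``ramp_depth``;
    with ``horizontal_stiffness > 0``
    an anchor spring (anchor set at touchdown, released at liftoff) is added
    in nonlinear simulation only -- the Floquet machinery requires the
    default anchor-free law so that the vector field is a pure function of
    the state.

    ``heel_offset`` and ``sole_drop`` place the heel/toe contact points in
    the foot frame: heel at (-heel_offset, -sole_drop), toe at
    (L1, -sole_drop) from the ankle.
    """

    vertical_stiffness: float = 2.0e6   # N m^-e
    exponent: float = 2.0               # dimensionless
    vertical_damping: float = 0.5       # s m^-1 (Hunt-Crossley dissipation)
    horizontal_damping: float = 1.5e3   # N s m^-1 per contact point
    ramp_depth: float = 0.005           # m, horizontal-force engagement depth
    heel_offset: float = 0.06           # m behind the ankle
    sole_drop: float = 0.04             # m below the ankle
    horizontal_stiffness: float = 0.0   # N m^-1; >0 enables anchor springs
    slip_force: float = 0.0             # N; 0 disables the slip threshold

    def __post_init__(self):
        if min(self.vertical_stiffness, self.vertical_damping,
               self.horizontal_damping, self.horizontal_stiffness) < 0:
            raise ValueError("stiffness and damping must be nonnegative")
        if self.ramp_depth <= 0 or self.sole_drop < 0 or self.heel_offset < 0:
            raise ValueError("invalid contact geometry")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.vertical_stiffness, self.exponent, self.vertical_damping,
                self.horizontal_damping, self.ramp_depth,
                self.heel_offset, self.sole_drop,
                self.horizontal_stiffness, self.slip_force,
            ],
            dtype=np.float64,
        )


def _diag9(ankle: float, knee: float, hip: float) -> np.ndarray:
    """Diagonal of a 9x9 gain matrix: zero HAT block, per-joint values."""
    return np.array([0.0, 0.0, 0.0, ankle, knee, hip, ankle, knee, hip])


@dataclass
class GainSet(_ConfigIO):
    """PD feedback gains = joint impedance (stiffness P, viscosity D).

    Units: P N m rad^-1, D N m s rad^-1.  The first three generalized
    coordinates (HAT tilt and CoM position) are unactuated, so the expanded
    diagonal matrices carry zeros there.
    """

    Pa: float = 2000.0
    Pk: float = 2000.0
    Ph: float = 2000.0
    Da: float = 50.0
    Dk: float = 50.0
    Dh: float = 50.0

    def __post_init__(self):
        if min(self.Pa, self.Pk, self.Ph, self.Da, self.Dk, self.Dh) < 0:
            raise ValueError("gains must be nonnegative")

    def p_diag(self) -> np.ndarray:
        return _diag9(self.Pa, self.Pk, self.Ph)

    def d_diag(self) -> np.ndarray:
        return _diag9(self.Da, self.Dk, self.Dh)

    def replace(self, **kw) -> "GainSet":
        d = self.to_dict()
        d.update(kw)
        return GainSet(**d)


@dataclass
class IntermittentGains(_ConfigIO):
    """Gains of the intermittent (on-period) PD controller, same structure
    as :class:`GainSet`.

    Defaults are deliberately viscosity-dominant: the fixture's unstable
    pair lives mostly in joint/trunk velocities, and the stable-manifold
    target is extracted through an oblique projection whose gain is
    already large, so a small P+ with substantial D+ stabilizes where a
    stiff on-period torque overdrives the loop.
    """

    Pa: float = 30.0
    Pk: float = 30.0
    Ph: float = 30.0
    Da: float = 100.0
    Dk: float = 100.0
    Dh: float = 100.0

    def __post_init__(self):
        if min(self.Pa, self.Pk, self.Ph, self.Da, self.Dk, self.Dh) < 0:
            raise ValueError("gains must be nonnegative")

    def p_diag(self) -> np.ndarray:
        return _diag9(self.Pa, self.Pk, self.Ph)

    def d_diag(self) -> np.ndarray:
        return _diag9(self.Da, self.Dk, self.Dh)


@dataclass
class Schedule(_ConfigIO):
    """Phase-triggered on/off schedule of the intermittent torque.

    The controller switches on when the desired-trajectory phase reaches
    ``phi_on`` (and again at ``phi_on + 0.5``, once per step) and off after
    ``w`` seconds.  ``mode`` selects the target: ``"smc"`` drives to the
    projection of the state on the stable manifold, ``"lcc"`` directly to
    the limit cycle, ``"off"`` disables the controller.
    """

    phi_on: float = 0.0
    w: float = 0.1          # s
    mode: str = "off"       # off | smc | lcc

    def __post_init__(self):
        if not 0.0 <= self.phi_on < 0.5:
            raise ValueError("phi_on must lie in [0, 0.5)")
        if self.mode not in ("off", "smc", "lcc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.w < 0:
            raise ValueError("w must be nonnegative")

    def validate_period(self, T: float):
        if self.w >= T / 2:
            raise ValueError("on-period duration must be below T/2")


@dataclass
class SimConfig(_ConfigIO):
    """Settings of one forward simulation of the controlled walker."""

    dt: float = 1e-5                 # s
    n_cycles: int = 10
    gains: GainSet = field(default_factory=GainSet)
    igains: IntermittentGains = field(default_factory=IntermittentGains)
    schedule: Schedule = field(default_factory=Schedule)
    perturbation: dict = field(default_factory=dict)  # state index -> magnitude
    phi0: float = 0.0
    seed: int = 0
    output_stride: int = 100

    def __post_init__(self):
        if self.dt <= 0 or self.n_cycles < 1:
            raise ValueError("dt must be positive and n_cycles >= 1")
        if isinstance(self.gains, dict):
            self.gains = GainSet(**self.gains)
        if isinstance(self.igains, dict):
            self.igains = IntermittentGains(**self.igains)
        if isinstance(self.schedule, dict):
            self.schedule = Schedule(**self.schedule)
        for i, v in self.perturbation.items():
            if not (0 <= int(i) < 18) or not np.isfinite(v):
                raise ValueError("perturbation entries must be finite, index in 0..17")

    def perturbation_vector(self) -> np.ndarray:
        dx = np.zeros(18)
        for i, v in self.perturbation.items():
            dx[int(i)] = v
        return dx
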