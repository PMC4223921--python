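"""Controllers: feed-forward playback, continuous PD feedback, and the
phase-gated intermittent torque (SMC / LCC).

The continuous controller tracks the desired trajectory with joint
stiffness P and viscosity D (the joint impedance).  The intermittent
controller adds, during two short windows per gait cycle (once per step,
exploiting the left-right symmetry), a second PD torque towards either

* SMC -- the projection of the current state onto the local stable
  manifold of the (possibly unstable) limit cycle, computed in the basis
  of the window's onset phase and re-projected every integration step, or
* LCC -- the reference state on the limit cycle itself.

All torques vanish on the three unactuated HAT coordinates.
"""

from __future__ import annotations

import numpy as np

from .manifold import PhaseBasis, projection_matrix, reference_error
from .params import GainSet, IntermittentGains, Schedule
from .trajectory import ReferenceGait

__all__ = [
    "pd_feedback",
    "is_on",
    "window_phases",
    "schedule_array",
    "intermittent_torque",
]


def pd_feedback(x, phase: float, gains: GainSet,
                ref: ReferenceGait) -> np.ndarray:
    """Continuous tracking torque ``-P (q - q_r) - D (qd - qd_r)``."""
    x = np.asarray(x, dtype=float)
    xr = ref.state_at_phase(phase)
    Pd = gains.p_diag()
    Dd = gains.d_diag()
    return -Pd * (x[:9] - xr[:9]) - Dd * (x[9:] - xr[9:])


def is_on(phase: float, schedule: Schedule, T: float) -> bool:
    """Purely clock-driven on/off state of the intermittent controller.

    On iff ``(phase - phi_on) mod 0.5`` lies in ``[0, w/T)``: the window
    opens at ``phi_on`` and again half a cycle later.
    """
    if schedule.mode == "off" or schedule.w == 0.0:
        return False
    return (phase - schedule.phi_on) % 0.5 < schedule.w / T


def window_phases(schedule: Schedule) -> tuple:
    """Onset phases of the two windows within one cycle."""
    return (schedule.phi_on, schedule.phi_on + 0.5)


def schedule_array(schedule: Schedule, N: int, T: float) -> np.ndarray:
    """Per-reference-step window id: 0 off, 1 first window (onset at
    ``phi_on``), 2 second window (onset at ``phi_on + 0.5``)."""
    out = np.zeros(N, dtype=np.int8)
    if schedule.mode == "off" or schedule.w == 0.0:
        return out
    schedule.validate_period(T)
    phases = np.arange(N) / N
    frac = schedule.w / T
    d = (phases - schedule.phi_on) % 1.0
    out[d < frac] = 1
    out[(d - 0.5 >= 0) & (d - 0.5 < frac)] = 2
    return out


def intermittent_torque(x, phase: float, schedule: Schedule,
                        igains: IntermittentGains,
                        basis: PhaseBasis | None,
                        ref: ReferenceGait,
                        cycles: int = 0) -> np.ndarray:
    """Intermittent torque at one instant (zero outside on-periods).

    For SMC the nominal point is the stable-manifold projection of the
    *current* state in the onset-phase basis (held fixed through the
    window); for LCC it is the reference state itself.
    """
    if not is_on(phase, schedule, ref.T):
        return np.zeros(9)
    x = np.asarray(x, dtype=float)
    xt = reference_error(x, ref, phase, cycles)
    if schedule.mode == "lcc":
        err = xt
    elif schedule.mode == "smc":
        if basis is None:
            raise ValueError("SMC requested without a phase basis")
        err = xt - projection_matrix(basis) @ xt
    else:
        return np.zeros(9)
    Pd = igains.p_diag()
    Dd = igains.d_diag()
    return -Pd * err[:9] - Dd * err[9:]
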