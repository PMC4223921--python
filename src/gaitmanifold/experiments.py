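"""Scenario runner: perturbed-gait simulations, fall statistics, scans of
the intermittent controller and the distance-to-reference metric.

All experiments integrate the full 18-state model with forward Euler at
the reference step, torqued by the feed-forward table, the continuous PD
feedback and (optionally) the intermittent SMC/LCC torque.  Results are
deterministic functions of their configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as _k
from .control import schedule_array, window_phases
from .floquet import FloquetError, classify_stability, monodromy
from .manifold import phase_basis, projection_matrix
from .params import (BodyParameters, ContactParams, GainSet,
                     IntermittentGains, Schedule, SimConfig)
from .trajectory import ReferenceGait

__all__ = [
    "SimResult",
    "run_gait",
    "detect_fall",
    "dist_to_reference",
    "scan_onset_duration",
    "scan_stabilized_gains",
    "min_stabilizing_duration",
]


@dataclass
class SimResult:
    """Sampled output of one controlled walking simulation."""

    config: SimConfig
    states: np.ndarray          # (n_rec, 18) every output_stride steps
    strobo: np.ndarray          # (n_cycles+1, 18) once per cycle
    sched: np.ndarray           # (N,) window id per reference step
    fall_cycle: int | None
    ref: ReferenceGait = field(repr=False, default=None)

    @property
    def fell(self) -> bool:
        return self.fall_cycle is not None

    def times(self) -> np.ndarray:
        return (np.arange(self.states.shape[0])
                * self.config.output_stride * self.ref.dt)


def _bases_for_schedule(ref: ReferenceGait, gains: GainSet,
                        schedule: Schedule, bases: dict | None = None):
    """Projection matrices for the two windows (SMC); zeros drive to the
    limit cycle (LCC)."""
    Z = np.zeros((18, 18))
    if schedule.mode != "smc":
        return Z, Z
    out = []
    for phi in window_phases(schedule):
        key = None
        if bases is not None:
            key = (round(phi % 1.0, 9),
                   gains.Pa, gains.Pk, gains.Ph, gains.Da, gains.Dk, gains.Dh)
            if key in bases:
                out.append(projection_matrix(bases[key]))
                continue
        b = phase_basis(monodromy(ref, gains, phi % 1.0))
        if bases is not None:
            bases[key] = b
        out.append(projection_matrix(b))
    return out[0], out[1]


def run_gait(config: SimConfig, ref: ReferenceGait,
             body: BodyParameters | None = None,
             contact: ContactParams | None = None,
             bases: dict | None = None) -> SimResult:
    """Integrate ``n_cycles`` of the controlled model from a perturbed
    reference state at phase ``phi0``.

    The initial state is ``x_r(phi0)`` plus the configured perturbation
    (which must be small enough for the phase assignment to be
    meaningful).  A numerical blow-up or a fall is recorded as the fall
    cycle, not an exception.
    """
    body = body or ref.body
    contact = contact or ref.contact
    if abs(config.dt - ref.dt) > 1e-15:
        raise ValueError(
            f"config.dt={config.dt} differs from the reference step "
            f"{ref.dt}; rebuild the reference at the desired step")
    N = ref.N
    sched = schedule_array(config.schedule, N, ref.T)
    PiA, PiB = _bases_for_schedule(ref, config.gains, config.schedule, bases)
    x0 = ref.state_at_phase(config.phi0) + config.perturbation_vector()
    k0 = ref.index_of_phase(config.phi0)
    nsteps = config.n_cycles * N
    stride_rec = max(int(config.output_stride), 1)
    n_rec = nsteps // stride_rec + 1
    rec = np.zeros((n_rec, 18))
    strobo = np.zeros((config.n_cycles + 1, 18))
    use_int = 1 if config.schedule.mode in ("smc", "lcc") else 0
    _, fall, nrec, nstr = _k.run_full(
        x0, nsteps, k0, N, ref.dt, body.to_array(), contact.to_array(),
        ref.X, ref.Uff, ref.stride, config.gains.p_diag(),
        config.gains.d_diag(), sched, PiA, PiB,
        config.igains.p_diag(), config.igains.d_diag(), use_int,
        ref.fall_threshold(), stride_rec, rec, strobo)
    return SimResult(config=config, states=rec[:nrec], strobo=strobo[:nstr],
                     sched=sched, fall_cycle=None if fall < 0 else int(fall),
                     ref=ref)


def detect_fall(states, ref: ReferenceGait, steps_per_sample: int = 1):
    """First cycle (1-based) in which the HAT drops below 60% of its
    reference mean height or tilts beyond 1 rad; None without a fall.
    Thresholds are closed: exactly reaching one counts as a fall."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    y_low = ref.fall_threshold()
    bad = (states[:, 2] <= y_low) | (np.abs(states[:, 0]) >= 1.0)
    idx = np.nonzero(bad)[0]
    if idx.size == 0:
        return None
    return int(idx[0] * steps_per_sample // ref.N) + 1


def dist_to_reference(result: SimResult, ref: ReferenceGait) -> float:
    """Normalized distortion of the final simulated cycle from the cycle.

    RMS over phase and components of the error, each state component
    normalized by its reference peak-to-peak range; the horizontal
    position (which advances freely) contributes its per-cycle
    stride-advance error relative to the reference stride.  Undefined for
    falling runs.
    """
    if result.fell:
        raise ValueError("distance to reference is undefined for a fall")
    stride_rec = result.config.output_stride
    if ref.N % stride_rec != 0:
        raise ValueError("output_stride must divide the steps per cycle")
    per_cycle = ref.N // stride_rec
    if result.states.shape[0] <= per_cycle:
        raise ValueError("need at least one full recorded cycle")
    seg = result.states[-per_cycle - 1:-1]
    n_prev = result.states.shape[0] - 1 - per_cycle
    k0 = ref.index_of_phase(result.config.phi0)
    comps = []
    for i in range(18):
        if i == 1:
            continue
        idx = (k0 + np.arange(per_cycle) * stride_rec
               + n_prev * stride_rec) % ref.N
        err = seg[:, i] - ref.X[idx, i]
        rng = np.ptp(ref.X[:, i])
        comps.append(np.sqrt(np.mean((err / rng) ** 2)))
    q2_adv = result.states[-1, 1] - result.states[-1 - per_cycle, 1]
    comps.append(abs(q2_adv - ref.stride) / ref.stride)
    return float(np.sqrt(np.mean(np.square(comps))))


def _survival(ref, gains, igains, schedule, n_cycles, perturbation,
              phi0, bases, output_stride=0):
    cfg = SimConfig(dt=ref.dt, n_cycles=n_cycles, gains=gains,
                    igains=igains, schedule=schedule,
                    perturbation=perturbation, phi0=phi0,
                    output_stride=output_stride or ref.N)
    res = run_gait(cfg, ref, bases=bases)
    n_fall = res.fall_cycle if res.fell else n_cycles
    return n_fall, res


#: default perturbation: HAT tilt, rad
DEFAULT_PERTURBATION = {0: 1e-3}


def scan_onset_duration(ref: ReferenceGait, mode: str, gains: GainSet,
                        igains: IntermittentGains, phi_on_values, w_values,
                        n_cycles: int = 20,
                        perturbation: dict | None = None,
                        phi0: float = 0.0) -> pd.DataFrame:
    """Survival map of the intermittent controller over (phi_on, w).

    Each cell runs ``n_cycles`` cycles and records the fall cycle
    ``N_fall`` (equal to ``n_cycles`` for survivors), the survival ratio
    ``N_fall / n_cycles`` and, for survivors, the distortion of the final
    cycle from the limit cycle (``dist``) -- survival alone does not
    distinguish re-convergence to the reference gait from capture by a
    nearby distorted attractor.
    """
    perturbation = DEFAULT_PERTURBATION if perturbation is None else perturbation
    bases: dict = {}
    rows = []
    for phi_on in phi_on_values:
        for w in w_values:
            row = {"phi_on": phi_on, "w": w, "n_fall": 0,
                   "ratio": 0.0, "dist": np.nan, "error": ""}
            try:
                sched = Schedule(phi_on=float(phi_on), w=float(w), mode=mode)
                n_fall, res = _survival(ref, gains, igains, sched, n_cycles,
                                        perturbation, phi0, bases,
                                        output_stride=100)
                row["n_fall"] = n_fall
                row["ratio"] = n_fall / n_cycles
                if not res.fell:
                    row["dist"] = dist_to_reference(res, ref)
            except (FloquetError, ValueError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def scan_stabilized_gains(ref: ReferenceGait, mode: str,
                          igains: IntermittentGains, schedule: Schedule,
                          P_values, gains_base: GainSet | None = None,
                          n_cycles: int = 20,
                          perturbation: dict | None = None,
                          phi0: float = 0.0,
                          dist_thresholds=(0.05, 0.1)) -> pd.DataFrame:
    """Which unstable P-gain points the intermittent controller rescues.

    Grid points that are already stable without intermittent control are
    excluded (marked ``skipped``).  Stabilized points are categorized by
    the distortion of the steady trajectory from the limit cycle.
    """
    perturbation = DEFAULT_PERTURBATION if perturbation is None else perturbation
    gains_base = gains_base or GainSet()
    bases: dict = {}
    rows = []
    sched = Schedule(phi_on=schedule.phi_on, w=schedule.w, mode=mode)
    for P in P_values:
        Pa, Pk, Ph = (P if np.iterable(P) else (P, P, P))
        g = gains_base.replace(Pa=float(Pa), Pk=float(Pk), Ph=float(Ph))
        row = {"Pa": Pa, "Pk": Pk, "Ph": Ph, "skipped": False,
               "stabilized": False, "n_fall": 0, "dist": np.nan,
               "category": "", "error": ""}
        try:
            verdict, _ = classify_stability(monodromy(ref, g, phi0))
            if verdict == "stable":
                row["skipped"] = True
                rows.append(row)
                continue
            n_fall, res = _survival(ref, g, igains, sched, n_cycles,
                                    perturbation, phi0, bases,
                                    output_stride=100)
            row["n_fall"] = n_fall
            if not res.fell:
                row["stabilized"] = True
                d = dist_to_reference(res, ref)
                row["dist"] = d
                lo, hi = dist_thresholds
                row["category"] = ("close" if d < lo
                                   else "medium" if d < hi else "far")
        except (FloquetError, ValueError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def min_stabilizing_duration(ref: ReferenceGait, mode: str, gains: GainSet,
                             igains: IntermittentGains, phi_on: float,
                             n_cycles: int = 20,
                             perturbation: dict | None = None,
                             phi0: float = 0.0,
                             w_max: float | None = None,
                             tol: float = 1e-3,
                             dist_ok: float | None = 0.05):
    """Smallest on-period duration w (s) that stabilizes the gait, by
    bisection under the (documented) assumption that success is monotone
    in w.  Success means surviving ``n_cycles`` cycles and, when
    ``dist_ok`` is set, returning to within that distortion of the limit
    cycle (capture by a distorted attractor does not count).  None if
    even ``w_max`` fails."""
    perturbation = DEFAULT_PERTURBATION if perturbation is None else perturbation
    bases: dict = {}
    w_hi = w_max if w_max is not None else 0.45 * ref.T

    def survives(w):
        if w <= 0:
            return False
        sched = Schedule(phi_on=phi_on, w=float(w), mode=mode)
        n_fall, res = _survival(ref, gains, igains, sched, n_cycles,
                                perturbation, phi0, bases,
                                output_stride=100)
        if n_fall < n_cycles:
            return False
        if dist_ok is not None and dist_to_reference(res, ref) >= dist_ok:
            return False
        return True

    if not survives(w_hi):
        return None
    w_lo = 0.0
    while w_hi - w_lo > tol:
        mid = 0.5 * (w_lo + w_hi)
        if survives(mid):
            w_hi = mid
        else:
            w_lo = mid
    return w_hi
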