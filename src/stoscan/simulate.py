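"""Closed-loop scan simulation: the measurement model of the virtual
scanner.

``simulate_scan`` runs the acquisition controller against a breathing
phantom in real time: the surrogate samples stream into the phase
predictor, the controller commands gantry speed and the projection gate,
a first-order plant (speed tracking saturated at the acceleration limit)
moves the gantry, and projections fire only on the trigger-rate grid.
Acquired projections render the phantom at the trace's current
displacement and forward-project it at the current gantry angle.

Recorded bin labels are the ground-truth labels from the trace, so
prediction errors surface as errors in the *data structure* (wrong angle
for a bin, broken bin succession) rather than as label noise --
retrospective sorting from the recorded signal is how the real system
bins its projections too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stoscan.breathing import FitError, PhasePredictor, PredictorConfig
from stoscan.control import (
    GATE_GUARD_S,
    AcquisitionSchedule,
    GantryState,
    PhaseOutlook,
    ScanProtocol,
    control_step,
)
from stoscan.grids import GridSpec, ProjectionSet, ScanGeometry
from stoscan.phantom import BreathingTrace, PhantomModel, phantom_volume
from stoscan.projector import forward_project

__all__ = ["NoiseModel", "SimResult", "simulate_scan", "apply_noise"]

_CTRL_RATE_HZ = 30.0  # controller tick rate


@dataclass(frozen=True)
class NoiseModel:
    """Poisson photon noise at ``i0`` incident photons per detector
    element; disabled models pass projections through unchanged."""

    i0: float = 1e4
    enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")


@dataclass
class SimResult:
    schedule: AcquisitionSchedule
    projections: ProjectionSet | None
    trajectory: list[GantryState]
    events: list[str]


def apply_noise(projections: ProjectionSet, noise: NoiseModel) -> ProjectionSet:
    """Poissonize the line integrals: counts ~ Poisson(I0 exp(-p)),
    clamped at 0.5 counts, converted back to -log(counts / I0)."""
    if not noise.enabled:
        return projections
    p = projections.stack.astype(np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("line integrals must be finite")
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(noise.i0 * np.exp(-p)).astype(np.float64)
    counts = np.maximum(counts, 0.5)
    return projections.replace_stack((-np.log(counts / noise.i0))
                                     .astype(np.float32))


class _PhantomRenderCache:
    """Render the phantom at quantized displacements and memoize."""

    def __init__(self, model: PhantomModel, grid: GridSpec,
                 levels: int = 200):
        self.model = model
        self.grid = grid
        self.levels = levels
        self._cache: dict[int, object] = {}

    def volume(self, u: float):
        q = int(round(np.clip(u, 0.0, 1.0) * self.levels))
        if q not in self._cache:
            self._cache[q] = phantom_volume(self.model, q / self.levels,
                                            self.grid)
        return self._cache[q]


def _render_projections(model: PhantomModel, trace: BreathingTrace,
                        geometry: ScanGeometry, grid: GridSpec,
                        times: np.ndarray, angles: np.ndarray,
                        bins: np.ndarray) -> ProjectionSet:
    cache = _PhantomRenderCache(model, grid)
    stacks = []
    for t, ang in zip(times, angles):
        _, u, _ = trace.sample_at(float(t))
        vol = cache.volume(u)
        stacks.append(forward_project(vol, geometry, [ang]).stack[0])
    return ProjectionSet(np.stack(stacks), angles, geometry, times, bins)


def _simulate_conventional(model, trace, protocol, geometry, grid,
                           render) -> SimResult:
    from stoscan.control import conventional_schedule

    sched = conventional_schedule(protocol)
    if trace.times[-1] < sched.times_s[-1]:
        raise ValueError("trace shorter than the conventional scan duration")
    bins = np.array([trace.sample_at(float(t))[2] for t in sched.times_s],
                    np.int64)
    schedule = AcquisitionSchedule(
        sched.k, sched.times_s, sched.angles_deg, bins,
        np.ones(protocol.n_projections, bool), "simulated",
        protocol.n_bins)
    speed = protocol.arc_deg / protocol.duration_s
    traj = [GantryState(float(t), float(a), speed)
            for t, a in zip(sched.times_s, sched.angles_deg)]
    proj = None
    if render:
        proj = _render_projections(model, trace, geometry, grid,
                                   sched.times_s, sched.angles_deg, bins)
    return SimResult(schedule, proj, traj, [])


def simulate_scan(model: PhantomModel, trace: BreathingTrace,
                  protocol: ScanProtocol, geometry: ScanGeometry,
                  predictor_cfg: PredictorConfig | None = None,
                  grid: GridSpec | None = None, seed: int = 0,
                  noise: NoiseModel | None = None,
                  render: bool = True) -> SimResult:
    """Run one scan (conventional or closed-loop STO) against the phantom.

    Returns the realized schedule, the projection stack (None when
    ``render`` is off), the gantry trajectory from the first acquisition
    onward, and controller event log entries. If the trace ends before
    the scan completes, the partial schedule is returned with the abort
    flag set.
    """
    grid = grid or GridSpec()
    if protocol.mode == "conventional":
        return _simulate_conventional(model, trace, protocol, geometry,
                                      grid, render)

    cfg = predictor_cfg or PredictorConfig(n_bins=protocol.n_bins)
    if cfg.n_bins != protocol.n_bins:
        raise ValueError("predictor and protocol disagree on n_bins")
    pred = PhasePredictor(cfg)
    dt = 1.0 / _CTRL_RATE_HZ
    dtrig = protocol.trigger_period_s
    events: list[str] = []

    # plant state
    t = float(trace.times[0])
    angle = 0.0
    speed = 0.0
    setpoint = 0.0

    k_star = 1
    acq_t: list[float] = []
    acq_ang: list[float] = []
    acq_bin: list[int] = []
    traj: list[GantryState] = []
    pending_gate = False
    next_trig = np.ceil((t + 1e-9) / dtrig) * dtrig
    aborted = True  # until N_p projections are in

    n_samples = trace.times.size
    for m in range(n_samples):
        tm = float(trace.times[m])
        pred.push(tm, float(trace.amplitude[m]))

        # fire any trigger tick inside (t, tm + dt]
        while next_trig <= tm + dt + 1e-12:
            # advance plant to the trigger instant
            step_dt = next_trig - t
            if step_dt > 0:
                speed_new = speed + np.clip(setpoint - speed,
                                            -protocol.a_max * step_dt,
                                            protocol.a_max * step_dt)
                angle += (speed + speed_new) / 2.0 * step_dt
                speed = speed_new
                t = next_trig
            if pending_gate and k_star <= protocol.n_projections:
                _, _, truth_bin = trace.sample_at(t)
                acq_t.append(t)
                acq_ang.append(angle)
                acq_bin.append(truth_bin)
                target_bin = (k_star - 1) % protocol.n_bins + 1
                if truth_bin != target_bin:
                    events.append(f"t={t:.3f}s bin mismatch: wanted "
                                  f"{target_bin}, patient in {truth_bin}")
                k_star += 1
            pending_gate = False
            # decide the gate for the *next* trigger tick now; the bin
            # must be predicted active both at the tick and a guard
            # interval before it, so the patient is safely inside the
            # target bin when the x-ray fires
            if k_star <= protocol.n_projections and pred.ready:
                target_bin = (k_star - 1) % protocol.n_bins + 1
                lead = next_trig + dtrig - t
                pending_gate = (
                    pred.predict_bin(lead) == target_bin
                    and pred.predict_bin(max(lead - GATE_GUARD_S, 0.0)) == target_bin)
            next_trig += dtrig
            if k_star > protocol.n_projections:
                aborted = False
                break
        if k_star > protocol.n_projections:
            break

        # controller tick: recompute the speed setpoint
        scan_started = len(acq_t) > 0
        if pred.ready and k_star <= protocol.n_projections:
            target_bin = (k_star - 1) % protocol.n_bins + 1
            try:
                ttb = pred.time_to_bin(target_bin)
                outlook = PhaseOutlook(pred.predict_bin(cfg.latency_s),
                                       ttb, pred.period_estimate(), True)
                cmd = control_step(GantryState(tm, angle, speed), outlook,
                                   k_star, protocol, next_trig, scan_started)
                setpoint = cmd.speed_setpoint
                if cmd.unavoidable_error:
                    events.append(f"t={tm:.3f}s unavoidable schedule error "
                                  f"(k={k_star})")
            except FitError:
                setpoint = max(speed, protocol.v_abort) if scan_started else 0.0
        else:
            setpoint = protocol.v_abort if scan_started else 0.0

        # advance plant to the end of this controller tick
        remaining = tm + dt - t
        if remaining > 0:
            speed_new = speed + np.clip(setpoint - speed,
                                        -protocol.a_max * remaining,
                                        protocol.a_max * remaining)
            angle += (speed + speed_new) / 2.0 * remaining
            speed = speed_new
        t = tm + dt
        if scan_started:
            traj.append(GantryState(t, angle, speed))

    n_acq = len(acq_t)
    if n_acq == 0:
        raise ValueError("no projections acquired; trace too short or "
                         "no breathing detected")
    if aborted:
        events.append(f"scan aborted after {n_acq} of "
                      f"{protocol.n_projections} projections")
    k = np.arange(1, n_acq + 1)
    schedule = AcquisitionSchedule(
        k, np.asarray(acq_t), np.asarray(acq_ang), np.asarray(acq_bin),
        np.ones(n_acq, bool), "simulated", protocol.n_bins,
        aborted=aborted, events=list(events))
    # trim the trajectory to the acquisition window
    traj = [s for s in traj if acq_t[0] <= s.time <= acq_t[-1]]

    proj = None
    if render:
        proj = _render_projections(model, trace, geometry, grid,
                                   schedule.times_s, schedule.angles_deg,
                                   schedule.bins)
        if noise is not None:
            proj = apply_noise(proj, noise)
    return SimResult(schedule, proj, traj, events)
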