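"""Acquisition schedules and the real-time gantry controller.

Two schedule families are defined. A *conventional* scan rotates at
constant speed and acquires at a constant trigger rate: even spacing in
angle and time with no reference to the patient. An *STO* (spatio-
temporally optimized) scan targets the interleaved ideal structure:
projection ``k`` at angle ``k * arc / N_p`` with respiratory bin
``((k - 1) mod N_b) + 1``, so consecutive projections step through the
breathing cycle and projections of the same bin are spread evenly
``N_b * arc / N_p`` apart.

The closed-loop controller that realizes the STO structure is a
receding-horizon greedy rule: it always works on the next ideal
projection ``k*``, estimates from the phase predictor when the target bin
will next be active, commands the gantry speed needed to arrive at the
ideal angle at that time (saturated by the hardware constraint set), and
opens the projection gate only during predicted occupancy of the target
bin. The objective it greedily minimizes is the absolute angular
deviation from the ideal schedule -- the same quantity the schedule MAE
metric reports.

Hardware constraint set: unidirectional rotation, speed <= 6 deg/s,
acceleration <= 2 deg/s^2, projections only on the 5.5 Hz trigger grid,
and a minimum sustained speed of 0.3 deg/s below which a real scan would
abort. The controller never *commands* less than the abort speed while a
scan is in progress; when the patient makes the ideal angle unreachable
(e.g. a skipped breath) the gantry drifts past it and the excess shows up
as schedule error rather than as an abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GATE_GUARD_S = 0.08  # patient must be this far inside the bin at the trigger

__all__ = [
    "ScanProtocol",
    "AcquisitionSchedule",
    "ControlCommand",
    "GantryState",
    "PhaseOutlook",
    "Violation",
    "ideal_schedule",
    "conventional_schedule",
    "control_step",
    "validate_constraints",
    "CONVENTIONAL_PROTOCOL",
    "STO600_PROTOCOL",
    "STO200_PROTOCOL",
]


@dataclass(frozen=True)
class ScanProtocol:
    """Scan protocol: projection count, binning, arc and hardware limits."""

    n_projections: int = 1320
    n_bins: int = 10
    arc_deg: float = 200.0
    duration_s: float = 240.0  # conventional scans only
    trigger_rate_hz: float = 5.5
    v_max: float = 6.0       # deg/s
    v_abort: float = 0.3     # deg/s
    a_max: float = 2.0       # deg/s^2
    mode: str = "conventional"  # "conventional" | "STO"

    def __post_init__(self) -> None:
        if self.mode not in ("conventional", "STO"):
            raise ValueError("mode must be 'conventional' or 'STO'")
        if self.n_projections < 1 or self.n_bins < 1:
            raise ValueError("projection and bin counts must be positive")
        if self.mode == "STO" and self.n_projections % self.n_bins:
            raise ValueError("STO requires N_p divisible by N_b")
        if self.arc_deg / self.n_projections <= 0:
            raise ValueError("angular step must be positive")
        if not (0 <= self.v_abort < self.v_max):
            raise ValueError("need 0 <= v_abort < v_max")
        if self.a_max <= 0 or self.trigger_rate_hz <= 0:
            raise ValueError("a_max and trigger_rate_hz must be positive")

    @property
    def angular_step_deg(self) -> float:
        return self.arc_deg / self.n_projections

    @property
    def same_bin_separation_deg(self) -> float:
        """Ideal angular separation between projections of one bin."""
        return self.n_bins * self.arc_deg / self.n_projections

    @property
    def trigger_period_s(self) -> float:
        return 1.0 / self.trigger_rate_hz


CONVENTIONAL_PROTOCOL = ScanProtocol()
STO600_PROTOCOL = ScanProtocol(n_projections=600, mode="STO")
STO200_PROTOCOL = ScanProtocol(n_projections=200, mode="STO")


@dataclass
class AcquisitionSchedule:
    """Per-projection schedule records: index, time, angle, bin.

    ``provenance`` is ``ideal`` (times unbound), ``conventional`` or
    ``simulated``. ``aborted`` marks a scan cut short by the controller.
    """

    k: np.ndarray
    times_s: np.ndarray
    angles_deg: np.ndarray
    bins: np.ndarray
    acquired: np.ndarray
    provenance: str = "simulated"
    n_bins: int = 10
    aborted: bool = False
    events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.bins = np.asarray(self.bins, dtype=np.int64)
        self.acquired = np.asarray(self.acquired, dtype=bool)
        n = self.k.size
        for a in (self.times_s, self.angles_deg, self.bins, self.acquired):
            if a.shape != (n,):
                raise ValueError("schedule column lengths disagree")
        t = self.times_s[self.acquired & np.isfinite(self.times_s)]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if np.any(np.diff(self.angles_deg) < -1e-9):
            raise ValueError("angles must be nondecreasing (unidirectional)")

    @property
    def n_acquired(self) -> int:
        return int(np.count_nonzero(self.acquired))

    def duration_s(self) -> float:
        t = self.times_s[self.acquired]
        return float(t[-1] - t[0]) if t.size > 1 else 0.0


@dataclass(frozen=True)
class ControlCommand:
    time: float
    speed_setpoint: float  # deg/s
    gate_open: bool
    unavoidable_error: bool = False

    def __post_init__(self) -> None:
        if self.speed_setpoint < 0:
            raise ValueError("speed setpoint must be nonnegative")


@dataclass(frozen=True)
class GantryState:
    time: float
    angle: float  # deg
    speed: float  # deg/s


@dataclass(frozen=True)
class PhaseOutlook:
    """What the controller knows about the breathing at decision time:
    the bin predicted one latency ahead, the seconds until the target bin
    next becomes active (0 if active at the horizon), the period estimate
    and the predictor's confidence flag."""

    predicted_bin: int
    time_to_target_s: float
    period_s: float
    confident: bool = True


def ideal_schedule(protocol: ScanProtocol) -> AcquisitionSchedule:
    """The ideal STO schedule: angles ``k * arc / N_p``, bins cycling
    ``1..N_b``. Times are unbound (NaN) -- they depend on the patient."""
    if protocol.mode != "STO":
        raise ValueError("ideal_schedule requires an STO protocol")
    np_ = protocol.n_projections
    k = np.arange(1, np_ + 1)
    return AcquisitionSchedule(
        k=k,
        times_s=np.full(np_, np.nan),
        angles_deg=k * protocol.angular_step_deg,
        bins=((k - 1) % protocol.n_bins) + 1,
        acquired=np.ones(np_, bool),
        provenance="ideal",
        n_bins=protocol.n_bins,
    )


def conventional_schedule(protocol: ScanProtocol) -> AcquisitionSchedule:
    """The conventional schedule: even steps in angle and time; bins are
    unassigned (0) until a breathing trace is available."""
    np_ = protocol.n_projections
    k = np.arange(1, np_ + 1)
    return AcquisitionSchedule(
        k=k,
        times_s=k * (protocol.duration_s / np_),
        angles_deg=k * protocol.angular_step_deg,
        bins=np.zeros(np_, np.int64),
        acquired=np.ones(np_, bool),
        provenance="conventional",
        n_bins=protocol.n_bins,
    )


def control_step(state: GantryState, outlook: PhaseOutlook, k_star: int,
                 protocol: ScanProtocol, next_trigger_s: float,
                 scan_started: bool = True) -> ControlCommand:
    """One receding-horizon control decision.

    Estimates the trigger tick at which ideal projection ``k_star`` can
    be acquired (the first tick inside the next predicted occupancy of
    its bin), commands the speed needed to be at the ideal angle then,
    and opens the gate when that tick is the immediate next one and the
    prediction says the target bin will be active.

    Before the first projection (``scan_started=False``) the gantry may
    park; afterwards the commanded speed never drops below the abort
    threshold, so unreachable targets overshoot instead of stalling.
    """
    target_bin = (k_star - 1) % protocol.n_bins + 1
    s_target = k_star * protocol.angular_step_deg
    dt_trig = protocol.trigger_period_s

    # first trigger tick at/after the bin entry, with a small guard so
    # the patient is safely inside the bin when the x-ray fires; a bin
    # that is already active needs no guard
    if outlook.time_to_target_s <= 0.0:
        t_star = next_trigger_s
    else:
        t_entry = state.time + outlook.time_to_target_s
        if t_entry + GATE_GUARD_S <= next_trigger_s:
            t_star = next_trigger_s
        else:
            n_ahead = int(np.ceil((t_entry + GATE_GUARD_S - next_trigger_s)
                                  / dt_trig))
            t_star = next_trigger_s + n_ahead * dt_trig

    # track the ideal pace line: arrive at the target angle at the target
    # tick while moving at the steady ideal speed (one angular step per
    # bin dwell), so consecutive projections need no speed transients
    period = outlook.period_s if outlook.period_s > 0.5 else 0.5
    v_pace = protocol.angular_step_deg * protocol.n_bins / period
    horizon = max(t_star - state.time, 1e-6)
    line_pos = s_target - v_pace * horizon
    v_req = v_pace + (line_pos - state.angle) / 0.3
    unavoidable = False
    if (s_target - state.angle) / horizon > protocol.v_max:
        unavoidable = True
    if v_req > protocol.v_max:
        v_req = protocol.v_max
    v_floor = protocol.v_abort if scan_started else 0.0
    if v_req < v_floor:
        v_req = v_floor
        if state.angle > s_target + 0.5:
            unavoidable = True
    gate = (outlook.confident
            and t_star == next_trigger_s
            and outlook.predicted_bin == target_bin)
    return ControlCommand(state.time, float(max(v_req, 0.0)), bool(gate),
                          unavoidable)


@dataclass(frozen=True)
class Violation:
    kind: str
    time: float
    detail: str


def validate_constraints(trajectory: list[GantryState],
                         protocol: ScanProtocol,
                         schedule: AcquisitionSchedule | None = None,
                         abort_dwell_s: float = 5.0,
                         tol: float = 1e-6) -> list[Violation]:
    """Check a gantry trajectory (and optionally its schedule) against
    the hardware constraint set. An empty report means compliant.

    Checks: unidirectional rotation, speed cap, acceleration cap, the
    sustained-underspeed abort condition, and (when a simulated schedule
    is given) alignment of acquisition times with the trigger grid.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    out: list[Violation] = []
    t = np.array([s.time for s in trajectory])
    ang = np.array([s.angle for s in trajectory])
    v = np.array([s.speed for s in trajectory])

    rev = np.nonzero(np.diff(ang) < -tol)[0]
    for i in rev:
        out.append(Violation("unidirectional", float(t[i + 1]),
                             f"angle decreased by {ang[i] - ang[i+1]:.4g} deg"))
    over = np.nonzero(v > protocol.v_max + tol)[0]
    for i in over[:10]:
        out.append(Violation("speed", float(t[i]),
                             f"speed {v[i]:.3f} > v_max {protocol.v_max}"))
    dt = np.diff(t)
    good = dt > 0
    acc = np.abs(np.diff(v)[good] / dt[good])
    tacc = t[1:][good]
    bad = np.nonzero(acc > protocol.a_max + 1e-3)[0]
    for i in bad[:10]:
        out.append(Violation("acceleration", float(tacc[i]),
                             f"|dv/dt| {acc[i]:.3f} > a_max {protocol.a_max}"))

    # sustained underspeed -> the hardware would have aborted
    slow = v < protocol.v_abort - tol
    if np.any(slow):
        start = None
        for i in range(len(v)):
            if slow[i] and start is None:
                start = t[i]
            elif not slow[i] and start is not None:
                if t[i] - start > abort_dwell_s:
                    out.append(Violation("abort", float(start),
                                         "sustained speed below abort limit"))
                start = None
        if start is not None and t[-1] - start > abort_dwell_s:
            out.append(Violation("abort", float(start),
                                 "sustained speed below abort limit"))

    if schedule is not None and schedule.provenance == "simulated":
        tk = schedule.times_s[schedule.acquired]
        frac = tk * protocol.trigger_rate_hz
        off = np.abs(frac - np.round(frac)) / protocol.trigger_rate_hz
        for i in np.nonzero(off > 1e-6)[0][:10]:
            out.append(Violation("trigger_grid", float(tk[i]),
                                 f"time off trigger grid by {off[i]:.3g} s"))
    return out
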