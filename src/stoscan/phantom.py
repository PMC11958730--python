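"""Breathing thorax phantom and surrogate-signal generator.

The phantom is a deliberately simple geometric thorax: an elliptical body,
two low-attenuation lung ellipsoids, a spherical tumor inside one lung and
a spherical-cap diaphragm dome at the base of the other. The tumor and the
diaphragm apex translate along the superior-inferior axis as a function of
a normalized breathing displacement ``u`` in [0, 1] (``u = 1`` at peak
inhale). The surrogate signal emulates anterior chest-surface height as
seen by a depth camera: a per-breath raised-cosine waveform with variable
period and amplitude, linear baseline drift, sensor noise, and optionally
a window of irregular breathing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from stoscan.grids import GridSpec, Volume3D

__all__ = [
    "IrregularEpisode",
    "TraceParams",
    "BreathingTrace",
    "Ellipsoid",
    "Sphere",
    "DiaphragmDome",
    "PhantomModel",
    "generate_breathing_trace",
    "make_phantom",
    "phantom_volume",
    "retrospective_phase_bins",
]


# --------------------------------------------------------------------------
# surrogate trace
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IrregularEpisode:
    """A window of disrupted breathing (e.g. coughing).

    During ``[start_s, start_s + duration_s]`` each breath's period and
    amplitude are multiplied by factors drawn uniformly from the given
    ranges, emulating the short stretches of very irregular breathing seen
    in some patients.
    """

    start_s: float = 40.0
    duration_s: float = 20.0
    period_factor_range: tuple[float, float] = (0.55, 1.9)
    amplitude_factor_range: tuple[float, float] = (0.4, 1.3)


@dataclass(frozen=True)
class TraceParams:
    """Generator parameters for the chest-height surrogate signal.

    Defaults model a regular adult breather: 4 s mean period, 10 mm
    peak-to-trough chest excursion, mild breath-to-breath variability,
    slow baseline drift and sub-millimeter sensor noise.
    """

    period_mean_s: float = 4.0
    period_std_s: float = 0.2
    amplitude_mm: float = 10.0
    amplitude_jitter: float = 0.05
    baseline_mm: float = 0.0
    drift_mm_per_min: float = 0.5
    noise_std_mm: float = 0.1
    shape: float = 1.0  # waveform exponent; >1 lengthens the exhale dwell
    sample_rate_hz: float = 30.0
    n_bins: int = 10
    irregular: IrregularEpisode | None = None

    def __post_init__(self) -> None:
        if self.period_mean_s <= 0:
            raise ValueError("period_mean_s must be positive")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be positive")
        if self.period_std_s < 0 or self.noise_std_mm < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")


# Preset breathers. "Regular" keeps a reproducible 4 s period (plus sensor
# noise and baseline drift): with breath-to-breath period variability the
# time-normalized phase of the *current* breath is intrinsically
# unpredictable at the bin-boundary level, so the regular preset is the
# reference condition for closed-loop schedule fidelity. "Variable" is the
# realistic default; "irregular" adds a 20 s disrupted-breathing episode.
REGULAR_BREATHER = TraceParams(period_std_s=0.0, amplitude_jitter=0.0)
VARIABLE_BREATHER = TraceParams()
IRREGULAR_BREATHER = TraceParams(irregular=IrregularEpisode())


@dataclass
class BreathingTrace:
    """Uniformly sampled surrogate signal with ground-truth phase labels.

    ``amplitude`` is the measured (noisy) chest height in mm;
    ``displacement`` is the noiseless normalized breathing displacement
    u(t) in [0, 1] that actually drives the anatomy (sensor noise does not
    move the patient); ``true_phase`` is the bin label 1..n_bins assigned
    from the normalized time within each breath, bin 1 starting at peak
    inhale.
    """

    times: np.ndarray
    amplitude: np.ndarray
    true_phase: np.ndarray
    displacement: np.ndarray
    params: TraceParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.true_phase = np.asarray(self.true_phase, dtype=np.int64)
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        n = self.times.size
        if not (self.amplitude.size == self.true_phase.size == n
                == self.displacement.size):
            raise ValueError("trace arrays must have equal length")
        dt = np.diff(self.times)
        if n > 1 and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite everywhere")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sample_at(self, t: float) -> tuple[float, float, int]:
        """(amplitude, displacement, true bin) at time t, linearly
        interpolated for the continuous signals, nearest for the label."""
        a = float(np.interp(t, self.times, self.amplitude))
        u = float(np.interp(t, self.times, self.displacement))
        i = int(np.clip(round((t - self.times[0]) / self.dt), 0,
                        self.times.size - 1))
        return a, u, int(self.true_phase[i])


def _truncated_normal(rng: np.random.Generator, mean: float, std: float,
                      lo_frac: float = 0.5, hi_frac: float = 1.5) -> float:
    """Normal draw truncated (by redraw) to [lo_frac, hi_frac] * mean."""
    if std == 0:
        return mean
    for _ in range(100):
        x = rng.normal(mean, std)
        if lo_frac * mean <= x <= hi_frac * mean:
            return float(x)
    return mean


def generate_breathing_trace(params: TraceParams, duration: float,
                             seed: int) -> BreathingTrace:
    """Generate a surrogate breathing trace of the requested duration.

    Each breath draws its period from a truncated normal and its amplitude
    from a jittered mean; within a breath the waveform is
    ``((1 + cos(2 pi phi)) / 2) ** shape`` with ``phi`` the normalized
    time since the breath's peak inhale. Identical ``(params, seed)``
    yield identical output.
    """
    if duration <= params.period_mean_s:
        raise ValueError("duration must exceed one breath period")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sample_rate_hz
    n = int(np.floor(duration / dt)) + 1
    times = np.arange(n) * dt

    # breath boundaries covering [0, duration]
    starts = [0.0]
    periods: list[float] = []
    amps: list[float] = []
    while starts[-1] < duration:
        t0 = starts[-1]
        T = _truncated_normal(rng, params.period_mean_s, params.period_std_s)
        A = params.amplitude_mm * max(
            0.1, 1.0 + params.amplitude_jitter * rng.standard_normal())
        ep = params.irregular
        if ep is not None and ep.start_s <= t0 < ep.start_s + ep.duration_s:
            T *= rng.uniform(*ep.period_factor_range)
            A *= rng.uniform(*ep.amplitude_factor_range)
        periods.append(T)
        amps.append(A)
        starts.append(t0 + T)
    starts_arr = np.asarray(starts)

    idx = np.clip(np.searchsorted(starts_arr, times, side="right") - 1,
                  0, len(periods) - 1)
    T_i = np.asarray(periods)[idx]
    A_i = np.asarray(amps)[idx]
    phi = (times - starts_arr[idx]) / T_i
    u = ((1.0 + np.cos(2.0 * np.pi * phi)) / 2.0) ** params.shape
    drift = params.drift_mm_per_min * times / 60.0
    noise = (params.noise_std_mm * rng.standard_normal(n)
             if params.noise_std_mm > 0 else 0.0)
    amplitude = params.baseline_mm + drift + A_i * u + noise
    true_phase = (np.floor(np.clip(phi, 0, 1 - 1e-12) * params.n_bins)
                  .astype(np.int64) % params.n_bins) + 1
    return BreathingTrace(times, amplitude, true_phase, u, params)


def retrospective_phase_bins(trace: BreathingTrace, n_bins: int) -> np.ndarray:
    """Ground-truth style phase labels from peak detection on the signal.

    Each sample gets a bin 1..n_bins by its normalized time between the
    surrounding peak-inhale events; bin 1 starts at peak inhale. Samples
    before the first / after the last detected peak reuse the neighboring
    breath's period.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    y = trace.amplitude
    dt = trace.dt
    span = float(np.percentile(y, 97) - np.percentile(y, 3))
    if span <= 0:
        raise ValueError("no detectable breathing peaks in trace")
    min_dist = max(2, int(round(0.4 * trace.params.period_mean_s / dt)))
    peaks, _ = find_peaks(y, distance=min_dist, prominence=0.3 * span)
    if peaks.size < 2:
        raise ValueError("no detectable breathing peaks in trace")
    t_peaks = trace.times[peaks]
    # extend the peak grid beyond both ends with the edge periods
    first_T = t_peaks[1] - t_peaks[0]
    last_T = t_peaks[-1] - t_peaks[-2]
    n_left = int(np.ceil((t_peaks[0] - trace.times[0]) / first_T)) + 1
    n_right = int(np.ceil((trace.times[-1] - t_peaks[-1]) / last_T)) + 1
    left = t_peaks[0] - first_T * np.arange(n_left, 0, -1)
    right = t_peaks[-1] + last_T * np.arange(1, n_right + 1)
    grid = np.concatenate([left, t_peaks, right])
    idx = np.clip(np.searchsorted(grid, trace.times, side="right") - 1,
                  0, grid.size - 2)
    phi = (trace.times - grid[idx]) / (grid[idx + 1] - grid[idx])
    labels = (np.floor(np.clip(phi, 0, 1 - 1e-12) * n_bins)
              .astype(np.int64) % n_bins) + 1
    return labels


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    attenuation: float


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    attenuation: float


@dataclass(frozen=True)
class MovingSphere:
    """A small intrapulmonary structure (vessel/bronchus cross-section)
    that translates with breathing: position = center - u * amplitude."""

    center: tuple[float, float, float]
    radius: float
    attenuation: float
    amplitude_mm: tuple[float, float, float]


@dataclass(frozen=True)
class DiaphragmDome:
    """Spherical-cap dome: the part of a sphere of radius ``radius``
    centered ``radius`` below the apex that intrudes into the lung."""

    apex: tuple[float, float, float]
    radius: float
    attenuation: float


@dataclass(frozen=True)
class PhantomModel:
    """Geometric breathing-thorax phantom.

    ``tumor_amplitude_mm`` and ``diaphragm_amplitude_mm`` are displacement
    vectors (mm); the default motion is superior-inferior only. At
    displacement ``u`` the tumor center and diaphragm apex sit at their
    reference position minus ``u`` times the amplitude vector (anatomy
    descends toward peak inhale, ``u = 1``).
    """

    body: Ellipsoid
    lungs: tuple[Ellipsoid, Ellipsoid]
    tumor: Sphere
    diaphragm: DiaphragmDome
    tumor_amplitude_mm: tuple[float, float, float] = (0.0, 0.0, 15.0)
    diaphragm_amplitude_mm: tuple[float, float, float] = (0.0, 0.0, 25.0)
    vessels: tuple[MovingSphere, ...] = ()

    def __post_init__(self) -> None:
        atts = [self.body.attenuation, self.lungs[0].attenuation,
                self.lungs[1].attenuation, self.tumor.attenuation,
                self.diaphragm.attenuation]
        if any(a < 0 for a in atts):
            raise ValueError("attenuations must be nonnegative")
        lung_att = max(self.lungs[0].attenuation, self.lungs[1].attenuation)
        if self.body.attenuation > 0 and lung_att >= self.body.attenuation:
            raise ValueError("lung attenuation must be below body attenuation")
        if (self.tumor.radius > 0 and self.tumor.attenuation > 0
                and self.body.attenuation > self.tumor.attenuation):
            raise ValueError("tumor attenuation must be >= body attenuation")
        for u in (0.0, 0.5, 1.0):
            if self.tumor.radius > 0 and not self._tumor_inside_lung(u):
                raise ValueError(
                    f"tumor leaves the lung at displacement u={u}")

    def tumor_center(self, u: float) -> np.ndarray:
        c = np.asarray(self.tumor.center, float)
        return c - u * np.asarray(self.tumor_amplitude_mm, float)

    def diaphragm_apex(self, u: float) -> np.ndarray:
        a = np.asarray(self.diaphragm.apex, float)
        return a - u * np.asarray(self.diaphragm_amplitude_mm, float)

    def _tumor_inside_lung(self, u: float) -> bool:
        c = self.tumor_center(u)
        r = self.tumor.radius
        for lung in self.lungs:
            axes = np.asarray(lung.semi_axes, float) - r
            if np.any(axes <= 0):
                continue
            d = (c - np.asarray(lung.center, float)) / axes
            if float(d @ d) <= 1.0:
                return True
        return False


def make_phantom(config: dict | None = None) -> PhantomModel:
    """Build a validated phantom, defaults giving a desk-scale thorax.

    The default body is an elliptical cylinder-like trunk ~230 x 180 mm
    in cross-section and ~240 mm tall, sized to stay inside the default
    detector field of view, with a 20 mm diameter tumor moving 15 mm and
    a diaphragm dome moving 25 mm superior-inferior.
    """
    cfg = dict(config or {})

    def get(name, default):
        return cfg.pop(name, default)

    body = Ellipsoid(tuple(get("body_center", (0.0, 0.0, 0.0))),
                     tuple(get("body_axes", (115.0, 90.0, 120.0))),
                     float(get("body_attenuation", 0.02)))
    lung_att = float(get("lung_attenuation", 0.004))
    lung_r = Ellipsoid(tuple(get("lung_r_center", (-52.0, 0.0, 10.0))),
                       tuple(get("lung_r_axes", (46.0, 60.0, 90.0))),
                       lung_att)
    lung_l = Ellipsoid(tuple(get("lung_l_center", (52.0, 0.0, 10.0))),
                       tuple(get("lung_l_axes", (46.0, 60.0, 90.0))),
                       lung_att)
    tumor = Sphere(tuple(get("tumor_center", (-52.0, 0.0, 40.0))),
                   float(get("tumor_radius", 10.0)),
                   float(get("tumor_attenuation", 0.03)))
    dia = DiaphragmDome(tuple(get("diaphragm_apex", (52.0, 0.0, -40.0))),
                        float(get("diaphragm_radius", 70.0)),
                        float(get("diaphragm_attenuation", 0.025)))
    dia_amp = tuple(get("diaphragm_amplitude_mm", (0.0, 0.0, 25.0)))

    # Vessel-like moving structures give the lungs internal texture whose
    # displacement grades from near-zero at the apex to most of the
    # diaphragm excursion at the base -- the context deformable
    # registration needs to carry motion through otherwise uniform lung.
    n_vessels = int(get("vessel_count", 14))
    v_seed = int(get("vessel_seed", 0))
    v_att = float(get("vessel_attenuation", 0.014))
    rng = np.random.default_rng(v_seed)
    vessels = []
    max_amp = 0.8 * dia_amp[2]
    for lung in (lung_r, lung_l):
        lc = np.asarray(lung.center)
        la = np.asarray(lung.semi_axes)
        placed = 0
        for _ in range(400):
            if placed >= n_vessels:
                break
            r = rng.uniform(2.5, 5.0)
            pos = lc + la * rng.uniform(-0.85, 0.85, 3)
            frac = (lc[2] + la[2] - pos[2]) / (2 * la[2])  # 0 apex, 1 base
            amp = (0.0, 0.0, float(np.clip(frac, 0.05, 1.0) * max_amp))
            ok = True
            for u in (0.0, 1.0):
                p = pos - u * np.asarray(amp)
                d = (p - lc) / (la - r)
                if np.any(la - r <= 0) or d @ d > 1.0:
                    ok = False
                    break
            if ok and np.linalg.norm(
                    pos - np.asarray(tumor.center)) > tumor.radius + r + 18:
                vessels.append(MovingSphere(tuple(pos), float(r), v_att,
                                            amp))
                placed += 1
    model = PhantomModel(
        body, (lung_r, lung_l), tumor, dia,
        tuple(get("tumor_amplitude_mm", (0.0, 0.0, 15.0))),
        dia_amp,
        tuple(vessels),
    )
    if cfg:
        raise ValueError(f"unknown phantom config keys: {sorted(cfg)}")
    return model


def _ellipsoid_alpha(X, Y, Z, center, semi_axes, edge_mm: float) -> np.ndarray:
    """Soft inside-indicator of an ellipsoid: 1 deep inside, 0 outside,
    ramping linearly over ~``edge_mm`` of approximate signed distance."""
    cx, cy, cz = center
    ax, ay, az = semi_axes
    q = np.sqrt(((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2
                + ((Z - cz) / az) ** 2)
    # approximate distance to the surface: (1 - q) * local radius scale
    r_loc = min(ax, ay, az)
    return np.clip(0.5 + (1.0 - q) * r_loc / edge_mm, 0.0, 1.0)


def _sphere_alpha(X, Y, Z, center, radius, edge_mm: float) -> np.ndarray:
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2
                + (Z - center[2]) ** 2)
    return np.clip(0.5 + (radius - r) / edge_mm, 0.0, 1.0)


def phantom_volume(model: PhantomModel, displacement: float,
                   grid: GridSpec, edge_mm: float = 4.0) -> Volume3D:
    """Voxelize the phantom at normalized breathing displacement ``u``.

    Structures are composited back to front (body, lungs, diaphragm dome
    clipped to the lung, vessels, tumor) with partial-volume antialiased
    edges of width ~``edge_mm``: tissue boundaries in real scans are
    never voxel-sharp, and razor edges at desk-scale voxel sizes would
    dominate the reconstruction error with ringing. Deterministic.
    """
    u = float(displacement)
    if not (0.0 <= u <= 1.0):
        raise ValueError("displacement must lie in [0, 1]")
    ax_x, ax_y, ax_z = grid.axes()
    X, Y, Z = np.meshgrid(ax_x, ax_y, ax_z, indexing="ij")

    def paint(vol, alpha, attenuation):
        return vol * (1.0 - alpha) + attenuation * alpha

    vol = np.zeros(grid.shape, np.float64)
    b = model.body
    vol = paint(vol, _ellipsoid_alpha(X, Y, Z, b.center, b.semi_axes,
                                      edge_mm), b.attenuation)
    lung_alphas = []
    for lung in model.lungs:
        a = _ellipsoid_alpha(X, Y, Z, lung.center, lung.semi_axes, edge_mm)
        vol = paint(vol, a, lung.attenuation)
        lung_alphas.append(a)

    apex = model.diaphragm_apex(u)
    R = model.diaphragm.radius
    dome_center = apex - np.array([0.0, 0.0, R])
    dome = _sphere_alpha(X, Y, Z, dome_center, R, edge_mm)
    in_lung = np.maximum(lung_alphas[0], lung_alphas[1])
    vol = paint(vol, dome * in_lung, model.diaphragm.attenuation)

    for ves in model.vessels:
        vc = np.asarray(ves.center, float) - u * np.asarray(ves.amplitude_mm)
        vol = paint(vol, _sphere_alpha(X, Y, Z, vc, ves.radius, edge_mm),
                    ves.attenuation)

    if model.tumor.radius > 0:
        tc = model.tumor_center(u)
        vol = paint(vol, _sphere_alpha(X, Y, Z, tc, model.tumor.radius,
                                       edge_mm), model.tumor.attenuation)
    return Volume3D(vol.astype(np.float32), grid.spacing, grid.origin)
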