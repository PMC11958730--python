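"""Real-time respiratory phase estimation from the surrogate signal.

The phase estimator follows the lag-plot construction: plotting the
surrogate ``y(t)`` against its lagged copy ``y(t - omega)`` traces an
ellipse for quasi-sinusoidal breathing, centred at the baseline of the
signal (so baseline drift moves the ellipse, not the phase). The ellipse
is divided into ``n_bins`` equal angular sectors measured from the major
axis in the traversal direction; the sector currently being traced is the
respiratory phase. Prediction a latency ``tau`` ahead extrapolates the
elliptical angle at the current angular speed.

A subtlety worth stating: the lag-plot point ``(y(t - omega), y(t))``
represents the respiratory state at ``t - omega/2``, not at ``t``. The
streaming predictor therefore advances the angle by
``(tau + omega/2) * angular_speed`` so that its bins line up with phase
defined on the signal itself (peak inhale = start of bin 1). For a pure
sinusoid this alignment is exact.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EllipseFit",
    "PredictorConfig",
    "PhasePredictor",
    "FitError",
    "fit_ellipse",
    "phase_from_point",
]


class FitError(RuntimeError):
    """Raised when no breathing ellipse can be fitted (e.g. flat signal)."""


@dataclass(frozen=True)
class EllipseFit:
    """A fitted lag-plot ellipse.

    ``center`` is (mm, mm) in the (lagged, current) plane, ``semi_axes``
    is (major, minor) with major >= minor, ``orientation`` is the major
    axis angle in [0, pi), and ``fit_residual`` the RMS point-to-ellipse
    distance in mm.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    fit_residual: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy major >= minor > 0")
        if not (0.0 <= self.orientation < np.pi):
            raise ValueError("orientation must lie in [0, pi)")

    def angle_of(self, point: tuple[float, float]) -> float:
        """Elliptical (parametric) angle of a point, radians in [0, 2 pi).

        The point is translated to the center, rotated into the axes
        frame, scaled by the semi-axes and its polar angle taken; points
        off the ellipse are projected by angle only.
        """
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = (dx * c + dy * s) / self.semi_axes[0]
        v = (-dx * s + dy * c) / self.semi_axes[1]
        return float(np.arctan2(v, u) % (2.0 * np.pi))


@dataclass(frozen=True)
class PredictorConfig:
    """Configuration of the streaming phase predictor.

    ``lag_s`` is the lag-plot delay omega, ``latency_s`` the system
    latency tau that predictions must bridge, ``window_s`` the sliding
    fit window, and ``n_bins`` the number of phase sectors.
    """

    lag_s: float = 0.5
    latency_s: float = 0.4
    window_s: float = 10.0
    n_bins: int = 10
    sample_rate_hz: float = 30.0
    speed_window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.lag_s <= 0:
            raise ValueError("lag_s must be positive")
        if self.latency_s < 0:
            raise ValueError("latency_s must be nonnegative")
        if self.window_s <= 2 * self.lag_s:
            raise ValueError("window_s too short for the chosen lag")
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")


def _direct_ellipse_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ellipse-specific direct least-squares conic fit (partitioned
    scatter-matrix formulation). Inputs are expected pre-normalized.
    Returns conic coefficients (A, B, C, D, E, F) with 4AC - B^2 > 0.
    """
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate lag plot: no breathing detected") from exc
    m = s1 + s2 @ t_mat
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    w, v = np.linalg.eig(m)
    cond = 4.0 * v[0] * v[2] - v[1] ** 2
    good = np.nonzero(np.isreal(w) & (cond.real > 0))[0]
    if good.size == 0:
        raise FitError("no ellipse solution: no breathing detected")
    a1 = v[:, good[0]].real
    return np.concatenate([a1, t_mat @ a1])


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Ellipse-constrained direct least-squares conic fit.

    ``points`` is (n, 2) with n >= 6 non-collinear lag-plot samples.
    Points are centered and scaled before fitting for numerical
    stability. Raises :class:`FitError` when the points are degenerate
    (collinear or nearly so) -- the "no breathing detected" condition.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise FitError("need at least 6 (y(t), y(t-omega)) points")
    if not np.all(np.isfinite(pts)):
        raise FitError("non-finite surrogate samples")
    mean = pts.mean(axis=0)
    centered = pts - mean
    # collinearity / degeneracy screen via the principal components
    sing = np.linalg.svd(centered, compute_uv=False)
    if sing[0] <= 0 or sing[1] / sing[0] < 1e-6 or sing[1] < 1e-9:
        raise FitError("lag-plot points are collinear: no breathing detected")
    scale = float(np.sqrt((centered ** 2).sum(axis=1).mean()))
    xn = centered[:, 0] / scale
    yn = centered[:, 1] / scale
    A, B, C, D, E, F = _direct_ellipse_conic(xn, yn)

    # conic -> geometric parameters (still in normalized coordinates)
    mat = np.array([[2 * A, B], [B, 2 * C]])
    try:
        xc_n, yc_n = np.linalg.solve(mat, [-D, -E])
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate conic: no breathing detected") from exc
    f0 = (A * xc_n ** 2 + B * xc_n * yc_n + C * yc_n ** 2
          + D * xc_n + E * yc_n + F)
    lam, vec = np.linalg.eigh(np.array([[A, B / 2.0], [B / 2.0, C]]))
    if np.any(lam * (-f0) <= 0):
        raise FitError("degenerate ellipse: no breathing detected")
    axes_n = np.sqrt(-f0 / lam)
    order = np.argsort(axes_n)[::-1]  # major first
    a_n, b_n = axes_n[order]
    major_vec = vec[:, order[0]]
    theta = float(np.arctan2(major_vec[1], major_vec[0]) % np.pi)

    center = (float(mean[0] + scale * xc_n), float(mean[1] + scale * yc_n))
    a, b = float(scale * a_n), float(scale * b_n)
    if not np.isfinite([*center, a, b, theta]).all() or b <= 0:
        raise FitError("degenerate ellipse: no breathing detected")
    # RMS distance to the ellipse point at the same parametric angle
    c, s = np.cos(theta), np.sin(theta)
    dx, dy = pts[:, 0] - center[0], pts[:, 1] - center[1]
    u = (dx * c + dy * s) / a
    v2 = (-dx * s + dy * c) / b
    ang = np.arctan2(v2, u)
    ex = a * np.cos(ang) * c - b * np.sin(ang) * s + center[0]
    ey = a * np.cos(ang) * s + b * np.sin(ang) * c + center[1]
    residual = float(np.sqrt(np.mean((pts[:, 0] - ex) ** 2
                                     + (pts[:, 1] - ey) ** 2)))
    return EllipseFit(center, (a, b), theta, residual)


def phase_from_point(model: EllipseFit, point: tuple[float, float],
                     direction: int, n_bins: int = 10,
                     angle_offset: float = 0.0) -> int:
    """Respiratory bin of a lag-plot point.

    The elliptical angle is measured from the major-axis direction in the
    traversal ``direction`` (+1 counter-clockwise, -1 clockwise) and the
    circle of ``n_bins`` equal angular sectors is mapped to bins
    ``1..n_bins``. ``angle_offset`` (radians, in the traversal direction)
    lets callers apply the half-lag correction.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    ang = model.angle_of(point)
    ang = (direction * ang + angle_offset) % (2.0 * np.pi)
    return int(ang / (2.0 * np.pi) * n_bins) % n_bins + 1


def _angles(model: EllipseFit, pts: np.ndarray) -> np.ndarray:
    """Vectorized :meth:`EllipseFit.angle_of` over an (n, 2) array."""
    dx = pts[:, 0] - model.center[0]
    dy = pts[:, 1] - model.center[1]
    c, s = np.cos(model.orientation), np.sin(model.orientation)
    u = (dx * c + dy * s) / model.semi_axes[0]
    v = (-dx * s + dy * c) / model.semi_axes[1]
    return np.arctan2(v, u) % (2.0 * np.pi)


class PhasePredictor:
    """Streaming ellipse-fit phase predictor.

    Samples are pushed one at a time with :meth:`push`; the predictor can
    be queried at any time and never looks ahead. It refits the ellipse
    on its sliding window, estimates the angular speed from a robust
    (median) finite difference of the unwrapped angle over the last
    second, and extrapolates the angle across the latency.

    When the fit fails (flat or degenerate signal) the predictor flags
    low confidence and holds the last known bin.
    """

    def __init__(self, cfg: PredictorConfig):
        self.cfg = cfg
        n_keep = int(round(cfg.window_s * cfg.sample_rate_hz)) + 2
        self._t: deque[float] = deque(maxlen=n_keep)
        self._y: deque[float] = deque(maxlen=n_keep)
        self._lag_n = max(1, int(round(cfg.lag_s * cfg.sample_rate_hz)))
        self._refit_every = max(1, int(round(cfg.sample_rate_hz / 30.0)))
        self._since_fit = 10 ** 9
        self.model: EllipseFit | None = None
        self.direction: int = 1
        self.angular_speed: float = 0.0  # rad/s, in traversal direction
        self.confident: bool = False
        self._last_bin: int = 1
        self._last_angle: float | None = None

    # -- streaming interface ------------------------------------------------

    def push(self, t: float, y: float) -> None:
        """Consume one surrogate sample (t seconds, y mm)."""
        self._t.append(float(t))
        self._y.append(float(y))
        self._since_fit += 1
        if (self._since_fit >= self._refit_every
                and len(self._y) > 3 * self._lag_n):
            self._refit()
            self._since_fit = 0

    @property
    def ready(self) -> bool:
        if self.model is None or not self.confident or len(self._t) < 2:
            return False
        span = self._t[-1] - self._t[0]
        return span >= self.cfg.window_s - 2.0 / self.cfg.sample_rate_hz

    def _lag_points(self) -> np.ndarray:
        y = np.asarray(self._y)
        return np.column_stack([y[:-self._lag_n], y[self._lag_n:]])

    def _refit(self) -> None:
        pts = self._lag_points()
        try:
            self.model = fit_ellipse(pts)
        except FitError:
            self.confident = False
            return
        # raw (uncorrected) angles of the trailing samples
        ang = np.unwrap(_angles(self.model, pts))
        n_speed = max(2, int(round(self.cfg.speed_window_s
                                   * self.cfg.sample_rate_hz)))
        tail = ang[-n_speed:]
        d = np.diff(tail)
        if d.size == 0:
            self.confident = False
            return
        step = float(np.median(d))
        self.direction = 1 if step >= 0 else -1
        self.angular_speed = abs(step) * self.cfg.sample_rate_hz
        # average the trailing angles (advanced to the newest sample) to
        # suppress sensor noise on the instantaneous phase estimate
        n_avg = min(5, tail.size)
        trailing = tail[-n_avg:] + step * np.arange(n_avg - 1, -1, -1)
        self._last_angle = float(np.mean(trailing) % (2.0 * np.pi))
        # a plausible breath sweeps the ellipse in 1..20 s
        self.confident = 0.3 < self.angular_speed < 10.0

    # -- queries ------------------------------------------------------------

    def _half_lag_offset(self) -> float:
        return self.angular_speed * self.cfg.lag_s / 2.0

    def current_bin(self) -> int:
        """Phase bin of the most recent sample (half-lag corrected)."""
        return self.predict_bin(horizon_s=0.0)

    def predict_bin(self, horizon_s: float | None = None) -> int:
        """Predicted bin ``horizon_s`` (default: the latency) ahead.

        Falls back to holding the last bin, flagged by ``confident``.
        """
        if horizon_s is None:
            horizon_s = self.cfg.latency_s
        if not self.ready or self._last_angle is None:
            return self._last_bin
        extra = self.angular_speed * horizon_s + self._half_lag_offset()
        ang = (self.direction * self._last_angle + extra) % (2.0 * np.pi)
        b = int(ang / (2.0 * np.pi) * self.cfg.n_bins) % self.cfg.n_bins + 1
        self._last_bin = b
        return b

    def predict_value(self, horizon_s: float | None = None) -> float:
        """Predicted surrogate value (mm) ``horizon_s`` ahead.

        Evaluates the fitted ellipse at the extrapolated *raw* angle; the
        y-coordinate of the lag plot is the current signal value.
        """
        if horizon_s is None:
            horizon_s = self.cfg.latency_s
        if not self.ready or self._last_angle is None:
            return self._y[-1] if self._y else 0.0
        m = self.model
        ang = self._last_angle + self.direction * self.angular_speed * horizon_s
        c, s = np.cos(m.orientation), np.sin(m.orientation)
        u = m.semi_axes[0] * np.cos(ang)
        v = m.semi_axes[1] * np.sin(ang)
        return float(m.center[1] + u * s + v * c)

    def time_to_bin(self, target_bin: int, horizon_s: float = 0.0) -> float:
        """Seconds until the *start* of ``target_bin`` is reached,
        measured from ``horizon_s`` ahead of the latest sample.

        Returns 0.0 if the target bin is already active at the horizon.
        Requires a confident fit.
        """
        if not self.ready or self._last_angle is None:
            raise FitError("predictor not ready")
        nb = self.cfg.n_bins
        extra = self.angular_speed * horizon_s + self._half_lag_offset()
        ang = (self.direction * self._last_angle + extra) % (2.0 * np.pi)
        cur_frac = ang / (2.0 * np.pi)
        cur_bin = int(cur_frac * nb) % nb + 1
        if cur_bin == target_bin:
            return 0.0
        start_frac = ((target_bin - 1) / nb)
        delta = (start_frac - cur_frac) % 1.0
        if self.angular_speed <= 0:
            raise FitError("angular speed unavailable")
        return float(delta * 2.0 * np.pi / self.angular_speed)

    def period_estimate(self) -> float:
        """Current breath-period estimate in seconds."""
        if self.angular_speed <= 0:
            raise FitError("angular speed unavailable")
        return float(2.0 * np.pi / self.angular_speed)
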