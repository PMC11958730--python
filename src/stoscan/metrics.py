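"""Schedule-structure and image-quality metrics.

Implementation accuracy of the acquisition is quantified against the
ideal schedule (mean absolute angular error, per-bin angular gaps, dose
reduction as the relative projection count). Image quality uses the
contrast-to-noise ratio between lung and diaphragm regions and the
tissue-interface width (TIW): the mean 10-90% width of logistic sigmoids
fitted across an anatomical edge, a proxy for how accurately motion was
resolved (uncompensated motion manifests as edge blur under filtered
backprojection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import curve_fit

from stoscan.control import AcquisitionSchedule
from stoscan.grids import Volume3D

__all__ = [
    "MetricsReport",
    "TIWProbe",
    "schedule_mae",
    "interbin_separation",
    "cnr",
    "tiw",
    "dose_reduction",
    "motion_robustness",
]


@dataclass
class MetricsReport:
    """Bundle of the quantities reported for one scan."""

    mae_deg: float | None = None
    interbin_separation_deg: dict[int, list[float]] = field(
        default_factory=dict)
    cnr: float | None = None
    tiw_mm: dict[str, float] = field(default_factory=dict)
    dose_reduction_percent: float | None = None
    robustness: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        vals = [self.mae_deg, self.cnr, self.dose_reduction_percent]
        vals += list(self.tiw_mm.values()) + list(self.robustness.values())
        for gaps in self.interbin_separation_deg.values():
            vals += list(gaps)
        for v in vals:
            if v is not None and not np.isfinite(v):
                raise ValueError("metrics report contains non-finite values")
        for w in self.tiw_mm.values():
            if w < 0:
                raise ValueError("TIW must be nonnegative")
        if self.dose_reduction_percent is not None and not (
                0 <= self.dose_reduction_percent <= 100):
            raise ValueError("dose reduction must lie in [0, 100] percent")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interbin_separation_deg"] = {
            str(k): list(map(float, v))
            for k, v in self.interbin_separation_deg.items()}
        return d


def schedule_mae(acquired: AcquisitionSchedule,
                 ideal: AcquisitionSchedule) -> float:
    """Mean absolute angular deviation of the realized schedule from the
    ideal one, matched by projection index, in degrees."""
    a = acquired.angles_deg[acquired.acquired]
    b = ideal.angles_deg[ideal.acquired]
    if a.size != b.size:
        raise ValueError(
            f"schedule length mismatch: {a.size} acquired vs {b.size} ideal")
    return float(np.mean(np.abs(a - b)))


def interbin_separation(schedule: AcquisitionSchedule) -> dict[int, list[float]]:
    """Sorted consecutive angular gaps among each bin's projections."""
    out: dict[int, list[float]] = {}
    ang = schedule.angles_deg[schedule.acquired]
    bins = schedule.bins[schedule.acquired]
    if ang.size < 2:
        raise ValueError("need at least two projections")
    for j in sorted(set(int(b) for b in bins)):
        a = np.sort(ang[bins == j])
        out[j] = list(np.diff(a)) if a.size > 1 else []
    return out


def cnr(volume: Volume3D, roi_lung: np.ndarray,
        roi_diaphragm: np.ndarray) -> float:
    """Contrast-to-noise ratio ``(mu_lung - mu_diaphragm) / sigma`` with
    ``sigma`` the standard deviation of the pooled voxels of both ROIs."""
    roi_lung = np.asarray(roi_lung, bool)
    roi_diaphragm = np.asarray(roi_diaphragm, bool)
    if not roi_lung.any() or not roi_diaphragm.any():
        raise ValueError("both ROIs must be nonempty")
    if (roi_lung & roi_diaphragm).any():
        raise ValueError("ROIs must be disjoint")
    v = volume.voxels
    lung = v[roi_lung].astype(np.float64)
    dia = v[roi_diaphragm].astype(np.float64)
    sigma = float(np.concatenate([lung, dia]).std())
    if sigma == 0:
        return 0.0
    return float((lung.mean() - dia.mean()) / sigma)


@dataclass(frozen=True)
class TIWProbe:
    """Axis-aligned probe box at a tissue interface.

    ``center_index`` is the voxel index of the box center, ``axis`` the
    axis (0..2) along which the runs cross the interface, ``n_perp`` the
    runs per transverse direction and ``n_along`` the run length in
    voxels (default 5 x 5 x 60)."""

    center_index: tuple[int, int, int]
    axis: int = 2
    n_perp: int = 5
    n_along: int = 60


def _logistic(x, lo, hi, x0, s):
    return lo + (hi - lo) / (1.0 + np.exp(-(x - x0) / s))


def _fit_run(run: np.ndarray) -> float | None:
    """10-90% width (in voxels) of a 4-parameter logistic fitted to one
    run, or None when the run does not present a coherent edge."""
    n = run.size
    x = np.arange(n, dtype=float)
    rng_ = float(run.max() - run.min())
    if rng_ <= 0:
        return None
    p0 = [float(run[:3].mean()), float(run[-3:].mean()), n / 2.0, 2.0]
    try:
        popt, _ = curve_fit(
            _logistic, x, run.astype(np.float64), p0=p0,
            bounds=([-np.inf, -np.inf, -n, 0.05],
                    [np.inf, np.inf, 2 * n, n]), maxfev=2000)
    except (RuntimeError, ValueError):
        return None
    lo, hi, x0, s = popt
    resid = run - _logistic(x, *popt)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((run - run.mean()) ** 2).sum())
    if ss_tot > 0 and 1.0 - ss_res / ss_tot < 0.5:
        return None
    if abs(hi - lo) < 0.25 * rng_:
        return None
    width = float(np.log(81.0) * s)
    if width > n:
        return None
    return width


def tiw(volume: Volume3D, probe: TIWProbe) -> tuple[float, int]:
    """Tissue-interface width at a probe, in mm.

    Extracts ``n_perp^2`` runs of ``n_along`` voxels along the probe
    axis, fits a logistic sigmoid to each, and averages the 10-90% widths
    of the successful fits. Returns ``(tiw_mm, n_failed)``; raises when
    more than half the runs fail to present a coherent interface.
    """
    ax = probe.axis
    if ax not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    shape = volume.voxels.shape
    half_a = probe.n_along // 2
    half_p = probe.n_perp // 2
    c = probe.center_index
    lo = [0, 0, 0]
    hi = [0, 0, 0]
    for i in range(3):
        h = half_a if i == ax else half_p
        n = probe.n_along if i == ax else probe.n_perp
        lo[i] = c[i] - h
        hi[i] = lo[i] + n
        if lo[i] < 0 or hi[i] > shape[i]:
            raise ValueError("probe box extends outside the volume")
    box = volume.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    box = np.moveaxis(box, ax, -1).reshape(-1, probe.n_along)

    widths = []
    n_failed = 0
    for run in box:
        w = _fit_run(run)
        if w is None:
            n_failed += 1
        else:
            widths.append(w)
    if n_failed > box.shape[0] // 2:
        raise ValueError(
            f"no coherent interface: {n_failed} of {box.shape[0]} "
            "sigmoid fits failed")
    return float(np.mean(widths) * volume.spacing[ax]), n_failed


def dose_reduction(n_p: int, n_p_ref: int) -> float:
    """Percentage reduction in acquired projections relative to a
    reference scan -- the leading-order imaging-dose reduction at fixed
    per-projection exposure."""
    if n_p_ref <= 0:
        raise ValueError("reference projection count must be positive")
    return 100.0 * (1.0 - n_p / n_p_ref)


def motion_robustness(mc_image: Volume3D, reference_image: Volume3D,
                      tumor_mask: np.ndarray, cfg=None,
                      dvf=None) -> dict[str, float]:
    """Consistency of tumor position between a motion-compensated image
    and a non-compensated reference.

    Registers ``mc_image`` to ``reference_image`` (same engine as the
    adaptive chain) and summarizes the displacement field over the tumor
    mask: per-axis mean and standard deviation plus the mean/std of the
    total displacement magnitude, all in mm. A precomputed ``dvf`` may be
    supplied; the statistics are computed over the mask only.
    """
    tumor_mask = np.asarray(tumor_mask, bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    if mc_image.voxels.shape != reference_image.voxels.shape:
        raise ValueError("images must share a grid")
    if dvf is None:
        from stoscan.adaptive import register_deformable
        dvf = register_deformable(mc_image, reference_image, cfg)
    vec = dvf.vectors[tumor_mask]
    mag = np.sqrt((vec ** 2).sum(axis=1))
    axes = "xyz"
    out: dict[str, float] = {}
    for i, a in enumerate(axes):
        out[f"mean_{a}_mm"] = float(vec[:, i].mean())
        out[f"std_{a}_mm"] = float(vec[:, i].std())
    out["mean_total_mm"] = float(mag.mean())
    out["std_total_mm"] = float(mag.std())
    return out
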