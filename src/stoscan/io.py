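"""File formats: volumes (NIfTI, MHA on read), projection stacks
(raw float32 + JSON sidecar), schedules and breathing traces (CSV).

All round trips are lossless: voxel/stack bytes are preserved bit for
bit and per-projection metadata is serialized through JSON, whose float
text representation round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from stoscan.control import AcquisitionSchedule
from stoscan.grids import ProjectionSet, ScanGeometry, Volume3D
from stoscan.phantom import BreathingTrace, TraceParams

__all__ = [
    "write_volume", "read_volume",
    "write_dvf", "read_dvf",
    "write_image4d", "read_image4d",
    "write_projections", "read_projections",
    "write_schedule", "read_schedule",
    "write_trace", "read_trace",
]


def write_volume(path: str | Path, volume: Volume3D) -> Path:
    """Write a volume as NIfTI; the affine carries spacing and origin."""
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine),
             str(path))
    return path


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI or MHA/MHD volume."""
    path = Path(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        vox = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return Volume3D(vox, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return Volume3D(np.asarray(img.dataobj, dtype=np.float32), spacing,
                    origin)


def write_dvf(path: str | Path, dvf) -> Path:
    """Write a displacement field as a 4D NIfTI (x, y, z, component)."""
    path = Path(path)
    affine = np.diag([*dvf.spacing, 1.0])
    affine[:3, 3] = dvf.origin
    nib.save(nib.Nifti1Image(dvf.vectors.astype(np.float32), affine),
             str(path))
    return path


def read_dvf(path: str | Path):
    from stoscan.adaptive import DVF

    img = nib.load(str(path))
    aff = img.affine
    return DVF(np.asarray(img.dataobj, dtype=np.float64),
               tuple(float(aff[i, i]) for i in range(3)),
               tuple(float(aff[i, 3]) for i in range(3)))


def write_image4d(directory: str | Path, image, prefix: str = "bin") -> Path:
    """Write a 4D image as one NIfTI per frame plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for j, frame in zip(image.bins, image.frames):
        name = f"{prefix}{j:02d}.nii.gz"
        write_volume(directory / name, frame)
        files[str(j)] = name
    (directory / "index.json").write_text(json.dumps(
        {"bins": files, "prefix": prefix}, indent=1))
    return directory


def read_image4d(directory: str | Path):
    from stoscan.grids import Image4D

    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    bins = sorted(int(b) for b in index["bins"])
    frames = [read_volume(directory / index["bins"][str(b)]) for b in bins]
    return Image4D(frames, bins)


_SIDE_FIELDS = ("angles_deg", "times_s", "bins")


def write_projections(path: str | Path, proj: ProjectionSet) -> Path:
    """Write a projection set: ``<path>.raw`` (float32, C-order) plus a
    ``<path>.json`` sidecar with geometry and per-projection metadata."""
    base = Path(path)
    raw = base.with_suffix(".raw")
    proj.stack.astype(np.float32).tofile(raw)
    g = proj.geometry
    side = {
        "shape": list(proj.stack.shape),
        "dtype": "float32",
        "geometry": {"sad": g.sad, "sdd": g.sdd, "det_rows": g.det_rows,
                     "det_cols": g.det_cols, "pixel_pitch": g.pixel_pitch,
                     "arc_deg": g.arc_deg},
        "angles_deg": [float(a) for a in proj.angles_deg],
        "times_s": [None if not np.isfinite(t) else float(t)
                    for t in proj.times_s],
        "bins": [int(b) for b in proj.bins],
    }
    base.with_suffix(".json").write_text(json.dumps(side, indent=1))
    return raw


def read_projections(path: str | Path) -> ProjectionSet:
    base = Path(path)
    side_path = base.with_suffix(".json")
    side = json.loads(side_path.read_text())
    for f in ("shape", "geometry") + _SIDE_FIELDS:
        if f not in side:
            raise ValueError(f"projection sidecar missing field '{f}'")
    geo = ScanGeometry(**side["geometry"])
    stack = np.fromfile(base.with_suffix(".raw"), dtype=np.float32)
    stack = stack.reshape(side["shape"])
    times = np.array([np.nan if t is None else t for t in side["times_s"]])
    return ProjectionSet(stack, np.asarray(side["angles_deg"]), geo, times,
                         np.asarray(side["bins"], np.int64))


def write_schedule(path: str | Path, schedule: AcquisitionSchedule) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "k": schedule.k,
        "t_s": schedule.times_s,
        "angle_deg": schedule.angles_deg,
        "bin": schedule.bins,
        "acquired": schedule.acquired.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_schedule(path: str | Path, provenance: str = "simulated",
                  n_bins: int = 10) -> AcquisitionSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"k", "t_s", "angle_deg", "bin", "acquired"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
    return AcquisitionSchedule(
        df["k"].to_numpy(), df["t_s"].to_numpy(),
        df["angle_deg"].to_numpy(), df["bin"].to_numpy(),
        df["acquired"].to_numpy().astype(bool), provenance, n_bins)


def write_trace(path: str | Path, trace: BreathingTrace) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": trace.times,
        "amplitude_mm": trace.amplitude,
        "phase_bin": trace.true_phase,
        "displacement_u": trace.displacement,
    }).to_csv(path, index=False, float_format="%.17g")
    return path


def read_trace(path: str | Path,
               params: TraceParams | None = None) -> BreathingTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"time_s", "amplitude_mm", "phase_bin"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    y = df["amplitude_mm"].to_numpy()
    if "displacement_u" in df.columns:
        u = df["displacement_u"].to_numpy()
    else:
        span = np.percentile(y, 98) - np.percentile(y, 2)
        u = np.clip((y - np.percentile(y, 2)) / max(span, 1e-9), 0, 1)
    return BreathingTrace(df["time_s"].to_numpy(), y,
                          df["phase_bin"].to_numpy(), u,
                          params or TraceParams())
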