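"""NIfTI-1 and sidecar-table input/output for phantom studies and results.

One subject is stored as a single 4D NIfTI file (baseline as volume 0,
then the dynamic frames) plus a per-study sidecar CSV listing subject ids,
groups, acquisition times and — for simulated studies — the ground-truth
parameters.  The affine encodes the voxel size and origin so physical
coordinates survive the round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageSeries, VoxelGrid

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_study",
    "read_study",
    "write_provenance",
]

SIDECAR_NAME = "study.csv"


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size
    aff[:3, 3] = grid.origin
    return aff


def write_image_series(series: ImageSeries, path: Path) -> Path:
    """Write one subject as a 4D NIfTI (baseline first, then frames)."""
    path = Path(path)
    data = np.concatenate([series.baseline[None], series.frames], axis=0)
    # NIfTI stores (x, y, z, t)
    img = nib.Nifti1Image(np.moveaxis(data, 0, -1), _affine(series.grid))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_image_series(
    path: Path, times_h, subject_id: str = "subject", group: str = "custom"
) -> ImageSeries:
    """Read a 4D NIfTI written by :func:`write_image_series`."""
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    aff = img.affine
    grid = VoxelGrid(
        shape=tuple(int(n) for n in data.shape[1:]),
        voxel_size=tuple(float(aff[i, i]) for i in range(3)),
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    times_h = np.asarray(times_h, dtype=float)
    if data.shape[0] != times_h.size + 1:
        raise ValueError(
            f"{path}: expected {times_h.size + 1} volumes (baseline + frames), "
            f"got {data.shape[0]}"
        )
    return ImageSeries(
        grid=grid,
        baseline=data[0],
        frames=data[1:],
        times=times_h,
        subject_id=subject_id,
        group=group,
    )


def write_study(
    series_list: list[ImageSeries], truth: pd.DataFrame | None, out_dir: Path
) -> Path:
    """Write a whole study: one NIfTI per subject plus the sidecar CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series_list:
        fname = f"{s.subject_id}.nii"
        write_image_series(s, out_dir / fname)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "file": fname,
                "times_h": ";".join(f"{t:g}" for t in s.times),
            }
        )
    sidecar = pd.DataFrame(rows)
    if truth is not None:
        sidecar = sidecar.merge(truth, on=["subject_id", "group"], how="left")
    sidecar.to_csv(out_dir / SIDECAR_NAME, index=False)
    return out_dir / SIDECAR_NAME


def read_study(in_dir: Path) -> tuple[list[ImageSeries], pd.DataFrame]:
    """Read a study directory written by :func:`write_study`."""
    in_dir = Path(in_dir)
    sidecar = pd.read_csv(in_dir / SIDECAR_NAME)
    series = []
    for _, row in sidecar.iterrows():
        times = np.array([float(t) for t in str(row["times_h"]).split(";")])
        series.append(
            read_image_series(
                in_dir / row["file"], times, subject_id=row["subject_id"], group=row["group"]
            )
        )
    return series, sidecar


def write_provenance(path: Path, **fields) -> Path:
    """Write a provenance JSON (tool version, config hash, seed, ...)."""
    from . import __version__

    path = Path(path)
    payload = {"tool": "issmri", "version": __version__, **fields}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
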