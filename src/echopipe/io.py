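"""Readers and writers for the pipeline's on-disk formats.

NIfTI-1 for volumes (via nibabel; data and affine stored at the
header's float32 precision), key=value sidecar text for echo metadata,
FSL-style 3-column
event files plus a tab-separated master trial table, and two-column
(time, value) text logs for physiological traces and the 6-column motion
parameter trace.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .physio import PhysioTrace
from .relaxometry import CombinedSeries, EchoSeries

__all__ = [
    "read_nifti_series",
    "write_nifti",
    "write_echo",
    "read_echo",
    "write_events",
    "read_events",
    "write_physio_log",
    "read_physio_log",
    "write_motion",
    "read_motion",
]


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write an array as float32 NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_nifti_series(path: str | Path, expect_4d: bool = True):
    """Load a NIfTI file, returning ``(data float64, affine)``.

    Raises a descriptive error for missing files, unreadable headers, or
    a 3D image where a 4D series is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if expect_4d and data.ndim != 4:
        raise ValueError(
            f"{path} is {data.ndim}D with shape {data.shape}; a 4D time "
            "series (x, y, z, t) is required"
        )
    return data, np.asarray(img.affine, dtype=np.float64)


def _sidecar_path(nii_path: Path) -> Path:
    stem = nii_path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return nii_path.with_name(stem + "_meta.txt")


def write_echo(echo: EchoSeries, path: str | Path) -> Path:
    """Write one echo as NIfTI plus a key=value metadata sidecar."""
    path = Path(path)
    write_nifti(echo.data, echo.affine, path)
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"te_ms={echo.te}\n")
        fh.write(f"tr_ms={echo.tr}\n")
    return path


def read_echo(path: str | Path, mask: np.ndarray | None = None) -> EchoSeries:
    """Read one echo NIfTI and its metadata sidecar."""
    path = Path(path)
    data, affine = read_nifti_series(path)
    meta = {}
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing echo metadata sidecar: {sidecar}")
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = float(v)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return EchoSeries(
        data=data, te=meta["te_ms"], tr=meta["tr_ms"], mask=mask, affine=affine
    )


def write_series(series: CombinedSeries, path: str | Path) -> Path:
    return write_nifti(series.data, series.affine, path)


EVENT_COLUMNS = ["onset", "condition", "cue", "rt", "correct"]


def write_events(events: pd.DataFrame, outdir: str | Path,
                 target_duration_s: float = 1.55) -> Path:
    """Write FSL-style 3-column files per condition x cue cell plus a
    master tab-separated trial table ``trials.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cond in sorted(events["condition"].unique()):
        for cue in sorted(events["cue"].unique()):
            sel = events[(events["condition"] == cond) & (events["cue"] == cue)]
            if len(sel) == 0:
                continue
            arr = np.column_stack(
                [
                    sel["onset"].to_numpy(float) + 0.55,
                    np.full(len(sel), target_duration_s),
                    np.ones(len(sel)),
                ]
            )
            np.savetxt(outdir / f"{cond}_{cue}.txt", arr, fmt="%.4f")
    events.to_csv(outdir / "trials.tsv", sep="\t", index=False)
    return outdir


def read_events(path: str | Path) -> pd.DataFrame:
    """Read the master trial table (``trials.tsv`` inside a directory, or a
    TSV path directly)."""
    path = Path(path)
    if path.is_dir():
        path = path / "trials.tsv"
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "condition", "cue") if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing columns {missing}")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    return df


def write_physio_log(trace: PhysioTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.column_stack([trace.time, trace.value]), fmt="%.6f")
    return path


def read_physio_log(path: str | Path, modality: str,
                    sampling_rate: float | None = None) -> PhysioTrace:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"physio log {path} must have two columns (time, value)")
    t, v = arr[:, 0], arr[:, 1]
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return PhysioTrace(time=t, value=v, modality=modality, sampling_rate=sampling_rate)


def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(motion, float), fmt="%.8f")
    return path


def read_motion(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion trace {path} must have 6 columns")
    return arr
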