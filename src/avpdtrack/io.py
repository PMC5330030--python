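"""Readers/writers for cine series, landmarks, curves, and parameter files.

The canonical interchange for a single-view cine is a multi-page TIFF
(one page per timeframe) plus a JSON sidecar carrying the acquisition
metadata the algorithm needs: pixel spacing (mm), cardiac-cycle
duration (ms), frame count, and the view label.  Landmarks, tracking
parameters and result summaries are plain JSON; displacement curves are
CSV.  A multi-frame DICOM reader is available when pydicom is
installed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from avpdtrack.geometry import Landmark

SIDECAR_FIELDS = ("pixel_spacing_mm", "cycle_duration_ms", "n_frames", "view")


@dataclass
class CineSeries:
    """One long-axis view's image stack over the cardiac cycle.

    ``frames`` is ``(n_frames, n_rows, n_cols)``; frame 0 is end
    diastole under retrospective gating.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]  # mm per pixel, (row, col)
    cycle_duration: float  # ms
    view: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("image stack contains non-finite intensities")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive (ms)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_duration(self) -> float:
        """Temporal spacing between frames in ms."""
        return self.cycle_duration / self.n_frames


def file_checksum(path: str | Path) -> str:
    """sha256 of a file, for embedding input provenance in outputs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def write_series(series: CineSeries, path: str | Path) -> Path:
    """Write a cine as multi-page TIFF + JSON sidecar; returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(path, series.frames.astype(np.float32))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "pixel_spacing_mm": list(series.pixel_spacing),
        "cycle_duration_ms": series.cycle_duration,
        "n_frames": series.n_frames,
        "view": series.view,
    }))
    return sidecar


def read_series(path: str | Path, sidecar: str | Path | None = None) -> CineSeries:
    """Read a cine from a multi-page TIFF and its JSON sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for fld in SIDECAR_FIELDS:
        if fld not in meta:
            raise ValueError(f"{sidecar}: missing required metadata field {fld!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != int(meta["n_frames"]):
        raise ValueError(
            f"{path}: {frames.shape[0]} frames on disk but sidecar declares {meta['n_frames']}"
        )
    return CineSeries(
        frames=frames,
        pixel_spacing=tuple(float(v) for v in meta["pixel_spacing_mm"]),
        cycle_duration=float(meta["cycle_duration_ms"]),
        view=str(meta["view"]),
    )


def read_series_dicom(path: str | Path, view: str = "") -> CineSeries:
    """Read a multi-frame cine DICOM (optional pydicom dependency).

    Pixel spacing is taken from the PixelSpacing tag (row, col mm) and
    the cycle duration from FrameTime * NumberOfFrames.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    frames = ds.pixel_array.astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{path}: DICOM lacks PixelSpacing")
    frame_time = getattr(ds, "FrameTime", None)
    if frame_time is None:
        raise ValueError(f"{path}: DICOM lacks FrameTime")
    return CineSeries(
        frames=frames,
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        cycle_duration=float(frame_time) * frames.shape[0],
        view=view or str(getattr(ds, "SeriesDescription", "")),
    )


# -- landmarks -------------------------------------------------------------

def write_landmarks(landmarks: Iterable[Landmark], path: str | Path) -> None:
    Path(path).write_text(json.dumps([
        {"view": lm.view, "label": lm.label,
         "row": lm.position[0], "col": lm.position[1], "frame": lm.frame}
        for lm in landmarks
    ]))


def read_landmarks(path: str | Path) -> list[Landmark]:
    return [
        Landmark(view=d["view"], label=d["label"],
                 position=(float(d["row"]), float(d["col"])), frame=int(d.get("frame", 0)))
        for d in json.loads(Path(path).read_text())
    ]


# -- curves ----------------------------------------------------------------

def write_curves(curves: Mapping[str, "np.ndarray"], path: str | Path,
                 cycle_duration: float | None = None) -> None:
    """Write per-landmark displacement curves as CSV (one column per landmark)."""
    df = pd.DataFrame({key: np.asarray(vals).ravel() for key, vals in curves.items()})
    df.insert(0, "frame", np.arange(len(df)))
    if cycle_duration is not None:
        df.insert(1, "time_ms", df["frame"] * cycle_duration / len(df))
    df.to_csv(path, index=False)


def read_curves(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {col: df[col].to_numpy(dtype=float)
            for col in df.columns if col not in ("frame", "time_ms")}


# -- training curve matrices ----------------------------------------------

def write_training_csv(matrices: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-landmark training curves: one row per (landmark, subject)."""
    frames = {mat.shape[1] for mat in matrices.values() if mat.size}
    if len(frames) > 1:
        raise ValueError("all training matrices must share one frame count")
    rows = []
    for key in sorted(matrices):
        for i, curve in enumerate(np.atleast_2d(matrices[key])):
            rows.append({"landmark": key, "subject": i,
                         **{f"f{j:02d}": v for j, v in enumerate(curve)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_training_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    frame_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    frame_cols.sort(key=lambda c: int(c[1:]))
    if not frame_cols or "landmark" not in df.columns:
        raise ValueError(f"{path}: not a training-curve CSV")
    return {
        str(key): grp.sort_values("subject")[frame_cols].to_numpy(dtype=float)
        for key, grp in df.groupby("landmark")
    }


# -- tracking parameter files ---------------------------------------------

def write_params(params: Mapping[str, "object"], path: str | Path,
                 extra: Mapping | None = None) -> None:
    from avpdtrack.tracking import TrackingParams

    doc: dict = {"format": "avpdtrack-params", **(extra or {})}
    doc["landmarks"] = {
        key: {"roi_size_mm": p.roi_size_mm, "ros_size_mm": p.ros_size_mm,
              "subpixel": p.subpixel}
        for key, p in params.items()
        if isinstance(p, TrackingParams)
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_params(path: str | Path) -> dict[str, "object"]:
    from avpdtrack.tracking import TrackingParams

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "avpdtrack-params":
        raise ValueError(f"{path}: not a tracking-parameter file")
    return {
        key: TrackingParams(roi_size_mm=float(d["roi_size_mm"]),
                            ros_size_mm=float(d["ros_size_mm"]),
                            subpixel=bool(d.get("subpixel", False)))
        for key, d in doc["landmarks"].items()
    }
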