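"""File formats: multi-page TIFF movies, CSV traces/events/results, JSON bundles.

CSV dialect is comma-separated UTF-8 with a header row and '.' decimals.
TIFF movies are 16-bit unsigned multi-page with ImageJ-style metadata
(frame interval in seconds, pixel size in um); reading fails loudly when
calibration is absent from both the file and the caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._errors import CalibrationError, DataError
from .trace_ops import FluorescenceTrace, MovieStack, SparkletEvent

__all__ = [
    "read_movie",
    "write_movie",
    "read_trace_csv",
    "write_trace_csv",
    "write_events_csv",
    "write_sites_csv",
    "write_json",
]


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a 16-bit ImageJ-compatible multi-page TIFF."""
    path = Path(path)
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    metadata = {"finterval": 1.0 / movie.frame_rate, "unit": "um", "axes": "TYX"}
    kwargs = {}
    if movie.pixel_size:
        ppu = 1.0 / movie.pixel_size  # pixels per micron
        kwargs["resolution"] = (ppu, ppu)
    tifffile.imwrite(path, data, imagej=True, metadata=metadata, **kwargs)
    return path


def read_movie(
    path: str | Path,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> MovieStack:
    """Read a TIFF stack; calibration from ImageJ metadata or the caller."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        finterval = meta.get("finterval")
        if finterval:
            frame_rate = 1.0 / float(finterval)
        if pixel_size is None:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
    if data.ndim == 2:
        data = data[None]
    if frame_rate is None:
        raise CalibrationError(
            f"{path}: no frame-interval metadata and no frame_rate given; refusing to guess"
        )
    return MovieStack(data, frame_rate, pixel_size)


def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "f_over_f0": trace.values}).to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path, frame_rate: float | None = None) -> FluorescenceTrace:
    """Read a (time_s, f_over_f0) CSV; frame rate inferred from time spacing."""
    df = pd.read_csv(path)
    if "f_over_f0" not in df.columns:
        raise DataError(f"{path}: expected a 'f_over_f0' column, got {list(df.columns)}")
    if frame_rate is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise CalibrationError(f"{path}: cannot infer frame rate; pass frame_rate")
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        if dt <= 0:
            raise DataError(f"{path}: non-increasing time column")
        frame_rate = 1.0 / dt
    return FluorescenceTrace(df["f_over_f0"].to_numpy(dtype=float), frame_rate)


def write_events_csv(
    events: list[SparkletEvent], frame_rate: float, path: str | Path
) -> Path:
    path = Path(path)
    rows = [
        {
            "start_s": ev.start_frame / frame_rate,
            "peak_s": ev.peak_frame / frame_rate,
            "end_s": ev.end_frame / frame_rate,
            "amplitude": ev.peak_amplitude,
            "auc": ev.auc,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["start_s", "peak_s", "end_s", "amplitude", "auc"]).to_csv(
        path, index=False
    )
    return path


def write_sites_csv(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    cols = ["site_id", "npo", "q_hat", "n_levels", "t_total_s", "n_events", "total_auc"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
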