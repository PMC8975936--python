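"""Readers and writers for the toolkit's file formats.

TIFF stacks or frame directories for video, headered CSV for traces and
dose-response tables, YAML for stimulus protocols (with unit normalization:
millisecond durations and mW/mm² intensities are converted to seconds and
µW/mm² on load), JSON for fit results.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ValidationError
from .flowcore import FlowField, FrameStack, MotionTrace
from .traces import StimulusEvent, StimulusProtocol

__all__ = [
    "read_stack",
    "read_trace",
    "write_trace",
    "write_flow_field",
    "load_protocol",
]

_FRAME_EXTS = (".tif", ".tiff", ".png")


def _to_gray(frame: np.ndarray) -> np.ndarray:
    # acquisition cameras are monochrome; RGB only occurs in synthetic fixtures
    if frame.ndim == 3:
        return frame.mean(axis=-1)
    if frame.ndim != 2:
        raise ValidationError(f"unsupported frame dimensionality {frame.ndim}")
    return frame


def read_stack(path: str | os.PathLike, fps: float) -> FrameStack:
    """Load a multi-page TIFF or a lexicographically ordered frame directory.

    Pixel values are kept as stored (16-bit data is not rescaled); RGB
    frames are reduced to grayscale by channel mean.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTS)
        if len(files) < 2:
            raise ValidationError(f"frame directory {p} holds fewer than 2 frames")
        frames = [_to_gray(np.asarray(iio.imread(f))) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValidationError(f"inconsistent frame shapes in {p}: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        arr = np.asarray(tifffile.imread(p))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:  # pages x H x W x channels
            arr = arr.mean(axis=-1)
    return FrameStack(frames=arr.astype(float), frame_interval_s=1.0 / fps)


def write_trace(trace: MotionTrace, path: str | os.PathLike,
                value_header: str = "v_px_per_frame") -> None:
    """Write a trace as locale-independent CSV with a ``time_s,...`` header."""
    pd.DataFrame({"time_s": trace.t, value_header: trace.v}).to_csv(path, index=False)


def read_trace(path: str | os.PathLike) -> MotionTrace:
    """Read a headered ``time_s,<value>`` CSV; rejects NaN cells."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValidationError("trace CSV must have a 'time_s' column plus one value column")
    value_col = [c for c in df.columns if c != "time_s"][0]
    if df.isna().any().any():
        raise ValidationError("trace CSV contains NaN cells")
    return MotionTrace(t=df["time_s"].to_numpy(float), v=df[value_col].to_numpy(float))


def write_flow_field(field: FlowField, stem: str | os.PathLike) -> tuple[Path, Path]:
    """Export a flow field as paired 32-bit TIFFs ``<stem>_dx.tif``/``_dy.tif``."""
    stem = Path(stem)
    px, py = stem.with_name(stem.name + "_dx.tif"), stem.with_name(stem.name + "_dy.tif")
    tifffile.imwrite(px, field.dx.astype(np.float32))
    tifffile.imwrite(py, field.dy.astype(np.float32))
    return px, py


_TIME_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(ms|s)?\s*$")
_INT_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([mµu]W)\s*/\s*mm\^?2\s*$")


def _parse_time_s(value) -> float:
    """Accept a number (seconds) or a '<num> ms|s' string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _TIME_RE.match(str(value))
    if not m:
        raise ValidationError(f"cannot parse time value {value!r}")
    x = float(m.group(1))
    return x / 1000.0 if m.group(2) == "ms" else x


def _parse_intensity_uw(value) -> float:
    """Accept a number (µW/mm²) or a '<num> mW/mm^2'-style string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _INT_RE.match(str(value))
    if not m:
        raise ValidationError(f"cannot parse intensity value {value!r}")
    x = float(m.group(1))
    return x * 1000.0 if m.group(2) == "mW" else x


def load_protocol(path: str | os.PathLike) -> StimulusProtocol:
    """Load a YAML stimulus protocol, normalizing units and sorting events.

    Expected structure::

        events:
          - {t_on: 10, duration: "100 ms", kind: light,
             wavelength_nm: 385, intensity: "1 mW/mm^2"}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "events" not in doc:
        raise ValidationError("protocol YAML must contain an 'events' list")
    events = []
    for ev in doc["events"]:
        events.append(
            StimulusEvent(
                t_on=_parse_time_s(ev["t_on"]),
                duration=_parse_time_s(ev.get("duration", 0.0)),
                kind=ev.get("kind", "light"),
                wavelength_nm=ev.get("wavelength_nm"),
                intensity_uw_mm2=(
                    _parse_intensity_uw(ev["intensity"]) if "intensity" in ev else None
                ),
                label=ev.get("label"),
            )
        )
    return StimulusProtocol(events=events)
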