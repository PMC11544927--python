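"""Video and trajectory file formats.

Videos are multi-page TIFF (16-bit unsigned counts or 32-bit float
contrast) or raw binary with a YAML/JSON sidecar describing width, height,
dtype and frame count.  Trajectories are delimited text with a commented
header block carrying units and the configuration hash; lengths on disk are
nm and times seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import ContrastVideo

__all__ = [
    "read_video",
    "write_video",
    "write_trajectory",
    "read_trajectory",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = ["frame", "t_s", "x_nm", "y_nm", "z_nm",
                      "peak_rho", "branch_id", "segment_id"]


def write_video(video: ContrastVideo | np.ndarray, path: str | Path,
                frame_interval: float | None = None,
                pixel_size: float | None = None) -> None:
    """Write frames as a multi-page TIFF with acquisition metadata."""
    if isinstance(video, ContrastVideo):
        frames = video.frames
        frame_interval = video.frame_interval
        pixel_size = video.pixel_size
        provenance = video.provenance
    else:
        frames = np.asarray(video)
        provenance = "raw"
    meta = {"frame_interval_s": frame_interval, "pixel_size_nm": pixel_size,
            "provenance": provenance}
    frames = frames.astype(np.float32) if frames.dtype.kind == "f" \
        else frames.astype(np.uint16)
    tifffile.imwrite(Path(path), frames, metadata=meta)


def _read_raw_sidecar(path: Path) -> tuple[np.ndarray, dict]:
    sidecar = None
    for suffix in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(path.suffix + suffix)
        if cand.exists():
            sidecar = cand
            break
    if sidecar is None:
        raise FileNotFoundError(f"raw video {path} needs a sidecar "
                                "(.yaml/.json) with width/height/dtype/frames")
    meta = (json.loads(sidecar.read_text()) if sidecar.suffix == ".json"
            else yaml.safe_load(sidecar.read_text()))
    for key in ("width", "height", "dtype", "frames"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    shape = (int(meta["frames"]), int(meta["height"]), int(meta["width"]))
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    expected = shape[0] * shape[1] * shape[2]
    if data.size != expected:
        found = data.size // (shape[1] * shape[2])
        raise ValueError(f"truncated raw video: expected {shape[0]} frames, "
                         f"found {found}")
    return data.reshape(shape), meta


def read_video(path: str | Path,
               frame_interval: float | None = None,
               pixel_size: float | None = None) -> ContrastVideo:
    """Read a multi-page TIFF or raw-binary-plus-sidecar video.

    Metadata from the file is merged with the explicitly passed values;
    explicit values win (they come from the run configuration).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
            elif tif.imagej_metadata:
                meta = dict(tif.imagej_metadata)
    else:
        frames, meta = _read_raw_sidecar(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"video must be 3-D (frames, h, w); got {frames.shape}")
    fi = frame_interval if frame_interval is not None \
        else meta.get("frame_interval_s") or 1.0
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
    provenance = meta.get("provenance",
                          "background_corrected" if frames.dtype.kind == "f"
                          else "raw")
    return ContrastVideo(frames=frames, frame_interval=float(fi),
                         provenance=provenance, pixel_size=px)


def write_trajectory(df_or_arrays, path: str | Path,
                     config_hash: str = "", extra_header: dict | None = None) -> None:
    """Write a trajectory table as commented-header CSV (full precision)."""
    if isinstance(df_or_arrays, pd.DataFrame):
        df = df_or_arrays
    else:
        df = pd.DataFrame(df_or_arrays)
    missing = [c for c in ("frame", "z_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    lines = ["# ispt3d trajectory",
             f"# config_hash: {config_hash}",
             "# units: lengths nm, times s",
             f"# columns: {','.join(df.columns)}"]
    for key, value in (extra_header or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table, validating the schema."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed trajectory file {path}: {err}") from err
    for col in ("frame", "z_nm"):
        if col not in df.columns:
            raise ValueError(f"trajectory file {path} missing required "
                             f"column {col!r}")
    return df
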