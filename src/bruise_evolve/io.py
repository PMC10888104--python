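"""Reading and writing frames, masks, traces and results.

Frames are 8-bit RGB PNGs named ``<specimen>_<T|C>_<NN>.png`` (frame index
01..n); a manifest CSV (columns: path, series, frame, time_min) may
override the naming convention and timestamps.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

FRAME_RE = re.compile(r"^(?P<specimen>.+)_(?P<series>[TC])_(?P<frame>\d+)\.(png|tif|tiff)$")


class SeriesError(ValueError):
    """Raised for malformed or incomplete frame series on disk."""


@dataclass
class FrameSeries:
    """Ordered frames of one series (injury T or control C)."""

    frames: list[np.ndarray]
    times: list[float]
    series: str                      # "T" | "C"
    specimen: str

    def __post_init__(self) -> None:
        if self.series not in ("T", "C"):
            raise SeriesError(f"unknown series tag {self.series!r}")
        if len(self.frames) != len(self.times):
            raise SeriesError("frames and times must align")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise SeriesError("timestamps must be strictly increasing")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise SeriesError(f"mixed frame dimensions: {sorted(shapes)}")


def write_frames(
    frames: Sequence[np.ndarray], out_dir: str | Path, specimen: str, series: str
) -> list[Path]:
    """Write a series as ``<specimen>_<series>_<NN>.png`` files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames, start=1):
        p = out / f"{specimen}_{series}_{i:02d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_masks(
    masks: Sequence[np.ndarray], out_dir: str | Path, stem: str
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(masks, start=1):
        p = out / f"{stem}_{i:02d}.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_masks(out_dir: str | Path, stem: str) -> list[np.ndarray]:
    paths = sorted(Path(out_dir).glob(f"{stem}_*.png"))
    if not paths:
        raise SeriesError(f"no {stem!r} masks found in {out_dir}")
    return [iio.imread(p) > 127 for p in paths]


def read_frame_series(
    path: str | Path,
    series: str = "T",
    frame_interval: float = 6.0,
    manifest: str | Path | None = None,
) -> FrameSeries:
    """Load one frame series from a directory or an explicit manifest CSV.

    Without a manifest, files matching the naming convention are used and
    timestamps default to frame index times ``frame_interval`` minutes.
    Missing frame indices raise an explicit error.
    """
    if manifest is not None:
        table = pd.read_csv(manifest)
        needed = {"path", "series", "frame", "time_min"}
        if not needed.issubset(table.columns):
            raise SeriesError(f"manifest must have columns {sorted(needed)}")
        sub = table[table["series"] == series].sort_values("frame")
        if sub.empty:
            raise SeriesError(f"manifest has no frames for series {series!r}")
        base = Path(manifest).parent
        frames = [
            iio.imread(p if Path(p).is_absolute() else base / p)
            for p in sub["path"]
        ]
        return FrameSeries(
            frames=frames,
            times=[float(t) for t in sub["time_min"]],
            series=series,
            specimen=str(sub.get("specimen", pd.Series(["specimen"])).iloc[0]),
        )

    directory = Path(path)
    found: dict[int, Path] = {}
    specimen = None
    for p in sorted(directory.iterdir()):
        m = FRAME_RE.match(p.name)
        if m and m.group("series") == series:
            found[int(m.group("frame"))] = p
            specimen = m.group("specimen")
    if not found:
        raise SeriesError(f"no {series}-series frames found in {directory}")
    n = max(found)
    missing = sorted(set(range(1, n + 1)) - set(found))
    if missing:
        raise SeriesError(f"missing {series}-series frames: {missing}")
    frames = [iio.imread(found[i]) for i in range(1, n + 1)]
    return FrameSeries(
        frames=frames,
        times=[frame_interval * i for i in range(1, n + 1)],
        series=series,
        specimen=specimen or "specimen",
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trace.to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
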