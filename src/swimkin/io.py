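"""Readers and writers for landmark tracks, binary frame stacks, and metadata.

Landmark tracks use the pose-estimation CSV dialect with a three-row header
(``scorer`` / ``bodyparts`` / ``coords``) and per-landmark ``x``, ``y``,
``likelihood`` columns.  Frame stacks are multi-page TIFFs or zero-padded PNG
sequences; any nonzero pixel counts as foreground.  Neither format carries a
frame rate, so ``fps`` is always supplied by the caller (the study default is
500 frames/s).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import FormatError, MissingLandmark

__all__ = [
    "PointTrack",
    "BinaryFrameStack",
    "read_pose_csv",
    "write_pose_csv",
    "read_frames",
    "write_frames",
    "read_config",
    "write_config",
    "DEFAULT_FPS",
]

DEFAULT_FPS = 500.0

FIN_LANDMARKS = ("fin_left", "fin_right")
CORE_LANDMARKS = ("nose", "tail")


@dataclass
class PointTrack:
    """Per-frame 2D landmark coordinates with confidences.

    ``xy[name]`` is an ``(n_frames, 2)`` float array of pixel coordinates and
    ``confidence[name]`` the matching ``(n_frames,)`` array in ``[0, 1]``.
    All landmark series must have the same length.
    """

    fps: float
    xy: dict = field(default_factory=dict)
    confidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        lengths = {name: len(a) for name, a in self.xy.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"landmark series have unequal lengths: {lengths}")
        for name, conf in self.confidence.items():
            conf = np.asarray(conf, float)
            if np.any((conf < 0) | (conf > 1)):
                raise ValueError(f"confidence for {name!r} outside [0, 1]")
            self.confidence[name] = conf
        for name in self.xy:
            self.xy[name] = np.asarray(self.xy[name], float)
            if name not in self.confidence:
                self.confidence[name] = np.ones(len(self.xy[name]))

    @property
    def n_frames(self) -> int:
        return 0 if not self.xy else len(next(iter(self.xy.values())))

    @property
    def landmark_names(self) -> list:
        return list(self.xy)

    def require(self, name: str) -> np.ndarray:
        if name not in self.xy:
            raise MissingLandmark(
                f"{name} landmark required but track only has {self.landmark_names}"
            )
        return self.xy[name]


@dataclass
class BinaryFrameStack:
    """A stack of boolean silhouette frames of constant shape."""

    frames: np.ndarray  # (n_frames, H, W) bool
    fps: float
    px_per_bl: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.frames.shape[0] < 1:
            raise ValueError("frame stack must contain at least one frame")
        self.frames = self.frames.astype(bool)
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


def read_pose_csv(
    path: str | os.PathLike,
    fps: float = DEFAULT_FPS,
    min_confidence: float = 0.0,
) -> PointTrack:
    """Read a pose-estimation CSV (scorer/bodyparts/coords header dialect).

    Landmark names come from the ``bodyparts`` header row.  A missing
    ``likelihood`` column defaults confidence to 1.0.  When
    ``min_confidence`` > 0, points below it are masked and linearly
    interpolated from neighbouring frames (the low-confidence treatment of
    hand-corrected digitizing).

    Raises
    ------
    FormatError
        On a malformed header (citing the offending row) or a non-numeric
        data cell (citing row and column).
    """
    path = Path(path)
    with open(path) as fh:
        header_lines = [fh.readline().rstrip("\n") for _ in range(3)]
    expected = ("scorer", "bodyparts", "coords")
    for i, (line, tag) in enumerate(zip(header_lines, expected)):
        first = line.split(",")[0].strip().lower()
        if first != tag:
            raise FormatError(
                f"malformed header row {i + 1}: expected first cell {tag!r}, "
                f"got {first!r}"
            )
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"could not parse pose CSV {path}: {exc}") from exc

    bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
    xy: dict = {}
    confidence: dict = {}
    for part in bodyparts:
        sub = df.xs(part, axis=1, level=1)
        sub.columns = [c[-1] for c in sub.columns]
        for coord in ("x", "y"):
            if coord not in sub.columns:
                raise FormatError(f"landmark {part!r} lacks a {coord!r} column")
        for col in sub.columns:
            vals = pd.to_numeric(sub[col], errors="coerce")
            bad = vals.index[vals.isna() & sub[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric cell at row {bad[0]}, column ({part}, {col})"
                )
            if vals.isna().any():
                raise FormatError(
                    f"missing value at row {vals.index[vals.isna()][0]}, "
                    f"column ({part}, {col})"
                )
        pts = sub[["x", "y"]].to_numpy(float)
        conf = (
            sub["likelihood"].to_numpy(float)
            if "likelihood" in sub.columns
            else np.ones(len(sub))
        )
        if min_confidence > 0:
            pts = _interpolate_masked(pts, conf < min_confidence)
        xy[part] = pts
        confidence[part] = np.clip(conf, 0.0, 1.0)
    return PointTrack(fps=fps, xy=xy, confidence=confidence)


def _interpolate_masked(pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate masked frames from surrounding good frames."""
    if not mask.any():
        return pts
    if mask.all():
        raise FormatError("all points below the confidence threshold")
    out = pts.copy()
    idx = np.arange(len(pts))
    good = ~mask
    for d in range(2):
        out[mask, d] = np.interp(idx[mask], idx[good], pts[good, d])
    return out


def write_pose_csv(
    track: PointTrack, path: str | os.PathLike, scorer: str = "swimkin"
) -> None:
    """Write a PointTrack in the three-header-row pose CSV dialect."""
    cols = []
    data = []
    for part in track.landmark_names:
        for coord in ("x", "y"):
            cols.append((scorer, part, coord))
            data.append(track.xy[part][:, 0 if coord == "x" else 1])
        cols.append((scorer, part, "likelihood"))
        data.append(track.confidence[part])
    df = pd.DataFrame(
        np.column_stack(data),
        columns=pd.MultiIndex.from_tuples(cols, names=["scorer", "bodyparts", "coords"]),
    )
    df.index.name = None
    df.to_csv(path, float_format="%.6f")


def read_frames(
    path_or_dir: str | os.PathLike, fps: float = DEFAULT_FPS
) -> BinaryFrameStack:
    """Read a multi-page TIFF or a lexicographically ordered PNG directory.

    Any nonzero pixel is foreground.  Mixed frame shapes and empty
    directories are errors.
    """
    p = Path(path_or_dir)
    if p.is_dir():
        files = sorted(p.glob("*.png"))
        if not files:
            raise FormatError(f"no PNG frames found in directory {p}")
        frames = []
        shape = None
        for f in files:
            arr = np.asarray(iio.imread(f))
            if arr.ndim == 3:  # collapse any colour channels
                arr = arr.any(axis=-1)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise FormatError(
                    f"mixed frame shapes: {f.name} is {arr.shape}, expected {shape}"
                )
            frames.append(arr != 0)
        stack = np.stack(frames)
    else:
        try:
            arr = tifffile.imread(p)
        except Exception as exc:
            raise FormatError(f"could not read TIFF {p}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:
            arr = arr.any(axis=-1)
        if arr.ndim != 3:
            raise FormatError(f"unexpected TIFF dimensionality {arr.shape} in {p}")
        stack = arr != 0
    return BinaryFrameStack(frames=stack, fps=fps)


def write_frames(stack: BinaryFrameStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF (``.tif``) or PNG directory."""
    p = Path(path)
    data = stack.frames.astype(np.uint8) * 255
    if p.suffix.lower() in {".tif", ".tiff"}:
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, data)
    else:
        p.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(stack.n_frames)))
        for i, frame in enumerate(data):
            iio.imwrite(p / f"frame_{i:0{width}d}.png", frame)


def read_config(path: str | os.PathLike) -> dict:
    """Load a YAML run configuration (keys mirror simulator/trial fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping at top level")
    return cfg


def write_config(cfg: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
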