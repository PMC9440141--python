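"""Image, video, trace and configuration I/O.

Conventions used throughout the package:

* 3D stacks are indexed ``(z, y, x)``, 0-based; videos ``(t, z, y, x)``.
* On disk images are unsigned 16-bit multi-page TIFFs (one page per
  z-plane), the dynamic range of EMCCD-class cameras; in memory
  everything is float32.
* Videos are stored as one TIFF per timepoint in a directory with
  zero-padded frame indices (``frame_0000.tif`` ...).
* Traces are CSV with columns ``cell_id,t,value``; tracks are CSV with
  columns ``cell_id,t,z,y,x,valid``; cell positions ``cell_id,x,y,z``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("niddl")


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger with ISO-timestamped plain-text output."""
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S"))
        log.addHandler(handler)
    log.setLevel(level.upper())
    return log


@dataclass
class ImageStack:
    """A 3D intensity grid ``(z, y, x)`` with voxel-size metadata (um)."""

    data: np.ndarray
    pixel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got {self.data.ndim}D")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class VideoStack:
    """A 4D intensity grid ``(t, z, y, x)``; frames denoise independently."""

    frames: np.ndarray
    dt_s: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4:
            raise ValueError(
                f"video must be 4D (t, z, y, x), got {self.frames.ndim}D")

    @property
    def shape(self):
        return self.frames.shape

    def frame(self, t: int) -> ImageStack:
        return ImageStack(self.frames[t])


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def read_stack(path) -> ImageStack:
    """Read a single- or multi-page TIFF as a ``(z, y, x)`` stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt / non-TIFF
        raise ValueError(f"cannot parse {path} as TIFF: {exc}") from exc
    return ImageStack(np.asarray(data))


def write_stack(stack: ImageStack, path) -> None:
    """Write as uint16 multi-page TIFF, one page per z-plane.

    Values are clipped to [0, 65535] and rounded; clipping is logged.
    """
    data = np.asarray(stack.data if isinstance(stack, ImageStack) else stack,
                      dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError("stack contains non-finite values")
    if data.min() < 0 or data.max() > 65535:
        log.warning("write_stack: clipping intensities to [0, 65535] "
                    "(range was [%.1f, %.1f])", data.min(), data.max())
    out = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


# ---------------------------------------------------------------------------
# videos
# ---------------------------------------------------------------------------

def write_video(video: VideoStack, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(video.frames.shape[0]):
        write_stack(ImageStack(video.frames[t]),
                    directory / f"frame_{t:04d}.tif")


def read_video(path) -> VideoStack:
    """Read a video from a directory of per-timepoint TIFFs, or a 4D TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF frames in {path}")
        frames = []
        for i, f in enumerate(files):
            stack = read_stack(f)
            if frames and stack.data.shape != frames[0].shape:
                raise ValueError(
                    f"frame {i} ({f.name}) has shape {stack.data.shape}, "
                    f"expected {frames[0].shape}")
            frames.append(stack.data)
        return VideoStack(np.stack(frames))
    stack = read_stack(path)  # a single 4D-interpretable TIFF
    data = tifffile.imread(path)
    if data.ndim == 4:
        return VideoStack(np.asarray(data))
    return VideoStack(stack.data[None])


# ---------------------------------------------------------------------------
# traces / tracks / positions (CSV)
# ---------------------------------------------------------------------------

def write_traces(values: np.ndarray, path, cell_ids=None) -> None:
    """Serialize a cells x timepoints matrix as ``cell_id,t,value`` CSV."""
    values = np.asarray(values)
    n, T = values.shape
    if cell_ids is None:
        cell_ids = np.arange(n)
    df = pd.DataFrame({
        "cell_id": np.repeat(cell_ids, T),
        "t": np.tile(np.arange(T), n),
        "value": values.ravel(),
    })
    df.to_csv(path, index=False)


def read_traces(path):
    """Read a traces CSV back into (values, cell_ids)."""
    df = pd.read_csv(path)
    pivot = df.pivot(index="cell_id", columns="t", values="value").sort_index()
    return pivot.to_numpy(), pivot.index.to_numpy()


def write_tracks(coords: np.ndarray, valid: np.ndarray, path,
                 cell_ids=None) -> None:
    """coords: (n_cells, T, 3) in (z, y, x); valid: (n_cells, T) bool."""
    n, T, _ = coords.shape
    if cell_ids is None:
        cell_ids = np.arange(n)
    df = pd.DataFrame({
        "cell_id": np.repeat(cell_ids, T),
        "t": np.tile(np.arange(T), n),
        "z": coords[:, :, 0].ravel(),
        "y": coords[:, :, 1].ravel(),
        "x": coords[:, :, 2].ravel(),
        "valid": valid.astype(int).ravel(),
    })
    df.to_csv(path, index=False)


def read_tracks(path):
    df = pd.read_csv(path)
    ids = np.sort(df["cell_id"].unique())
    T = df["t"].max() + 1
    coords = np.zeros((len(ids), T, 3))
    valid = np.zeros((len(ids), T), dtype=bool)
    for i, cid in enumerate(ids):
        sub = df[df["cell_id"] == cid].sort_values("t")
        coords[i] = sub[["z", "y", "x"]].to_numpy()
        valid[i] = sub["valid"].to_numpy().astype(bool)
    return coords, valid, ids


def read_positions_csv(path) -> np.ndarray:
    """Cell positions CSV (``cell_id,x,y,z``) -> (n, 3) array in (z, y, x)."""
    df = pd.read_csv(path)
    return df[["z", "y", "x"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# configuration: INI-style structured text
# ---------------------------------------------------------------------------

def save_config(config: dict, path) -> None:
    """Write a (possibly nested one level) dict as INI-style text."""
    import configparser
    cp = configparser.ConfigParser()
    flat = {k: v for k, v in config.items() if not isinstance(v, dict)}
    if flat:
        cp["main"] = {k: repr(v) for k, v in flat.items()}
    for k, v in config.items():
        if isinstance(v, dict):
            cp[k] = {kk: repr(vv) for kk, vv in v.items()}
    with open(path, "w") as fh:
        cp.write(fh)


def load_config(path) -> dict:
    import ast
    import configparser
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    out: dict = {}
    for section in cp.sections():
        d = {k: ast.literal_eval(v) for k, v in cp[section].items()}
        if section == "main":
            out.update(d)
        else:
            out[section] = d
    return out
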