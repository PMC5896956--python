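"""Image-stack and movie containers plus TIFF/CSV input-output.

All confocal quantification in this package operates on :class:`ImageStack`
objects: a dictionary of named channels, each a 3D ``(plane, row, col)``
float array, together with voxel-size metadata.  Time-lapse TIRF data are
held in :class:`TirfMovie`.  Both are plain dataclasses so that downstream
modules stay free of file-format concerns.

Conventions shared by every module:

* voxel indexing is 0-based with axis order ``(plane, row, col)``;
* intensities are non-negative after background subtraction (negative
  values are clamped to zero so that mask intensity sums stay meaningful);
* results serialize to flat CSV tables through :func:`write_result_table`.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    """Raised when a file's layout does not match the declared channels."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no signal."""


@dataclass
class ImageStack:
    """Multichannel 3D intensity stack.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"Cy3"``, ``"Cy5"``, ``"YFP"``,
        ``"CFP"``, ``"FRET"``, ``"TxR"``) to a 3D ``(plane, row, col)``
        array of non-negative intensities.
    voxel_size
        ``(dz, dy, dx)`` in nanometres.
    metadata
        Free-form key/value annotation (acquisition notes, background
        offsets applied, simulation truth identifiers, ...).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (300.0, 100.0, 100.0)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {ch: np.asarray(g).shape for ch, g in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channel grids must be 3D (plane,row,col), got {first}")
        for ch, shp in shapes.items():
            if shp != first:
                raise ValueError(f"channel {ch!r} shape {shp} != {first}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            )
        return self.channels[name]


@dataclass
class TirfMovie:
    """2D time-lapse movie from total internal reflection microscopy.

    ``frames`` is a ``(t, row, col)`` array; ``frame_interval`` is the time
    between frames in minutes (the assays this package targets use 1-2 min
    intervals); ``pixel_size`` is in nanometres.
    """

    frames: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float = 160.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (t, row, col) array with >= 1 frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_min(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a multichannel TIFF (axes CZYX).

    Channel order follows the dictionary's insertion order and is recorded
    in the TIFF metadata so that :func:`read_stack` round-trips it.
    """
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "channel_names": names,
            "voxel_size_nm": list(stack.voxel_size),
        },
    )


def read_stack(path, channel_names: list[str]) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    The file's axes must resolve to ``(channel, plane, row, col)`` or
    ``(plane, channel, row, col)``; 2D and single-channel files are
    promoted (a 2D image becomes a one-plane stack).  ``channel_names``
    assigns names in order and must match the channel count.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path!r}: {exc}") from exc

    data = np.asarray(data)
    if data.ndim == 2:  # single-channel single-plane
        data = data[None, None]
        axes = "CZYX"
    elif data.ndim == 3:
        # Leading axis is channels if it matches the requested names,
        # otherwise interpret it as planes of a single channel.
        if len(channel_names) == data.shape[0] and "C" in axes:
            data = data[:, None]
        else:
            data = data[None]
        axes = "CZYX"
    elif data.ndim == 4:
        if axes[:2] in ("ZC", "TC") or (axes[0] not in "C" and axes[1] == "C"):
            data = np.moveaxis(data, 1, 0)
        axes = "CZYX"
    else:
        raise FormatError(f"unsupported TIFF dimensionality {data.ndim} (axes {axes})")

    if data.shape[0] != len(channel_names):
        raise FormatError(
            f"expected {len(channel_names)} channels {channel_names}, "
            f"found {data.shape[0]} in {path!r}"
        )
    channels = {name: data[i] for i, name in enumerate(channel_names)}
    return ImageStack(channels=channels)


def write_movie(path, movie: TirfMovie) -> None:
    tifffile.imwrite(
        path,
        movie.frames,
        metadata={
            "axes": "TYX",
            "frame_interval_min": movie.frame_interval,
            "pixel_size_nm": movie.pixel_size,
        },
    )


def read_movie(path, frame_interval: float = 1.0, pixel_size: float = 160.0) -> TirfMovie:
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"movie TIFF must be 2D or (t,row,col) 3D, got {data.ndim}D")
    return TirfMovie(frames=data, frame_interval=frame_interval, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Background subtraction


def subtract_background(stack: ImageStack, mode: str = "constant", value: float = 0.0) -> ImageStack:
    """Subtract a per-channel background offset, clamping at zero.

    ``mode="constant"`` subtracts ``value`` from every voxel of every
    channel.  ``mode="percentile"`` uses the given percentile (in
    ``(0, 50]``) of each channel's intensities as that channel's offset.
    Offsets actually applied are recorded in the returned stack's metadata.
    """
    if mode not in ("constant", "percentile"):
        raise ValueError(f"unknown background mode {mode!r}")
    if mode == "constant" and value < 0:
        raise ValueError("constant background offset must be >= 0")
    if mode == "percentile" and not 0 < value <= 50:
        raise ValueError("percentile must lie in (0, 50]")

    out: dict[str, np.ndarray] = {}
    meta = dict(stack.metadata)
    for name, grid in stack.channels.items():
        grid = np.asarray(grid, dtype=float)
        offset = value if mode == "constant" else float(np.percentile(grid, value))
        out[name] = np.maximum(grid - offset, 0.0)
        meta[f"background_offset_{name}"] = repr(offset)
    return ImageStack(channels=out, voxel_size=stack.voxel_size, metadata=meta)


def modal_background(grid: np.ndarray) -> float:
    """Estimate a channel's background as the modal intensity of its first plane.

    The mode is taken over a 256-bin histogram of the first plane, which in
    a sparsely labelled fluorescence image is dominated by background.  This
    is the package's default when no explicit offset is configured.
    """
    plane = np.asarray(grid)[0].ravel()
    counts, edges = np.histogram(plane, bins=256)
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2.0)


# ---------------------------------------------------------------------------
# Result tables and config

RESULT_COLUMNS = ["image_id", "condition", "metric", "value"]


def make_result_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-image metric rows into the package's flat result table.

    Each row needs at least ``image_id``, ``condition``, ``metric`` and a
    finite ``value``; extra keys become auxiliary columns.  One row per
    (image_id, metric) is enforced.
    """
    df = pd.DataFrame(rows)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result rows missing columns {missing}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("metric values must be finite")
    if df.duplicated(["image_id", "metric"]).any():
        raise ValueError("duplicate (image_id, metric) rows")
    front = [c for c in RESULT_COLUMNS if c in df.columns]
    return df[front + [c for c in df.columns if c not in front]]


def write_result_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a YAML config of thresholds, seeds and per-assay parameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def log(msg: str) -> None:
    """Per-image progress logging to stderr."""
    print(msg, file=sys.stderr)
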