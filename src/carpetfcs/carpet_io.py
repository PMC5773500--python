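"""Containers and I/O for line-scan carpets, image stacks and result tables.

A *carpet* is a line-scan time series stored as an (n_lines, n_pixels,
n_channels) array of photon counts: each column is the time trace of one
pixel position along the scanned line.  Carpets and image stacks travel as
multi-page TIFF files (one page per channel, or frame-major/channel-minor
for time series) with a JSON sidecar holding the acquisition metadata that
every physical-unit computation needs (pixel size, line/frame period,
dwell time).  Readers validate the sidecar and never silently coerce
units; writers round-trip bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LineScanCarpet",
    "ImageStack",
    "ImageStack3D",
    "read_carpet",
    "write_carpet",
    "read_stack",
    "write_stack",
    "write_results_table",
    "read_results_table",
]


class FormatError(ValueError):
    """Raised when a file's shape or sidecar disagrees with its declaration."""


def _check_counts(data: np.ndarray, ndim: int, name: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != ndim:
        raise FormatError(f"{name} must be {ndim}-dimensional, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer) and data.min(initial=0) < 0:
        raise FormatError(f"{name} contains negative counts")
    return data


@dataclass
class LineScanCarpet:
    """Line-scan time series F(t, r): shape (n_lines, n_pixels, n_channels).

    Metadata is mandatory: ``pixel_size_nm`` (sampling pitch along the
    line), ``line_period_ms`` (time between successive lines, the
    correlation time base) and ``dwell_time_us`` (per-pixel integration).
    """

    data: np.ndarray
    pixel_size_nm: float
    line_period_ms: float
    dwell_time_us: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = _check_counts(self.data, 3, "carpet data")
        if self.data.shape[2] not in (1, 2):
            raise FormatError(f"carpet must have 1 or 2 channels, got {self.data.shape[2]}")
        for key in ("pixel_size_nm", "line_period_ms", "dwell_time_us"):
            v = getattr(self, key)
            if v is None or not np.isfinite(v) or v <= 0:
                raise FormatError(f"{key} required and must be a positive number, got {v!r}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[2]))
        elif len(self.channel_names) != self.data.shape[2]:
            raise FormatError(
                f"{len(self.channel_names)} channel names declared for "
                f"{self.data.shape[2]}-channel data"
            )
        else:
            self.channel_names = tuple(self.channel_names)

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def line_period_s(self) -> float:
        return self.line_period_ms * 1e-3

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_period_s

    def positions_um(self) -> np.ndarray:
        """Physical pixel-center positions along the line (µm), column 0 first."""
        return np.arange(self.n_pixels) * self.pixel_size_nm * 1e-3

    def channel(self, index_or_name: int | str) -> np.ndarray:
        """2D (n_lines, n_pixels) view of one channel."""
        if isinstance(index_or_name, str):
            index_or_name = self.channel_names.index(index_or_name)
        return self.data[:, :, index_or_name]


@dataclass
class ImageStack:
    """2D time series: shape (n_frames, n_rows, n_cols, n_channels)."""

    data: np.ndarray
    pixel_size_nm: float
    frame_period_ms: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = _check_counts(self.data, 4, "stack data")
        if self.data.shape[3] not in (1, 2):
            raise FormatError(f"stack must have 1 or 2 channels, got {self.data.shape[3]}")
        for key in ("pixel_size_nm", "frame_period_ms"):
            v = getattr(self, key)
            if v is None or not np.isfinite(v) or v <= 0:
                raise FormatError(f"{key} required and must be a positive number, got {v!r}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[3]))
        else:
            self.channel_names = tuple(self.channel_names)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def frame_period_s(self) -> float:
        return self.frame_period_ms * 1e-3


@dataclass
class ImageStack3D:
    """Single-channel 3D volume (z, y, x) with anisotropic voxel sizes in nm."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]  # (z, y, x)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"3D stack must have 3 axes, got shape {self.data.shape}")
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != 3 or any(v <= 0 for v in self.voxel_size_nm):
            raise FormatError(f"voxel_size_nm must be 3 positive numbers, got {self.voxel_size_nm}")

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return tuple(v * 1e-3 for v in self.voxel_size_nm)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar I/O


def _default_sidecar(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def _require(meta: Mapping[str, Any], key: str, path: Path | str) -> Any:
    if key not in meta or meta[key] is None:
        raise FormatError(f"{key} required in sidecar {path}")
    return meta[key]


def write_carpet(
    carpet: LineScanCarpet,
    path: Path | str,
    sidecar_path: Path | str | None = None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write a carpet as a channel-interleaved multi-page TIFF plus JSON sidecar.

    Page ``k`` holds channel ``k`` as an (n_lines, n_pixels) image.  ``extra``
    (e.g. a simulation config and ground truth) is stored verbatim under
    ``"extra"`` in the sidecar.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    pages = np.moveaxis(carpet.data, 2, 0)  # (channels, lines, pixels)
    tifffile.imwrite(path, pages)
    meta: dict[str, Any] = {
        "kind": "line_scan_carpet",
        "n_lines": carpet.n_lines,
        "n_pixels": carpet.n_pixels,
        "n_channels": carpet.n_channels,
        "channel_names": list(carpet.channel_names),
        "pixel_size_nm": carpet.pixel_size_nm,
        "line_period_ms": carpet.line_period_ms,
        "dwell_time_us": carpet.dwell_time_us,
        "dtype": str(carpet.data.dtype),
    }
    if extra:
        meta["extra"] = dict(extra)
    sidecar.write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def read_carpet(path: Path | str, sidecar_path: Path | str | None = None) -> LineScanCarpet:
    """Read a carpet written by :func:`write_carpet`, validating the sidecar."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = int(_require(meta, "n_channels", sidecar))
    if pages.shape[0] != n_channels:
        raise FormatError(
            f"{path}: {pages.shape[0]} TIFF pages but {n_channels} channels declared"
        )
    data = np.moveaxis(pages, 0, 2)
    return LineScanCarpet(
        data=data,
        pixel_size_nm=float(_require(meta, "pixel_size_nm", sidecar)),
        line_period_ms=float(_require(meta, "line_period_ms", sidecar)),
        dwell_time_us=float(_require(meta, "dwell_time_us", sidecar)),
        channel_names=tuple(meta.get("channel_names") or ()),
    )


def write_stack(
    stack: ImageStack,
    path: Path | str,
    sidecar_path: Path | str | None = None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write an image time series, frame-major / channel-minor pages."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    f, r, c, ch = stack.data.shape
    pages = np.moveaxis(stack.data, 3, 1).reshape(f * ch, r, c)
    tifffile.imwrite(path, pages)
    meta: dict[str, Any] = {
        "kind": "image_stack",
        "n_frames": f,
        "n_rows": r,
        "n_cols": c,
        "n_channels": ch,
        "channel_names": list(stack.channel_names),
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_period_ms": stack.frame_period_ms,
        "page_order": "frame_major_channel_minor",
        "dtype": str(stack.data.dtype),
    }
    if extra:
        meta["extra"] = dict(extra)
    sidecar.write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def read_stack(path: Path | str, sidecar_path: Path | str | None = None) -> ImageStack:
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_frames = int(_require(meta, "n_frames", sidecar))
    n_channels = int(_require(meta, "n_channels", sidecar))
    if pages.shape[0] != n_frames * n_channels:
        raise FormatError(
            f"{path}: {pages.shape[0]} TIFF pages but "
            f"{n_frames} frames x {n_channels} channels declared"
        )
    data = np.moveaxis(pages.reshape(n_frames, n_channels, *pages.shape[1:]), 1, 3)
    return ImageStack(
        data=data,
        pixel_size_nm=float(_require(meta, "pixel_size_nm", sidecar)),
        frame_period_ms=float(_require(meta, "frame_period_ms", sidecar)),
        channel_names=tuple(meta.get("channel_names") or ()),
    )


# ---------------------------------------------------------------------------
# Result tables


def write_results_table(
    records: Sequence[Any] | pd.DataFrame,
    path: Path | str,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write homogeneous records (dataclasses, dicts or a DataFrame) as CSV.

    Column order is stable (declaration order of the first record) and
    floats are written at full round-trip precision.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            records = [dataclasses.asdict(r) for r in records]
        if records:
            df = pd.DataFrame.from_records(records)
        else:
            df = pd.DataFrame(columns=list(columns or []))
    if columns:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)
    return path


def read_results_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
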