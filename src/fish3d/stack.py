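"""Calibrated multi-channel z-stack I/O.

Coordinate conventions used throughout the package:

* ``voxels`` is indexed ``(layer, row, column, channel)``, 0-based.
* Physical position in μm is
  ``(column * pixel_size_xy, row * pixel_size_xy, layer * z_interval)``.
* On disk a stack is a multi-page TIFF, one page per (layer, channel).
  The default page order is layer-major with channel minor
  (L0/DAPI, L0/FITC, L0/TRITC, L1/DAPI, ...); ``page_order="channel_major"``
  selects the other dialect. Calibration is stored as JSON in the image
  description tag and honored on read, but an explicit RunConfig wins on
  conflict (with a warning).
"""

from __future__ import annotations

import json
import logging
import numbers
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .config import DEFAULT_CHANNELS, RunConfig

log = logging.getLogger(__name__)


class StackFormatError(ValueError):
    """The file on disk does not satisfy the page-layout contract."""


@dataclass
class ZStack:
    """One calibrated 3-channel confocal volume.

    voxels: (n_layers, rows, columns, n_channels) non-negative intensities.
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_interval: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.channel_names = tuple(self.channel_names)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (layer, row, column, channel)")
        if self.voxels.shape[3] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.voxels.shape[0] < 1:
            raise ValueError("need at least one layer")
        if self.pixel_size_xy <= 0 or self.z_interval <= 0:
            raise ValueError("calibration must be positive")
        if np.issubdtype(self.voxels.dtype, np.floating) and np.any(
            self.voxels < 0
        ):
            raise ValueError("voxel intensities must be non-negative")

    @property
    def n_layers(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """(n_layers, rows, columns) view of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.voxels[..., idx]

    def position_um(self, x_px: float, y_px: float, layer: float) -> tuple[float, float, float]:
        """Convert (column, row, layer) indices to a μm position (X, Y, Z)."""
        return (
            x_px * self.pixel_size_xy,
            y_px * self.pixel_size_xy,
            layer * self.z_interval,
        )


def _page_index(layer: int, chan: int, n_layers: int, n_chan: int, order: str) -> int:
    if order == "layer_major":
        return layer * n_chan + chan
    return chan * n_layers + layer


def read_stack(path: str | Path, config: RunConfig | None = None) -> ZStack:
    """Read a multi-page TIFF into a calibrated ZStack.

    The page count must be a multiple of the configured channel count.
    Calibration comes from the config; embedded metadata (JSON in the image
    description) is used when it agrees or when no config value differs —
    on conflict the config wins and a warning is logged.
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")

    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
        description = tf.pages[0].description or ""

    n_chan = len(config.channel_names)
    if len(pages) == 0 or len(pages) % n_chan != 0:
        raise StackFormatError(
            f"{path}: {len(pages)} pages is not a multiple of "
            f"{n_chan} channels"
        )
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise StackFormatError(f"{path}: inconsistent page dimensions {sorted(shapes)}")

    n_layers = len(pages) // n_chan
    pixel_size = config.pixel_size_xy
    z_interval = config.z_interval
    channel_names = config.channel_names
    meta = _parse_metadata(description)
    if meta:
        for key, cfg_val in (
            ("pixel_size_xy", pixel_size),
            ("z_interval", z_interval),
        ):
            if key in meta and isinstance(meta[key], numbers.Real):
                if abs(float(meta[key]) - cfg_val) > 1e-9:
                    log.warning(
                        "%s: embedded %s=%s disagrees with config %s; using config",
                        path, key, meta[key], cfg_val,
                    )
        if "channel_names" in meta and tuple(meta["channel_names"]) != channel_names:
            log.warning(
                "%s: embedded channels %s disagree with config %s; using config",
                path, meta["channel_names"], channel_names,
            )

    rows, cols = pages[0].shape
    voxels = np.empty((n_layers, rows, cols, n_chan), dtype=pages[0].dtype)
    for layer in range(n_layers):
        for chan in range(n_chan):
            idx = _page_index(layer, chan, n_layers, n_chan, config.page_order)
            voxels[layer, :, :, chan] = pages[idx]
    return ZStack(
        voxels=voxels,
        pixel_size_xy=pixel_size,
        z_interval=z_interval,
        channel_names=channel_names,
    )


def write_stack(
    stack: ZStack, path: str | Path, page_order: str = "layer_major"
) -> Path:
    """Write a ZStack as a multi-page TIFF with calibration metadata.

    Round-trips bit-exactly through :func:`read_stack` with the same page
    order.
    """
    path = Path(path)
    n_layers = stack.n_layers
    n_chan = len(stack.channel_names)
    pages = np.empty(
        (n_layers * n_chan,) + stack.shape_2d, dtype=stack.voxels.dtype
    )
    for layer in range(n_layers):
        for chan in range(n_chan):
            idx = _page_index(layer, chan, n_layers, n_chan, page_order)
            pages[idx] = stack.voxels[layer, :, :, chan]
    meta = {
        "pixel_size_xy": stack.pixel_size_xy,
        "z_interval": stack.z_interval,
        "channel_names": list(stack.channel_names),
        "n_layers": n_layers,
        "page_order": page_order,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    # photometric forced so a 3-page stack is never stored as one RGB page
    tifffile.imwrite(
        path, pages, photometric="minisblack", description=json.dumps(meta)
    )
    return path


def _parse_metadata(description: str) -> dict:
    if not description:
        return {}
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, ValueError):
        return {}
    return meta if isinstance(meta, dict) else {}
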