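"""4D volume container and OME-TIFF input/output.

A :class:`VolumeSeries` holds a (t, c, z, y, x) intensity record with
physical voxel spacing and per-frame timestamps.  Channel 0 is the GFP
sensor channel; an optional second channel labels the (non-fluorescent)
APC.  Files are written as OME-TIFF with TCZYX axes and physical sizes in
the metadata; readers fall back to configured spacing when metadata is
missing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger(__name__)

GFP_CHANNEL = "gfp"
APC_CHANNEL = "apc"


@dataclass
class VolumeSeries:
    """Time series of fluorescence volumes.

    Parameters
    ----------
    data : ndarray, shape (t, c, z, y, x)
        Intensity data.
    spacing : tuple of float
        Voxel spacing (z, y, x) in µm.
    timestamps : ndarray, shape (t,)
        Frame acquisition times in seconds.
    channels : tuple of str
        Channel names; by convention ``("gfp",)`` or ``("gfp", "apc")``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    timestamps: np.ndarray
    channels: tuple[str, ...] = (GFP_CHANNEL,)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("data must be 5-dimensional (t, c, z, y, x)")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.data.shape[0],):
            raise ValueError("timestamps must have one entry per frame")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel names must match data channels")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel(self, name: str, frame: int) -> np.ndarray:
        """One (z, y, x) volume for a named channel at a frame index."""
        return self.data[frame, self.channels.index(name)]

    def write_ome_tiff(self, path: str | Path) -> None:
        path = Path(path)
        dt = (
            float(self.timestamps[1] - self.timestamps[0])
            if self.n_frames > 1
            else 0.0
        )
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "TCZYX",
                "PhysicalSizeZ": self.spacing[0],
                "PhysicalSizeY": self.spacing[1],
                "PhysicalSizeX": self.spacing[2],
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
                "TimeIncrement": dt,
                "TimeIncrementUnit": "s",
                "Channel": {"Name": list(self.channels)},
            },
        )


def _ome_float(xml: str, attr: str) -> float | None:
    m = re.search(rf'{attr}="([0-9.eE+-]+)"', xml)
    return float(m.group(1)) if m else None


def read_volume_series(
    path: str | Path,
    fallback_spacing: tuple[float, float, float] | None = None,
    fallback_interval: float | None = None,
    channels: tuple[str, ...] | None = None,
) -> VolumeSeries:
    """Read a TIFF/OME-TIFF stack into a :class:`VolumeSeries`.

    Axes are taken from the file metadata (any subset/order of TCZYX is
    accepted and expanded to the full 5D layout).  Voxel spacing and frame
    interval come from OME metadata; when missing, the fallback values are
    used and a warning is logged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C")
        ome = tf.ome_metadata or ""

    # map unlabelled axes (e.g. 'Q') onto the canonical ones not yet used:
    # innermost unlabelled axis is Z, then T, then C going outward
    free = [ax for ax in "ZTC" if ax not in axes]
    chars = list(axes)
    for i in range(len(chars) - 1, -1, -1):
        if chars[i] not in "TCZYX":
            if not free:
                raise ValueError(
                    f"{path}: ambiguous axis layout {series.axes!r}"
                )
            chars[i] = free.pop(0)
    axes = "".join(chars)
    if len(set(axes)) != len(axes):
        raise ValueError(f"{path}: ambiguous axis layout {series.axes!r}")
    # Expand to TCZYX
    for ax in "TCZYX":
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCZYX"]
    data = np.transpose(data, order)

    sz = _ome_float(ome, "PhysicalSizeZ")
    sy = _ome_float(ome, "PhysicalSizeY")
    sx = _ome_float(ome, "PhysicalSizeX")
    if sz is None or sy is None or sx is None:
        if fallback_spacing is None:
            raise ValueError(
                f"{path}: no voxel-size metadata and no fallback spacing"
            )
        log.warning(
            "%s: missing voxel-size metadata, using configured spacing %s",
            path, fallback_spacing,
        )
        spacing = tuple(fallback_spacing)
    else:
        spacing = (sz, sy, sx)

    dt = _ome_float(ome, "TimeIncrement")
    if dt is None or dt == 0.0:
        if data.shape[0] > 1:
            if fallback_interval is None:
                raise ValueError(
                    f"{path}: no frame-interval metadata and no fallback"
                )
            log.warning(
                "%s: missing frame interval, using configured %.3g s",
                path, fallback_interval,
            )
            dt = fallback_interval
        else:
            dt = fallback_interval or 0.0
    timestamps = np.arange(data.shape[0], dtype=float) * dt

    if channels is None:
        names = re.findall(r'Channel[^>]*Name="([^"]+)"', ome)
        if len(names) == data.shape[1]:
            channels = tuple(names)
        else:
            channels = tuple(
                (GFP_CHANNEL, APC_CHANNEL)[: data.shape[1]]
            ) if data.shape[1] <= 2 else tuple(
                f"ch{i}" for i in range(data.shape[1])
            )
    return VolumeSeries(
        data=data, spacing=spacing, timestamps=timestamps, channels=channels
    )
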