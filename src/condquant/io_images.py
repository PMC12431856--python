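"""Reading, writing and rescaling of image stacks and label masks.

Conventions used throughout the package:

* voxel coordinates are 0-based and ordered ``(z, y, x)``;
* bounding boxes are half-open, ``(z0, z1, y0, y1, x0, x1)``;
* multichannel stacks are ordered ``(channel, z, y, x)``;
* time-lapse movies are ordered ``(t, y, x)``;
* physical voxel sizes are micrometres per axis, ``(dz, dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "rescale_16bit",
]

#: Axis layouts read_stack knows how to normalize.
_KNOWN_LAYOUTS = ("yx", "zyx", "tyx", "czyx")


@dataclass
class ImageStack:
    """An intensity array with physical voxel sizes and channel labels.

    ``data`` is indexed ``(z, y, x)``, ``(channel, z, y, x)`` or
    ``(t, y, x)`` according to ``layout``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.2, 0.11, 0.11)
    channel_labels: tuple[str, ...] = ()
    bit_depth: int = 16
    layout: str = "zyx"

    def __post_init__(self) -> None:
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.channel_labels = tuple(self.channel_labels)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.layout not in _KNOWN_LAYOUTS and self.layout != "zyx":
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "czyx":
            if self.data.ndim != 4:
                raise ValueError("czyx layout requires a 4D array")
            if self.channel_labels and len(self.channel_labels) != self.data.shape[0]:
                raise ValueError("channel count must equal label count")
        if min(self.spatial_shape) < 1:
            raise ValueError("all spatial dims must be >= 1")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        if self.layout == "czyx":
            return tuple(self.data.shape[1:])
        return tuple(self.data.shape)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, label: str) -> np.ndarray:
        """Return the 3D ``(z, y, x)`` array for a named channel."""
        if self.layout != "czyx":
            raise ValueError("channel() requires a czyx stack")
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; have {list(self.channel_labels)}"
            ) from None
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=data)


def _normalize_layout(data: np.ndarray, layout: str) -> tuple[np.ndarray, str]:
    """Promote 2D arrays to single-plane stacks; leave the rest alone."""
    if layout == "yx":
        return data[np.newaxis, ...], "zyx"
    return data, layout


def read_stack(
    path: str | Path,
    layout_hint: str | None = None,
    voxel_size: Sequence[float] | None = None,
    channel_labels: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF stack (or an HDF5 volume) into an ImageStack.

    Axis order and voxel size are taken from OME metadata when present;
    otherwise ``layout_hint`` must disambiguate and ``voxel_size`` supplies
    physical sizes (package defaults apply when omitted).
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        data = _read_hdf5_volume(path)
        meta_layout, meta_voxel, meta_labels = None, None, None
    else:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            meta_layout, meta_voxel, meta_labels = _parse_ome(tif, series)

    layout = layout_hint or meta_layout
    if layout is None:
        candidates = [l for l in _KNOWN_LAYOUTS if len(l) == data.ndim]
        if data.ndim == 3:
            raise ValueError(
                "ambiguous axis order for a 3D array without OME metadata; "
                f"pass layout_hint, one of {candidates}"
            )
        layout = {2: "yx", 4: "czyx"}.get(data.ndim)
        if layout is None:
            raise ValueError(f"unsupported array dimensionality {data.ndim}")
    layout = layout.lower()
    if layout not in _KNOWN_LAYOUTS:
        raise ValueError(f"layout_hint must be one of {_KNOWN_LAYOUTS}")

    data, layout = _normalize_layout(data, layout)
    vs = tuple(voxel_size) if voxel_size is not None else (meta_voxel or (0.2, 0.11, 0.11))
    labels = tuple(channel_labels) if channel_labels is not None else tuple(meta_labels or ())
    if layout == "czyx" and not labels:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    bit_depth = data.dtype.itemsize * 8 if data.dtype.kind in "ui" else 16
    return ImageStack(data=data, voxel_size=vs, channel_labels=labels,
                      bit_depth=bit_depth, layout=layout)


def _read_hdf5_volume(path: Path) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        keys = sorted(f.keys())
        if not keys:
            raise ValueError(f"{path}: empty HDF5 file")
        return np.asarray(f[keys[0]])


def _parse_ome(tif: "tifffile.TiffFile", series) -> tuple:
    """Extract (layout, voxel_size, channel_labels) from OME metadata."""
    axes = series.axes.lower().replace("s", "c")
    # "q" marks an axis tifffile could not identify: keep it ambiguous
    layout = axes if axes in _KNOWN_LAYOUTS else None
    voxel = None
    labels = None
    if tif.ome_metadata:
        try:
            meta = tifffile.xml2dict(tif.ome_metadata)
            pixels = meta["OME"]["Image"]["Pixels"]
            if isinstance(pixels.get("Channel"), list):
                labels = [c.get("Name", f"ch{i}") for i, c in enumerate(pixels["Channel"])]
            elif isinstance(pixels.get("Channel"), dict):
                labels = [pixels["Channel"].get("Name", "ch0")]
            voxel = (
                float(pixels.get("PhysicalSizeZ", 0.2)),
                float(pixels.get("PhysicalSizeY", 0.11)),
                float(pixels.get("PhysicalSizeX", 0.11)),
            )
        except (KeyError, TypeError, ValueError):
            pass
    return layout, voxel, labels


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as OME-TIFF with voxel size and channel names."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    axes = stack.layout.upper()
    metadata = {
        "axes": axes,
        "PhysicalSizeZ": dz,
        "PhysicalSizeY": dy,
        "PhysicalSizeX": dx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }
    if stack.channel_labels:
        metadata["Channel"] = {"Name": list(stack.channel_labels)}
    # content-derived UUID so identical stacks produce identical bytes
    import hashlib
    import uuid as _uuid

    digest = hashlib.sha256(stack.data.tobytes() + repr(metadata).encode()).digest()
    metadata["UUID"] = f"urn:uuid:{_uuid.UUID(bytes=digest[:16])}"
    tifffile.imwrite(path, stack.data, ome=True, metadata=metadata)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label or probability volume from TIFF or HDF5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5_volume(path)
    return tifffile.imread(path)


def write_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Write a label mask as a 16-bit label TIFF."""
    path = Path(path)
    if labels.min() < 0:
        raise ValueError("label masks must be non-negative")
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be written as 16-bit")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    return path


def rescale_16bit(channel: np.ndarray) -> np.ndarray:
    """Linearly rescale a channel onto the full unsigned 16-bit range.

    The minimum maps to 0 and the maximum to 65535; intermediate values are
    rounded half-to-even.  A constant channel maps to all zeros (the
    degenerate min == max rule used consistently across the package).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    lo = channel.min()
    hi = channel.max()
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint16)
    scaled = (channel.astype(np.float64) - lo) * (65535.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint16)
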