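"""Image containers and OME-TIFF / CSV input-output.

The universal in-memory object is :class:`ImageVolume`: an intensity grid in
counts with canonical axis order ``(T?, C?, Z, Y, X)``, physical voxel sizes in
micrometres, and optional channel names and frame interval.  All downstream
modules consume and produce these, so physical units flow through the whole
pipeline without per-call bookkeeping.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageVolume",
    "read_volume",
    "write_volume",
    "write_measurements",
    "read_measurements",
]

_CANONICAL = "TCZYX"


@dataclass
class ImageVolume:
    """A multi-channel 2D/3D/4D fluorescence image with physical calibration.

    Parameters
    ----------
    data
        Intensity grid in detector counts. Axis order must follow ``axes``.
    voxel_size
        Physical voxel size ``(z, y, x)`` in μm. ``z`` may exceed ``y``/``x``
        (anisotropic confocal stacks).
    axes
        Subset of ``"TCZYX"`` in that order; must contain ``"ZYX"``.
    channel_names
        One name per channel when a ``C`` axis is present.
    frame_interval
        Seconds between frames when a ``T`` axis is present.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    axes: str = "ZYX"
    channel_names: tuple[str, ...] | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats (z,y,x), got {self.voxel_size}")
        if self.axes != "".join(a for a in _CANONICAL if a in set(self.axes)) or not set(
            self.axes
        ) <= set(_CANONICAL):
            raise ValueError(f"axes must be an ordered subset of {_CANONICAL!r}, got {self.axes!r}")
        if not {"Z", "Y", "X"} <= set(self.axes):
            raise ValueError("axes must contain 'ZYX'")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dims but axes {self.axes!r} declares {len(self.axes)}"
            )
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if "C" in self.axes:
            n_c = self.data.shape[self.axes.index("C")]
            if self.channel_names is not None:
                self.channel_names = tuple(self.channel_names)
                if len(self.channel_names) != n_c:
                    raise ValueError("channel_names length must match C axis")
        if "T" in self.axes and self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[self.axes.index("C")] if "C" in self.axes else 1

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axes.index("T")] if "T" in self.axes else 1

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[self.axes.index(a)] for a in "ZYX")  # type: ignore[return-value]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel's ``(Z,Y,X)`` or ``(T,Z,Y,X)`` array by name or index."""
        if "C" not in self.axes:
            if name_or_index in (0, None) or (
                self.channel_names and name_or_index == self.channel_names[0]
            ):
                return self.data
            raise KeyError(f"volume has no channel axis; cannot select {name_or_index!r}")
        if isinstance(name_or_index, str):
            if self.channel_names is None or name_or_index not in self.channel_names:
                raise KeyError(f"unknown channel {name_or_index!r}; have {self.channel_names}")
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return np.take(self.data, idx, axis=self.axes.index("C"))

    def frame(self, t: int) -> "ImageVolume":
        """Return frame ``t`` as a new volume without the T axis."""
        if "T" not in self.axes:
            raise ValueError("volume has no time axis")
        return replace(
            self,
            data=np.take(self.data, t, axis=self.axes.index("T")),
            axes=self.axes.replace("T", ""),
            frame_interval=None,
        )


def _canonicalize(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    """Reorder/expand arbitrary tifffile axes to a TCZYX subset with Z present."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    keep = [i for i, a in enumerate(axes) if a in _CANONICAL]
    # squeeze axes we do not model (e.g. singleton extras)
    for i, a in enumerate(axes):
        if a not in _CANONICAL and data.shape[i] != 1:
            raise ValueError(f"unsupported non-singleton axis {a!r} in TIFF (axes={axes!r})")
    data = data.reshape([data.shape[i] for i in keep])
    axes = "".join(axes[i] for i in keep)
    order = [axes.index(a) for a in _CANONICAL if a in axes]
    data = np.transpose(data, order)
    axes = "".join(a for a in _CANONICAL if a in axes)
    if "Z" not in axes:
        i = axes.find("Y")
        data = np.expand_dims(data, axis=i)
        axes = axes[:i] + "Z" + axes[i:]
    return data, axes


def read_volume(
    path,
    voxel_size: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
) -> ImageVolume:
    """Read a TIFF / OME-TIFF into an :class:`ImageVolume`.

    Voxel sizes are taken from OME ``PhysicalSizeX/Y/Z`` metadata; a missing
    physical size is an error unless ``voxel_size`` overrides it.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_vs: dict[str, float] = {}
        names: tuple[str, ...] | None = None
        meta_dt: float | None = None
        if tf.ome_metadata:
            root = ET.fromstring(tf.ome_metadata)

            def findall(tag):
                return [e for e in root.iter() if e.tag.rpartition("}")[2] == tag]

            pixels = findall("Pixels")
            if pixels:
                p = pixels[0]
                for key, ax in (("PhysicalSizeZ", "z"), ("PhysicalSizeY", "y"), ("PhysicalSizeX", "x")):
                    if key in p.attrib:
                        meta_vs[ax] = float(p.attrib[key])
                if "TimeIncrement" in p.attrib:
                    meta_dt = float(p.attrib["TimeIncrement"])
                ch = [e.attrib.get("Name") for e in findall("Channel")]
                if ch and all(c is not None for c in ch):
                    names = tuple(ch)
    data, axes = _canonicalize(data, axes)
    if names is not None and "C" not in axes and len(names) == 1:
        # tifffile squeezes a singleton channel axis; restore it
        data = np.expand_dims(data, axis=1 if "T" in axes else 0)
        axes = (axes[:1] + "C" + axes[1:]) if "T" in axes else "C" + axes
    if voxel_size is None:
        missing = [ax for ax in ("z", "y", "x") if ax not in meta_vs]
        # a 2D plane carries no Z size; reuse 1.0 only for the synthetic Z axis
        if missing == ["z"] and data.shape[axes.index("Z")] == 1:
            meta_vs["z"] = 1.0
            missing = []
        if missing:
            raise ValueError(
                f"{path}: missing physical voxel size for axis/axes {missing}; "
                "pass voxel_size=(z, y, x) to override"
            )
        voxel_size = (meta_vs["z"], meta_vs["y"], meta_vs["x"])
    return ImageVolume(
        data=data,
        voxel_size=voxel_size,
        axes=axes,
        channel_names=names,
        frame_interval=frame_interval if frame_interval is not None else meta_dt,
    )


def write_volume(volume: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` to OME-TIFF with physical calibration."""
    vz, vy, vx = volume.voxel_size
    metadata: dict = {
        "axes": volume.axes,
        "PhysicalSizeZ": vz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": vy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": vx,
        "PhysicalSizeXUnit": "µm",
    }
    if volume.channel_names is not None:
        metadata["Channel"] = {"Name": list(volume.channel_names)}
    if volume.frame_interval is not None:
        metadata["TimeIncrement"] = volume.frame_interval
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, volume.data, ome=True, metadata=metadata)


def write_measurements(
    records: Sequence[Mapping] | pd.DataFrame,
    path,
    provenance: Mapping[str, str] | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write measurement records as CSV with full float precision.

    ``records`` must share one schema.  ``columns`` supplies the header when
    the record list is empty.  Provenance (config hash, package version) is
    embedded as ``#``-prefixed comment lines above the header.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            keys = set(records[0].keys())
            for r in records:
                if set(r.keys()) != keys:
                    raise ValueError("mixed record schemas; all records must share one key set")
        df = pd.DataFrame.from_records(records, columns=columns if not records else None)
    buf = io.StringIO()
    if provenance:
        for k, v in provenance.items():
            buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path, comment="#")
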