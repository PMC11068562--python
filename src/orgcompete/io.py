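"""Image stack I/O and region handling.

The in-memory convention for all pipeline stages is a five-dimensional
array ordered ``(T, C, Z, Y, X)`` with singleton axes allowed, physical
voxel sizes in micrometres and an optional frame interval in hours.
Readers permute whatever axis layout a file declares into this order so
that every downstream operation can rely on a single convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "OrganoidROI",
    "read_stack",
    "write_stack",
    "crop_roi",
    "max_project",
    "read_roi_table",
]

_CANONICAL_AXES = "TCZYX"


@dataclass
class ImageStack:
    """Multi-channel 3D (or 4D time-lapse) voxel data with geometry.

    Parameters
    ----------
    voxels
        Intensity array of shape ``(T, C, Z, Y, X)``.
    voxel_size
        Physical voxel extent in µm, ordered ``(z, y, x)``.
    channel_names
        One name per channel-axis entry.
    bit_depth
        Acquisition bit depth (8, 12 or 16).  12-bit data lives in
        16-bit containers; the declared depth governs clipping.
    frame_interval_h
        Time between frames in hours, or ``None`` for a single frame.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=lambda: ["ch0"])
    bit_depth: int = 16
    frame_interval_h: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 5:
            raise ValueError(
                f"voxels must be 5D (T, C, Z, Y, X); got shape {self.voxels.shape}"
            )
        if len(self.channel_names) != self.voxels.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[1]} channels"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {vs}")
        self.voxel_size = vs
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[2:]

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        return float(np.prod(self.voxel_size))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def get_channel(self, name: str, frame: int = 0) -> np.ndarray:
        """Return one (Z, Y, X) volume for a named channel."""
        return self.voxels[frame, self.channel_index(name)]


@dataclass(frozen=True)
class OrganoidROI:
    """Axis-aligned bounding box of one organoid, in voxel indices.

    Indices are 0-based and half-open per axis: ``z0 <= z < z1`` etc.
    """

    organoid_id: str
    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        for lo, hi, ax in ((self.z0, self.z1, "z"), (self.y0, self.y1, "y"),
                           (self.x0, self.x1, "x")):
            if lo < 0 or hi <= lo:
                raise ValueError(
                    f"empty or negative ROI on axis {ax}: [{lo}, {hi})"
                )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1), slice(self.y0, self.y1),
                slice(self.x0, self.x1))


def _parse_ome_geometry(ome_xml: str):
    """Extract voxel size (z, y, x) µm and channel names from OME-XML."""

    def _phys(axis: str) -> float | None:
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        return float(m.group(1)) if m else None

    sz, sy, sx = _phys("Z"), _phys("Y"), _phys("X")
    voxel_size = (sz, sy, sx) if None not in (sz, sy, sx) else None
    names = re.findall(r'<Channel[^>]*\bName="([^"]+)"', ome_xml)
    m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', ome_xml)
    interval = float(m.group(1)) if m else None
    return voxel_size, names or None, interval


def read_stack(
    path: str | Path,
    axis_order_hint: str | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
    bit_depth: int | None = None,
    frame_interval_h: float | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF file into the canonical (T, C, Z, Y, X) order.

    Geometry is taken from embedded OME metadata when present; a plain
    TIFF requires ``voxel_size`` (µm) to be supplied explicitly.  Explicit
    arguments always override embedded metadata.

    Raises
    ------
    ValueError
        If the file is not a readable TIFF, the axis layout cannot be
        determined, or no voxel size is available from any source.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = axis_order_hint or series.axes
            ome = tif.ome_metadata
    except (tifffile.TiffFileError, IndexError, IsADirectoryError,
            FileNotFoundError) as exc:
        raise ValueError(f"cannot read {path} as a TIFF stack: {exc}") from exc

    # samples (S) are channels; unlabelled page axes (Q/I) are Z slices
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if len(axes) != data.ndim:
        raise ValueError(
            f"axis label {axes!r} does not match array of {data.ndim} dims"
        )
    unknown = set(axes) - set(_CANONICAL_AXES)
    if unknown:
        raise ValueError(
            f"unsupported axes {sorted(unknown)} in layout {axes!r}; "
            f"expected a subset of {_CANONICAL_AXES}"
        )
    # Expand missing axes, then permute to canonical order.
    for ax in _CANONICAL_AXES:
        if ax not in axes:
            data = np.expand_dims(data, axis=0)
            axes = ax + axes
    data = np.transpose(data, [axes.index(ax) for ax in _CANONICAL_AXES])

    meta_vs = meta_names = meta_interval = None
    if ome:
        meta_vs, meta_names, meta_interval = _parse_ome_geometry(ome)

    vs = voxel_size or meta_vs
    if vs is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass voxel_size=(z, y, x) µm"
        )
    names = channel_names or meta_names or [f"ch{i}" for i in range(data.shape[1])]
    if bit_depth is None:
        bit_depth = 8 if data.dtype == np.uint8 else 16
    return ImageStack(
        voxels=data,
        voxel_size=tuple(vs),
        channel_names=list(names),
        bit_depth=bit_depth,
        frame_interval_h=frame_interval_h
        if frame_interval_h is not None else meta_interval,
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with geometry metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sz, sy, sx = stack.voxel_size
    metadata = {
        "axes": _CANONICAL_AXES,
        "PhysicalSizeZ": sz,
        "PhysicalSizeY": sy,
        "PhysicalSizeX": sx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": stack.channel_names},
    }
    if stack.frame_interval_h is not None:
        metadata["TimeIncrement"] = stack.frame_interval_h
        metadata["TimeIncrementUnit"] = "h"
    tifffile.imwrite(path, stack.voxels, ome=True, metadata=metadata)
    return path


def crop_roi(stack: ImageStack, roi: OrganoidROI) -> ImageStack:
    """Extract one organoid's bounding box; geometry metadata is preserved."""
    nz, ny, nx = stack.shape_zyx
    if roi.z1 > nz or roi.y1 > ny or roi.x1 > nx:
        raise ValueError(
            f"ROI {roi} exceeds stack extent (Z={nz}, Y={ny}, X={nx})"
        )
    cropped = stack.voxels[(slice(None), slice(None)) + roi.slices].copy()
    return replace(stack, voxels=cropped)


def max_project(stack: ImageStack, axis: str = "Z") -> np.ndarray:
    """Maximum-intensity projection along one spatial axis.

    Returns an array with the projected axis removed, keeping the frame
    and channel axes, e.g. ``(T, C, Y, X)`` for the default Z projection.
    """
    ax = {"Z": 2, "Y": 3, "X": 4}.get(axis.upper())
    if ax is None:
        raise ValueError(f"axis must be Z, Y or X, got {axis!r}")
    return stack.voxels.max(axis=ax)


def read_roi_table(path: str | Path) -> list[OrganoidROI]:
    """Read ROI boxes from CSV columns (organoid_id, z0, z1, y0, y1, x0, x1)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["organoid_id", "z0", "z1", "y0", "y1", "x0", "x1"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table missing columns {missing}")
    return [
        OrganoidROI(str(r.organoid_id), int(r.z0), int(r.z1), int(r.y0),
                    int(r.y1), int(r.x0), int(r.x1))
        for r in df.itertuples()
    ]
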