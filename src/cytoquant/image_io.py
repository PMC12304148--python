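"""Calibrated multi-channel TIFF I/O, Z-projection and polygon ROIs.

The canonical in-memory layout is a 4-D array indexed ``(z, channel, y, x)``.
Axis order in the file is normalized on load from the TIFF series axis
metadata (ImageJ-style or shaped/OME-style strings such as ``ZCYX``,
``CYX``, ``YX``). Pixel calibration is isotropic in-plane and expressed in
micrometres per pixel; an explicit argument always wins over file metadata.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import (
    CalibrationError,
    CalibrationMissingError,
    ChannelLimitError,
    ConfigurationError,
    InputFormatError,
    RoiInvalidError,
)

MAX_CHANNELS = 5

__all__ = [
    "CalibratedImage",
    "RegionOfInterest",
    "load_image",
    "save_image",
    "project_zstack",
    "rasterize_roi",
    "read_imagej_roi",
    "MAX_CHANNELS",
]


@dataclass
class CalibratedImage:
    """A pixel stack with physical calibration.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape ``(z, channel, y, x)`` with
        ``z >= 1`` and ``1 <= channel <= 5``.
    pixel_size_um : float
        In-plane pixel size in micrometres per pixel (isotropic).
    channel_names : list of str, optional
        One name per channel; defaults to ``ch0..chN``.
    nuclear_channel_index : int
        Channel holding the nuclear stain; default 0 (channel 1 in
        one-based microscope parlance).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_names: list[str] = field(default_factory=list)
    nuclear_channel_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise InputFormatError(
                f"pixels must be 4-D (z, channel, y, x); got {self.pixels.ndim}-D"
            )
        n_channels = self.pixels.shape[1]
        if not 1 <= n_channels <= MAX_CHANNELS:
            raise ChannelLimitError(
                f"{n_channels} channels; supported range is 1..{MAX_CHANNELS}"
            )
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise CalibrationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.pixel_size_um = float(self.pixel_size_um)
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise InputFormatError("pixel intensities must be finite")
            if np.any(self.pixels < 0):
                raise InputFormatError("pixel intensities must be >= 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_channels)]
        if len(self.channel_names) != n_channels:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if not 0 <= self.nuclear_channel_index < n_channels:
            raise ConfigurationError(
                f"nuclear_channel_index {self.nuclear_channel_index} outside 0..{n_channels - 1}"
            )

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def plane(self, channel: int) -> np.ndarray:
        """2-D view of one channel; requires a single-plane image."""
        if self.n_z != 1:
            raise ConfigurationError("plane() requires z=1; project the stack first")
        return self.pixels[0, channel]


@dataclass(frozen=True)
class RegionOfInterest:
    """Closed polygon in pixel coordinates ``(y, x)``, or a full-frame sentinel.

    ``vertices is None`` means the whole frame. Otherwise at least 3
    distinct vertices forming a simple (non-self-intersecting) polygon
    with non-zero area are required.
    """

    vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.vertices is None:
            return
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise RoiInvalidError(f"polygon vertices must be (N, 2); got {verts.shape}")
        if len(np.unique(verts, axis=0)) < 3:
            raise RoiInvalidError("polygon needs at least 3 distinct vertices")
        poly = Polygon([(x, y) for y, x in verts])
        if not poly.is_valid:
            raise RoiInvalidError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise RoiInvalidError("polygon has zero area")
        object.__setattr__(self, "vertices", verts)

    @classmethod
    def full_frame(cls) -> "RegionOfInterest":
        return cls(vertices=None)

    @property
    def is_full_frame(self) -> bool:
        return self.vertices is None


def _axes_to_zcyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Normalize a tifffile series to (z, channel, y, x)."""
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise InputFormatError(f"axis string {axes!r} does not match {data.ndim}-D data")
    # tifffile uses I/Q for unspecified stack axes; T is out of scope.
    alias = {"I": "Z", "Q": "Z", "S": "C"}
    axes = "".join(alias.get(a, a) for a in axes)
    if "T" in axes:
        i = axes.index("T")
        if data.shape[i] != 1:
            raise InputFormatError("time series are not supported")
        data = np.squeeze(data, axis=i)
        axes = axes.replace("T", "")
    for a in set(axes):
        if a not in "ZCYX":
            raise InputFormatError(f"unsupported axis {a!r} in TIFF axes {axes!r}")
    if "Y" not in axes or "X" not in axes:
        raise InputFormatError(f"TIFF axes {axes!r} lack Y/X")
    for missing in ("Z", "C"):
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "ZCYX"]
    return np.transpose(data, order)


def _rational(value) -> float:
    if isinstance(value, tuple):
        num, den = value
        return num / den if den else 0.0
    return float(value)


def _calibration_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in µm from resolution tags; None when absent.

    Accepts ImageJ-style files (ResolutionUnit NONE + ``unit`` metadata)
    and plain TIFFs with inch/centimetre resolution units. Raises on
    anisotropic in-plane resolution.
    """
    page = tif.pages[0]
    xres_tag = page.tags.get("XResolution")
    yres_tag = page.tags.get("YResolution")
    if xres_tag is None or yres_tag is None:
        return None
    xres = _rational(xres_tag.value)
    yres = _rational(yres_tag.value)
    if xres <= 0 or yres <= 0:
        return None
    if not np.isclose(xres, yres, rtol=1e-6):
        raise CalibrationError(
            f"anisotropic in-plane calibration (XResolution {xres} != YResolution {yres})"
        )
    unit_tag = page.tags.get("ResolutionUnit")
    unit_code = getattr(unit_tag, "value", None)
    unit_code = getattr(unit_code, "value", unit_code)  # enum -> int
    ij_unit = None
    if tif.imagej_metadata:
        ij_unit = tif.imagej_metadata.get("unit")
    elif tif.shaped_metadata:
        ij_unit = tif.shaped_metadata[0].get("unit")
    if ij_unit in {"um", "µm", "micron", "micrometer", "micrometre"}:
        return 1.0 / xres
    if unit_code == 2:  # inch
        return 25400.0 / xres
    if unit_code == 3:  # centimetre
        return 10000.0 / xres
    # resolution tags without a physical unit (tifffile's default (1, 1)
    # placeholder included) carry no calibration
    return None


def load_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    nuclear_channel: int = 0,
    channel_names: Sequence[str] | None = None,
) -> CalibratedImage:
    """Load a TIFF into the canonical ``(z, channel, y, x)`` layout.

    No projection is applied: a 3-slice stack keeps ``z=3``. Calibration
    precedence is ``pixel_size_um`` argument > TIFF resolution metadata;
    with neither, :class:`CalibrationMissingError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta_cal = _calibration_from_tiff(tif)
    except CalibrationError:
        raise
    except (tifffile.TiffFileError, ValueError, struct.error) as exc:
        raise InputFormatError(f"{path} is not a readable TIFF: {exc}") from exc
    data = _axes_to_zcyx(data, axes)
    n_channels = data.shape[1]
    if n_channels > MAX_CHANNELS:
        raise ChannelLimitError(
            f"{path}: {n_channels} channels; at most {MAX_CHANNELS} are supported"
        )
    if pixel_size_um is None:
        pixel_size_um = meta_cal
    if pixel_size_um is None:
        raise CalibrationMissingError(
            f"{path}: no pixel_size_um given and no resolution metadata in file"
        )
    return CalibratedImage(
        pixels=data,
        pixel_size_um=float(pixel_size_um),
        channel_names=list(channel_names) if channel_names else [],
        nuclear_channel_index=nuclear_channel,
    )


def save_image(image: CalibratedImage, path: str | Path) -> Path:
    """Write the image as a TIFF with ZCYX axis metadata and µm resolution.

    Integer dtypes round-trip bit-exactly through :func:`load_image`.
    """
    path = Path(path)
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path,
        image.pixels,
        metadata={"axes": "ZCYX", "unit": "um"},
        resolution=(res, res),
        photometric="minisblack",
    )
    return path


def project_zstack(image: CalibratedImage, method: str = "max") -> CalibratedImage:
    """Collapse the z axis by pixelwise maximum or arithmetic mean.

    A ``z=1`` image is returned unchanged for either method.
    """
    if method not in ("max", "mean"):
        raise ConfigurationError(f"unknown projection method {method!r}; use 'max' or 'mean'")
    if image.n_z == 1:
        return image
    if method == "max":
        projected = image.pixels.max(axis=0, keepdims=True)
    else:
        projected = image.pixels.mean(axis=0, keepdims=True)
    return CalibratedImage(
        pixels=projected,
        pixel_size_um=image.pixel_size_um,
        channel_names=list(image.channel_names),
        nuclear_channel_index=image.nuclear_channel_index,
    )


def rasterize_roi(roi: RegionOfInterest, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside (or on) the polygon.

    Parameters
    ----------
    roi : RegionOfInterest
    shape : (height, width) of the target grid; a :class:`CalibratedImage`
        may be passed instead.
    """
    if isinstance(shape, CalibratedImage):
        shape = shape.frame_shape
    h, w = shape
    if roi.is_full_frame:
        return np.ones((h, w), dtype=bool)
    poly = Polygon([(x, y) for y, x in roi.vertices])
    yy, xx = np.mgrid[0:h, 0:w]
    pts = shapely.points(xx.ravel(), yy.ravel())
    inside = shapely.covers(poly, pts)  # covers() includes the boundary
    return inside.reshape(h, w)


def read_imagej_roi(path: str | Path) -> RegionOfInterest:
    """Parse a binary ImageJ ``.roi`` file (polygon type only).

    The format begins with the magic ``Iout``; polygon vertices are stored
    as int16 offsets from the bounding-box top/left corner.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 64 or raw[:4] != b"Iout":
        raise InputFormatError(f"{path} is not an ImageJ .roi file")
    roi_type = raw[6]
    if roi_type != 0:  # 0 = polygon
        raise RoiInvalidError(f"{path}: only polygon ROIs are supported (type {roi_type})")
    top, left = struct.unpack(">hh", raw[8:12])
    (n,) = struct.unpack(">h", raw[16:18])
    if n < 3:
        raise RoiInvalidError(f"{path}: polygon has only {n} vertices")
    xs = struct.unpack(f">{n}h", raw[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", raw[64 + 2 * n : 64 + 4 * n])
    verts = np.array([(top + y, left + x) for x, y in zip(xs, ys)], dtype=float)
    return RegionOfInterest(vertices=verts)
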