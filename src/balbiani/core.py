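"""Calibrated image containers, TIFF I/O and preprocessing filters.

The quantification pipelines operate on multi-channel confocal z-stacks
(DAPI / DiOC6 / Buc / cytokeratin).  Everything downstream works in
physical units, so every pixel container carries a :class:`PixelCalibration`.

Preprocessing follows the standard confocal workflow: rolling-ball
background subtraction and a disk median filter applied slice-wise,
followed by a sum z-projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import restoration
from skimage.measure import block_reduce
from skimage.morphology import disk
from skimage.transform import resize

__all__ = [
    "PixelCalibration",
    "ImageStack",
    "Image2D",
    "BinaryMask",
    "read_image_stack",
    "write_image_stack",
    "z_project",
    "z_project_sum",
    "subtract_background",
    "median_filter",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel size: XY sampling (µm/px) and z-step (µm/slice)."""

    xy_um_per_px: float = 0.35
    z_um_per_slice: float = 1.0

    def __post_init__(self) -> None:
        for name in ("xy_um_per_px", "z_um_per_slice"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def px_area_um2(self) -> float:
        return self.xy_um_per_px ** 2

    def um_to_px(self, um: float) -> float:
        return um / self.xy_um_per_px

    def px_to_um(self, px: float) -> float:
        return px * self.xy_um_per_px


@dataclass
class ImageStack:
    """Multi-channel z-stack, axes ``(channel, z, y, x)``, intensities >= 0."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError(f"expected (channel, z, y, x) array, got ndim={self.data.ndim}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.data.shape[2] < 16 or self.data.shape[3] < 16:
            raise ValueError("y and x dimensions must be at least 16 pixels")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """(z, y, x) view of one channel."""
        return self.data[self.channel_index(name)]


@dataclass
class Image2D:
    """Single calibrated 2-D plane (e.g. a z-projection)."""

    data: np.ndarray
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"expected 2-D array, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean region mask sharing the geometry of its source image."""

    data: np.ndarray
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"expected 2-D mask, got ndim={self.data.ndim}")

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def area_um2(self) -> float:
        return self.area_px * self.calibration.px_area_um2

    def equivalent_diameter_um(self) -> float:
        """Diameter of the circle with the same area, 2*sqrt(A/pi)."""
        return 2.0 * np.sqrt(self.area_um2 / np.pi)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _normalise_axes(arr: np.ndarray, axes: str, n_channels: int) -> np.ndarray:
    """Reorder/expand a tifffile series to (C, Z, Y, X)."""
    axes = axes.upper()
    if len(axes) != arr.ndim:
        axes = "Q" * (arr.ndim - len(axes)) + axes
    # squeeze singleton axes we do not model (time, samples, ...)
    keep = []
    for i, ax in enumerate(axes):
        if ax in "CZYX":
            keep.append(i)
        elif arr.shape[i] == 1:
            continue
        elif ax in ("Q", "I", "T", "S"):
            # unnamed stack axis: interpret as channel if it matches the
            # declared channel count, else as z
            keep.append(i)
        else:
            raise ValueError(f"cannot interpret TIFF axis {ax!r} of size {arr.shape[i]}")
    arr = np.transpose(arr, keep + [i for i in range(arr.ndim) if i not in keep])
    arr = arr.reshape(arr.shape[: len(keep)])
    axes = "".join(axes[i] for i in keep)

    # resolve ambiguous axes
    resolved = ""
    for i, ax in enumerate(axes):
        if ax in "CZYX":
            resolved += ax
        else:
            resolved += "C" if ("C" not in axes and arr.shape[i] == n_channels) else "Z"
    axes = resolved
    if "Y" not in axes or "X" not in axes:
        # plain 2-D/3-D files report no axes string; assume trailing YX
        trail = list("YX")[::-1]
        axes_list = list(axes)
        for j in range(len(axes_list) - 1, -1, -1):
            if axes_list[j] not in "YX" and trail:
                axes_list[j] = trail.pop()
        axes = "".join(axes_list)

    for ax in "CZ":
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(arr, order)


def read_image_stack(
    path: str | Path,
    channel_names: tuple[str, ...] | list[str],
    calibration: PixelCalibration | None = None,
    fallback_calibration: PixelCalibration | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into a (channel, z, y, x) :class:`ImageStack`.

    ``channel_names`` declares the channel order; its length must match the
    channel axis of the file.  Single-plane files are promoted to z-length 1.
    An explicit ``calibration`` overrides everything; otherwise OME
    pixel-size metadata is used when present, then ``fallback_calibration``
    (e.g. from a run configuration), then library defaults.
    """
    path = Path(path)
    channel_names = tuple(channel_names)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            arr = series.asarray()
            axes = series.axes
            ome_cal = _ome_calibration(tif)
    except (tifffile.TiffFileError, FileNotFoundError, IndexError) as exc:
        raise OSError(f"cannot read TIFF file {path}: {exc}") from exc
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric pixel type {arr.dtype} in {path}")
    data = _normalise_axes(np.asarray(arr), axes, len(channel_names))
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: file has {data.shape[0]} channels but "
            f"{len(channel_names)} names declared"
        )
    if calibration is None:
        calibration = ome_cal or fallback_calibration or PixelCalibration()
    return ImageStack(data.astype(np.float64), channel_names, calibration)


def _ome_calibration(tif: "tifffile.TiffFile") -> PixelCalibration | None:
    if not tif.is_ome:
        return None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        x = float(px.get("PhysicalSizeX"))
        z = float(px.get("PhysicalSizeZ", 1.0))
        return PixelCalibration(xy_um_per_px=x, z_um_per_slice=z)
    except (TypeError, ValueError, AttributeError):
        return None


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as 32-bit float OME-TIFF with calibration."""
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.calibration.xy_um_per_px,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.calibration.xy_um_per_px,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.calibration.z_um_per_slice,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def z_project(
    stack: ImageStack,
    channel: str,
    z_range: tuple[int, int] | None = None,
    mode: str = "sum",
) -> Image2D:
    """Project a channel over an inclusive slice interval.

    SUM projection is the default; MAX is available via ``mode='max'``.
    """
    planes = stack.channel(channel)
    if z_range is None:
        z_range = (0, stack.n_slices - 1)
    lo, hi = z_range
    if not (0 <= lo <= hi < stack.n_slices):
        raise ValueError(f"z_range {z_range} outside [0, {stack.n_slices - 1}]")
    sel = planes[lo : hi + 1]
    if mode == "sum":
        out = sel.sum(axis=0)
    elif mode == "max":
        out = sel.max(axis=0)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return Image2D(out, stack.calibration)


def z_project_sum(
    stack: ImageStack, channel: str, z_range: tuple[int, int] | None = None
) -> Image2D:
    """Per-pixel sum over the selected slices of one channel."""
    return z_project(stack, channel, z_range, mode="sum")


def subtract_background(image: Image2D, ball_radius_px: int = 50) -> Image2D:
    """Rolling-ball background subtraction, clamped at zero.

    The background is the grayscale opening of the image by a ball structuring
    element of the given radius.  For radii >= 16 the estimate is computed on
    a 4x min-reduced image and upsampled (the classic large-radius shortcut),
    which leaves bright structures smaller than the ball untouched while
    removing slowly varying background.
    """
    if ball_radius_px < 1:
        raise ValueError("ball_radius_px must be >= 1")
    if ball_radius_px > min(image.shape):
        raise ValueError(
            f"ball radius {ball_radius_px} exceeds the smallest image "
            f"dimension {min(image.shape)}"
        )
    data = image.data
    if ball_radius_px >= 16:
        s = 4
        pad_y = (-data.shape[0]) % s
        pad_x = (-data.shape[1]) % s
        padded = np.pad(data, ((0, pad_y), (0, pad_x)), mode="edge")
        small = block_reduce(padded, (s, s), np.min)
        bg_small = restoration.rolling_ball(small, radius=ball_radius_px / s)
        bg = resize(bg_small, padded.shape, order=1, anti_aliasing=False)
        bg = bg[: data.shape[0], : data.shape[1]]
    else:
        bg = restoration.rolling_ball(data, radius=ball_radius_px)
    bg = np.minimum(bg, data)
    return Image2D(np.clip(data - bg, 0, None), image.calibration)


def median_filter(image: Image2D, radius_px: int = 5) -> Image2D:
    """Disk-neighbourhood median filter with reflective edge padding."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint = disk(radius_px)
    out = ndimage.median_filter(image.data, footprint=footprint, mode="reflect")
    return Image2D(out, image.calibration)


def preprocess_plane(
    plane: Image2D, ball_radius_px: int = 50, median_radius_px: int = 5
) -> Image2D:
    """Background subtraction followed by median filtering (the standard order).

    A radius of 0 skips the corresponding step (used for channels whose
    structures would not survive it, e.g. diffraction-limited spots).
    """
    out = plane
    if ball_radius_px > 0:
        out = subtract_background(out, ball_radius_px)
    if median_radius_px > 0:
        out = median_filter(out, median_radius_px)
    return out
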