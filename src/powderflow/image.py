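"""Image ingestion, grayscale handling, ROI resolution and histograms.

All downstream flow metrics operate on three light-weight containers:
:class:`GrayImage` (the raw intensity grid), :class:`RegionMask` (a binary
per-pixel region such as the illuminated background ROI, the segmented powder
pattern, or detected agglomerates) and :class:`Histogram` (256-bin intensity
counts over a mask).

Conventions
-----------
* Pixel coordinates are 0-based, row-major, origin at the top-left.
* Rectangles are half-open: ``(x0, y0, w, h)`` covers columns
  ``[x0, x0+w)`` and rows ``[y0, y0+h)``.
* 16-bit images are histogrammed into 256 bins by integer division of the
  intensity by 256, so thresholding behaves identically across bit depths.
* RGB input is converted to luminance with Rec. 709 weights
  (0.2126 R + 0.7152 G + 0.0722 B), the standard for digital camera output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ContractError, FormatError

__all__ = [
    "GrayImage",
    "RegionMask",
    "Histogram",
    "load_image",
    "save_image",
    "load_mask",
    "histogram",
    "resolve_roi",
    "rgb_to_luminance",
]

# Rec. 709 luma weights for RGB -> grayscale conversion.
_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

N_BINS = 256


@dataclass(frozen=True)
class GrayImage:
    """A single-channel image with an explicit bit depth (8 or 16).

    Parameters
    ----------
    pixels
        2-D array of dtype uint8 (``bit_depth=8``) or uint16 (``bit_depth=16``),
        row-major, values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ContractError(f"pixels must be a non-empty 2-D grid, got shape {px.shape}")
        if self.bit_depth == 8:
            expected = np.uint8
        elif self.bit_depth == 16:
            expected = np.uint16
        else:
            raise ContractError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.dtype != expected:
            raise ContractError(
                f"dtype {px.dtype} inconsistent with bit_depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def bin_indices(self) -> np.ndarray:
        """Map intensities onto the 256 histogram bins (identity for 8-bit)."""
        if self.bit_depth == 8:
            return self.pixels
        return (self.pixels // 256).astype(np.uint8)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GrayImage":
        """Wrap an integer array, inferring bit depth from its dtype."""
        arr = np.asarray(arr)
        if arr.dtype == np.uint16:
            return cls(arr, bit_depth=16)
        return cls(np.asarray(arr, dtype=np.uint8), bit_depth=8)


@dataclass(frozen=True)
class RegionMask:
    """Binary per-pixel membership with the same shape as the image it annotates."""

    members: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.members, dtype=bool)
        if m.ndim != 2:
            raise ContractError(f"mask must be 2-D, got shape {m.shape}")
        object.__setattr__(self, "members", m)

    @property
    def height(self) -> int:
        return self.members.shape[0]

    @property
    def width(self) -> int:
        return self.members.shape[1]

    @property
    def count(self) -> int:
        return int(self.members.sum())

    def is_subset_of(self, other: "RegionMask") -> bool:
        return bool(np.all(~self.members | other.members))

    @classmethod
    def full(cls, height: int, width: int) -> "RegionMask":
        return cls(np.ones((height, width), dtype=bool))

    @classmethod
    def empty(cls, height: int, width: int) -> "RegionMask":
        return cls(np.zeros((height, width), dtype=bool))


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram taken over a mask."""

    counts: np.ndarray  # shape (256,), int64

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_BINS,):
            raise ContractError(f"histogram must have {N_BINS} bins, got {c.shape}")
        if np.any(c < 0):
            raise ContractError("histogram counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


def rgb_to_luminance(rgb: np.ndarray, max_value: int) -> np.ndarray:
    """Convert an (H, W, 3) array to rounded integer luminance."""
    lum = np.tensordot(rgb.astype(np.float64), _LUMA_WEIGHTS, axes=([-1], [0]))
    return np.clip(np.rint(lum), 0, max_value).astype(rgb.dtype)


def load_image(path: str | os.PathLike) -> GrayImage:
    """Read a PNG or TIFF image as a :class:`GrayImage`.

    Single-channel input is passed through; RGB is converted to Rec. 709
    luminance. 16-bit input keeps ``bit_depth = 16``.
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise reader backends
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise FormatError(
                f"{path!r}: unsupported channel layout {arr.shape}; "
                "expected single-channel or RGB"
            )
        max_value = 65535 if arr.dtype == np.uint16 else 255
        arr = rgb_to_luminance(arr, max_value)
    elif arr.ndim != 2:
        raise FormatError(f"{path!r}: unsupported image shape {arr.shape}")
    if arr.dtype == np.uint16:
        return GrayImage(arr, bit_depth=16)
    if arr.dtype != np.uint8:
        raise FormatError(f"{path!r}: unsupported sample type {arr.dtype}")
    return GrayImage(arr, bit_depth=8)


def save_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write a :class:`GrayImage` to PNG or TIFF losslessly.

    TIFF output is byte-deterministic (no timestamp tags), so re-generating a
    fixture with the same seed reproduces the identical file.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    elif ext == ".png":
        iio.imwrite(path, image.pixels, extension=".png")
    else:
        raise FormatError(f"unsupported output format {ext!r}; use .png/.tif/.tiff")


def load_mask(path: str | os.PathLike) -> RegionMask:
    """Read a mask image; any nonzero pixel is a member."""
    img = load_image(path)
    return RegionMask(img.pixels > 0)


def histogram(image: GrayImage, mask: RegionMask) -> Histogram:
    """256-bin histogram of the image restricted to ``mask``.

    The bin total equals the mask member count exactly (conservation is the
    basis of every area-fraction metric downstream).
    """
    if mask.members.shape != image.pixels.shape:
        raise ContractError(
            f"mask shape {mask.members.shape} does not match image {image.pixels.shape}"
        )
    vals = image.bin_indices()[mask.members]
    counts = np.bincount(vals.ravel(), minlength=N_BINS).astype(np.int64)
    return Histogram(counts)


def resolve_roi(
    image: GrayImage,
    roi_spec: RegionMask | tuple[int, int, int, int] | None = None,
) -> RegionMask:
    """Resolve a region-of-interest specification against an image.

    ``None`` yields the full frame (the default reading of the illuminated
    background area); a rectangle ``(x0, y0, w, h)`` is clipped to the frame;
    an explicit :class:`RegionMask` is passed through after a dimension check.
    """
    h, w = image.pixels.shape
    if roi_spec is None:
        return RegionMask.full(h, w)
    if isinstance(roi_spec, RegionMask):
        if roi_spec.members.shape != (h, w):
            raise ContractError(
                f"ROI mask shape {roi_spec.members.shape} does not match image {(h, w)}"
            )
        return roi_spec
    x0, y0, rw, rh = (int(v) for v in roi_spec)
    if rw <= 0 or rh <= 0:
        raise ContractError(f"rectangle must have positive size, got w={rw}, h={rh}")
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1, cy1 = min(x0 + rw, w), min(y0 + rh, h)
    if cx0 >= cx1 or cy0 >= cy1:
        raise ContractError(
            f"rectangle ({x0},{y0},{rw},{rh}) lies fully outside the {w}x{h} frame"
        )
    m = np.zeros((h, w), dtype=bool)
    m[cy0:cy1, cx0:cx1] = True
    return RegionMask(m)
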