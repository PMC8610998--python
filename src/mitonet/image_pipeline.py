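"""Loading, enhancement and segmentation of two-channel nucleoid images.

The mitochondrial channel (TMRM / MitoTracker) is enhanced with a
Hessian-based tubeness filter and segmented with a single global threshold;
the DNA channel (PicoGreen / TFAM) has the nucleus zeroed out from a
user-supplied mask before nucleoid detection. Nucleus and cell masks are
inputs -- no automatic nucleus segmentation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ImageSet",
    "BinaryMask",
    "tubeness_filter",
    "global_threshold",
    "remove_nucleus",
    "to_8bit",
    "load_image_set",
]


@dataclass
class BinaryMask:
    """A boolean pixel grid with its physical pixel size (um/px)."""

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")


@dataclass
class ImageSet:
    """Two-channel field of view: mitochondria + nucleoids, optional masks."""

    mito_channel: np.ndarray
    nucleoid_channel: np.ndarray
    pixel_size: float
    nucleus_mask: BinaryMask | None = None
    cell_mask: BinaryMask | None = None

    def __post_init__(self):
        self.mito_channel = np.asarray(self.mito_channel, dtype=float)
        self.nucleoid_channel = np.asarray(self.nucleoid_channel, dtype=float)
        if self.mito_channel.ndim != 2 or self.nucleoid_channel.ndim != 2:
            raise ValueError("channels must be 2-D")
        if self.mito_channel.shape != self.nucleoid_channel.shape:
            raise ValueError("channel dimensions differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for m in (self.nucleus_mask, self.cell_mask):
            if m is not None and m.grid.shape != self.mito_channel.shape:
                raise ValueError("mask dimensions differ from channels")


def tubeness_filter(image: np.ndarray, scale: float = 2.0) -> np.ndarray:
    """Hessian ridge-enhancement (tubeness) response at a single scale.

    The response at each pixel is ``scale**2 * |lambda2|`` where lambda2 is
    the smaller Hessian eigenvalue, kept only where lambda2 < 0 (bright
    ridges on dark background), so flat and blob-free regions give 0. Adding
    a constant to the image leaves the response unchanged.
    """
    from skimage.feature import hessian_matrix, hessian_matrix_eigvals

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("tubeness_filter expects a 2-D image")
    if scale <= 0:
        raise ValueError("scale must be positive")
    H = hessian_matrix(
        image, sigma=scale, order="rc", mode="reflect", use_gaussian_derivatives=False
    )
    eigvals = hessian_matrix_eigvals(H)  # sorted descending; [-1] most negative
    lam2 = eigvals[-1]
    resp = np.where(lam2 < 0, -lam2, 0.0) * scale**2
    return resp


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to the 0..255 uint8 range (constant image -> 0)."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return np.round((image - lo) / (hi - lo) * 255).astype(np.uint8)


def global_threshold(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Segment with one whole-image threshold; mask = pixels >= threshold.

    "otsu" (default) maximizes between-class variance on the image after
    8-bit min-max conversion, so thresholds are reproducible regardless of
    the camera's dynamic range. "manual" applies ``threshold`` directly to
    the raw intensities.
    """
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("global_threshold expects a 2-D image")
    if method == "manual":
        if threshold is None:
            raise ValueError("manual method requires a threshold value")
        return BinaryMask(image >= threshold, pixel_size)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("cannot auto-threshold a constant image")
        img8 = to_8bit(image)
        t = threshold_otsu(img8)
        # skimage's threshold is the top of the background class; the mask is
        # every pixel at or above the next intensity level
        return BinaryMask(img8 > t, pixel_size)
    raise ValueError(f"unknown threshold method: {method!r}")


def remove_nucleus(nucleoid_channel: np.ndarray, nucleus_mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Zero every pixel inside the nucleus mask; all others are unchanged."""
    channel = np.asarray(nucleoid_channel, dtype=float).copy()
    grid = nucleus_mask.grid if isinstance(nucleus_mask, BinaryMask) else np.asarray(nucleus_mask, bool)
    if grid.shape != channel.shape:
        raise ValueError("nucleus mask dimensions differ from channel")
    channel[grid] = 0.0
    return channel


def load_image_set(
    mito_path: str | Path,
    nucleoid_path: str | Path | None,
    pixel_size: float,
    nucleus_mask_path: str | Path | None = None,
    cell_mask_path: str | Path | None = None,
) -> ImageSet:
    """Read channels from TIFF.

    If ``nucleoid_path`` is None, ``mito_path`` must be a multi-page TIFF
    with the mitochondrial channel on page 0 and the DNA channel on page 1.
    Masks are read as any nonzero pixel.
    """
    import tifffile

    mito_path = Path(mito_path)
    if not mito_path.exists():
        raise FileNotFoundError(str(mito_path))
    data = tifffile.imread(mito_path)
    if nucleoid_path is None:
        if data.ndim != 3 or data.shape[0] < 2:
            raise ValueError("expected a multi-page TIFF with >= 2 channels")
        mito, nucl = data[0], data[1]
    else:
        nucleoid_path = Path(nucleoid_path)
        if not nucleoid_path.exists():
            raise FileNotFoundError(str(nucleoid_path))
        mito, nucl = data, tifffile.imread(nucleoid_path)

    def _read_mask(p):
        if p is None:
            return None
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(str(p))
        from imageio.v3 import imread as iio_imread

        arr = iio_imread(p) if p.suffix.lower() == ".png" else tifffile.imread(p)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return BinaryMask(arr > 0, pixel_size)

    return ImageSet(
        mito_channel=mito,
        nucleoid_channel=nucl,
        pixel_size=pixel_size,
        nucleus_mask=_read_mask(nucleus_mask_path),
        cell_mask=_read_mask(cell_mask_path),
    )
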