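"""Grayscale conversion and binarization of stained histology images.

The stain of interest (pan-cytokeratin, dark) sits on a light background, so
*foreground* is always the dark side of a threshold: a pixel belongs to the
mask when its intensity lies in ``[0, T]`` inclusive.  Thresholds are either
fixed (the batch settings 220, 240, 250) or automatic per image (iterative
intermeans / IsoData on the intensity histogram).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "BinaryMask",
    "to_gray8",
    "threshold_fixed",
    "threshold_auto",
    "binarize",
    "read_image",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Physical edge length of one pixel, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 1.4

# ITU-R 601 luminance weights used for RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale raster with a physical pixel size.

    Parameters
    ----------
    data : ndarray of uint8, shape (rows, cols)
        Intensity values in [0, 255].
    pixel_size_um : float
        Edge length of one pixel in micrometres (> 0).
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D raster, got shape {d.shape}")
        if d.dtype != np.uint8:
            if d.min() < 0 or d.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            d = d.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class BinaryMask:
    """A foreground/background raster plus the threshold that produced it."""

    data: np.ndarray
    threshold: int
    mode: str = "fixed"  # "fixed" or "auto"

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


def to_gray8(image: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Reduce a 1- or 3-channel raster to 8-bit grayscale.

    RGB input is combined with the standard luminance weighting
    ``0.299 R + 0.587 G + 0.114 B`` and rounded to the nearest integer;
    single-channel input passes through unchanged (idempotent).
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return GrayImage(arr, pixel_size_um)
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = np.rint(arr.astype(float) @ _LUMA)
        return GrayImage(np.clip(gray, 0, 255).astype(np.uint8), pixel_size_um)
    raise ValueError(
        f"unsupported channel layout {arr.shape}; expected (r, c) or (r, c, 3)"
    )


def read_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Read a PNG/TIFF image from disk and convert to :class:`GrayImage`."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return to_gray8(arr, pixel_size_um)


def threshold_fixed(img: GrayImage, T: int) -> BinaryMask:
    """Binarize with a fixed threshold: foreground = intensity in [0, T]."""
    T = int(T)
    if not 0 <= T <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {T}")
    return BinaryMask(img.data <= T, threshold=T, mode="fixed")


def threshold_auto(img: GrayImage) -> tuple[int, BinaryMask]:
    """Automatic threshold by iterative intermeans (IsoData).

    Iterates ``T <- round((mean(I <= T) + mean(I > T)) / 2)`` on the intensity
    histogram until a fixed point is reached; foreground is ``[0, T]``.  The
    result depends only on the histogram shape, so it is invariant to tiling
    or duplicating the image.

    Raises
    ------
    ValueError
        If the image is constant (no histogram valley to find).
    """
    hist = np.bincount(img.data.ravel(), minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate image: automatic threshold requires >= 2 distinct intensities")

    csum = np.cumsum(hist)
    cmom = np.cumsum(hist * levels)
    total, moment = csum[-1], cmom[-1]

    T = int(round(moment / total))
    seen = set()
    while T not in seen:
        seen.add(T)
        n_lo = csum[T]
        if n_lo == 0 or n_lo == total:
            # all mass on one side: step toward the occupied side
            occ = np.nonzero(hist)[0]
            T = int(round((occ[0] + occ[-1]) / 2))
            if T in seen:
                break
            continue
        mean_lo = cmom[T] / n_lo
        mean_hi = (moment - cmom[T]) / (total - n_lo)
        T = int(round((mean_lo + mean_hi) / 2.0))
    mask = threshold_fixed(img, T)
    return T, BinaryMask(mask.data, threshold=T, mode="auto")


def binarize(img: GrayImage, setting) -> BinaryMask:
    """Dispatch on a grid setting: ``"auto"`` or an integer threshold."""
    if setting == "auto":
        return threshold_auto(img)[1]
    return threshold_fixed(img, int(setting))
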