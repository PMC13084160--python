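"""Image preprocessing applied before quantification.

The chain mirrors a standard FIJI workflow for single-molecule FISH /
immunofluorescence images: maximum-intensity projection of z-stacks,
Gaussian blur (sigma 1 px), contrast-limited adaptive histogram
equalization (block 127 px, max slope 6), and background thresholding
(Otsu by default, manual override available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import exposure
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

__all__ = [
    "ImageScene",
    "PrepParams",
    "max_project",
    "gaussian_blur",
    "clahe",
    "threshold",
]


@dataclass
class ImageScene:
    """Multi-channel intensity grids sharing one spatial geometry.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"rna"``, ``"marker"``) to a 2D
        ``(rows, cols)`` or 3D ``(z, rows, cols)`` nonnegative array.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    z_step_um
        Axial step of the stack, if 3D.
    """

    channels: dict
    pixel_size_um: float
    z_step_um: Optional[float] = None

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim not in (2, 3):
                raise ValueError(f"channel {name!r} must be 2D or 3D, got ndim={arr.ndim}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
            shapes.add(arr.shape[-2:])
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on spatial shape: {shapes}")

    @property
    def shape(self):
        """Spatial (rows, cols) shape shared by all channels."""
        first = next(iter(self.channels.values()))
        return first.shape[-2:]


@dataclass
class PrepParams:
    """Preprocessing settings; defaults are the published analysis values."""

    blur_sigma_px: float = 1.0
    clahe_block_px: int = 127
    clahe_max_slope: float = 6.0
    threshold_mode: str = "otsu"  # "otsu" | "manual"
    manual_threshold: Optional[float] = None

    def __post_init__(self):
        if self.blur_sigma_px <= 0:
            raise ValueError("blur_sigma_px must be positive")
        if self.clahe_block_px < 3 or self.clahe_block_px % 2 == 0:
            raise ValueError("clahe_block_px must be odd and >= 3")
        if self.clahe_max_slope <= 1:
            raise ValueError("clahe_max_slope must exceed 1")
        if self.threshold_mode not in ("otsu", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a ``(z, rows, cols)`` stack.

    Each output pixel is the maximum over z of the corresponding pixel.
    A single-plane stack projects to itself.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3D (z, rows, cols) stack, got ndim={stack.ndim}")
    if stack.shape[0] < 1 or stack.size == 0:
        raise ValueError("stack has no z-planes")
    return stack.max(axis=0)


def gaussian_blur(img: np.ndarray, sigma_px: float = 1.0) -> np.ndarray:
    """Gaussian convolution with reflective boundaries.

    Reflection preserves total intensity near the borders of straightened
    neurite crops, where signal frequently touches the image edge.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("gaussian_blur expects a 2D image")
    return gaussian_filter(img, sigma=sigma_px, mode="reflect")


def clahe(img: np.ndarray, block_px: int = 127, max_slope: float = 6.0,
          nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The histogram clip limit is ``max_slope`` times the uniform bin height
    (``block_px**2 / nbins`` pixels per bin), i.e. the slope limit of the
    local cumulative transfer function. Output is a float image in [0, 1].
    Bit-parity with any particular desktop implementation is not promised;
    the contract is the clip-limited equalization itself.
    """
    if block_px < 3 or block_px % 2 == 0:
        raise ValueError("block_px must be odd and >= 3")
    if max_slope <= 1:
        raise ValueError("max_slope must exceed 1")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("clahe expects a 2D image")
    if block_px > min(img.shape):
        raise ValueError(
            f"block_px={block_px} exceeds image extent {img.shape}; "
            "use a smaller block or pad the image"
        )
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:  # constant image: nothing to equalize
        return img.copy()
    norm = (img - lo) / (hi - lo)
    # skimage's clip is clip_limit * block_pixels; ours is
    # max_slope * block_pixels / nbins, hence clip_limit = max_slope / nbins.
    return exposure.equalize_adapthist(
        norm, kernel_size=block_px, clip_limit=max_slope / nbins, nbins=nbins
    )


def threshold(img: np.ndarray, params: PrepParams | None = None) -> np.ndarray:
    """Binarize an image to separate signal from background.

    The published analysis set thresholds manually per image; the
    reproducible default here is Otsu's criterion. The realized threshold
    is logged so a manual re-run can reproduce it exactly.

    Returns a boolean grid where True marks foreground (``>= threshold``
    in manual mode, ``> otsu`` in Otsu mode, matching the usual
    convention of each method).
    """
    params = params or PrepParams()
    img = np.asarray(img, dtype=float)
    if params.threshold_mode == "manual":
        if params.manual_threshold is None:
            raise ValueError("manual threshold_mode requires manual_threshold")
        t = float(params.manual_threshold)
        out = img >= t
    else:
        if img.max() == img.min():
            raise ValueError("Otsu threshold is undefined on a constant image")
        t = float(threshold_otsu(img))
        out = img > t
    log.info("threshold mode=%s value=%g foreground=%.1f%%",
             params.threshold_mode, t, 100.0 * out.mean())
    return out
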