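"""ACER image enhancement: adaptive contrast enhancement composed with SSR.

Single-scale Retinex (SSR) models an image as reflectance times
illumination. The illumination estimate is a center-surround Gaussian
filtering of the image, and the reflectance is recovered by subtraction in
the log domain::

    r(x, y) = log(I(x, y) + eps) - log((I * G)(x, y) + eps)

with the surround kernel G proportional to exp(-(x^2 + y^2) / (2 delta^2)),
discretely normalized to unit sum so that constant images map to zero
reflectance. Adaptive contrast enhancement (ACE) splits the image into a
Gaussian low-pass part and the residual high-pass part and amplifies the
high-pass part with a locally adaptive gain ``global_std / local_std``
clipped to ``[1, cg_max]`` before recombining.

ACER runs ACE first (sharpening local detail), then SSR on the sharpened
image, and linearly rescales the log-domain output to the display range.
On CT slices the single gray channel is processed once; a 3-channel input
is processed per channel and merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .ctslice import CTSlice

__all__ = [
    "EnhanceParams",
    "gaussian_surround",
    "ssr_retinex",
    "ace_decompose",
    "ace_enhance",
    "acer",
]

#: Offset added before taking logs, on the 0-255 scale.
LOG_EPS = 1.0


@dataclass
class EnhanceParams:
    """Tunables for the ACER stages.

    delta is the surround Gaussian scale in pixels; cg_max caps the local
    contrast gain; ace_window is the odd window for local statistics;
    lowpass_sigma the ACE low-pass scale; output_range the display range
    the result is rescaled/clipped to.
    """

    delta: float = 30.0
    cg_max: float = 3.0
    ace_window: int = 15
    lowpass_sigma: float = 5.0
    output_range: tuple[float, float] = (0.0, 255.0)
    clip_percentiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.lowpass_sigma <= 0:
            raise ValueError("delta and lowpass_sigma must be positive")
        if self.ace_window < 3 or self.ace_window % 2 == 0:
            raise ValueError("ace_window must be odd and >= 3")
        if self.cg_max < 1:
            raise ValueError("cg_max must be >= 1")
        lo, hi = self.output_range
        if hi <= lo:
            raise ValueError("output_range must be increasing")


def gaussian_surround(delta: float, size: int) -> np.ndarray:
    """Discrete center-surround Gaussian kernel, normalized to unit sum.

    The unnormalized entry at offset (x, y) is
    ``exp(-(x^2 + y^2) / (2 delta^2)) / (2 pi delta^2)``; normalization makes
    the filter preserve constants on the discrete grid.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if size < 3 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernel = np.exp(-(x**2 + y**2) / (2.0 * delta**2)) / (2.0 * np.pi * delta**2)
    return kernel / kernel.sum()


def _surround_size(delta: float) -> int:
    size = int(np.ceil(6.0 * delta))
    return size + 1 if size % 2 == 0 else max(size, 3)


def _rescale(
    arr: np.ndarray,
    output_range: tuple[float, float],
    clip_percentiles: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linear map to the output range, optionally percentile-clipped first.

    Percentile clipping is the usual Retinex display mapping: it stops a few
    extreme log-ratio pixels (dark lumens next to bright walls) from
    consuming the whole dynamic range.
    """
    lo, hi = output_range
    if clip_percentiles is not None:
        plo, phi = np.percentile(arr, clip_percentiles)
        arr = np.clip(arr, plo, phi)
    amin, amax = float(arr.min()), float(arr.max())
    if amax - amin < 1e-12:  # constant log-ratio -> midpoint of the range
        return np.full_like(arr, (lo + hi) / 2.0)
    return (arr - amin) / (amax - amin) * (hi - lo) + lo


def _as_pixels(image: CTSlice | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return arr


def _wrap_like(image: CTSlice | np.ndarray, pixels: np.ndarray):
    if isinstance(image, CTSlice):
        return image.copy_with(pixels)
    return pixels


def ssr_retinex(
    image: CTSlice | np.ndarray,
    params: EnhanceParams | None = None,
    rescale: bool = True,
):
    """Single-scale Retinex with center-surround Gaussian illumination.

    Computes ``log(I + eps) - log((I * G) + eps)`` with reflective border
    padding, then maps to ``params.output_range`` (percentile-clipped
    linear rescale). ``rescale=False`` returns the raw log-domain
    reflectance. Intensities must be non-negative.
    """
    params = params or EnhanceParams()
    arr = _as_pixels(image)
    if arr.min() < 0:
        raise ValueError("SSR expects non-negative intensities")
    size = _surround_size(params.delta)
    kernel = gaussian_surround(params.delta, size)
    # reflective (symmetric) padding + FFT convolution: identical to direct
    # convolution with mode="reflect" up to floating-point roundoff, but
    # tractable for the large surround kernels SSR uses (size ~ 6 delta)
    half = size // 2
    padded = np.pad(arr, half, mode="symmetric")
    surround = signal.fftconvolve(padded, kernel, mode="valid")
    r = np.log(arr + LOG_EPS) - np.log(surround + LOG_EPS)
    if not rescale:
        return _wrap_like(image, r)
    return _wrap_like(image, _rescale(r, params.output_range, params.clip_percentiles))


def ace_decompose(image: CTSlice | np.ndarray, lowpass_sigma: float):
    """Split into Gaussian low-pass part and high-pass residual.

    ``low + high`` reconstructs the input exactly.
    """
    if lowpass_sigma <= 0:
        raise ValueError("lowpass_sigma must be positive")
    arr = _as_pixels(image)
    low = ndimage.gaussian_filter(arr, lowpass_sigma, mode="reflect")
    high = arr - low
    return _wrap_like(image, low), _wrap_like(image, high)


def _local_std(arr: np.ndarray, window: int) -> np.ndarray:
    mean = ndimage.uniform_filter(arr, window, mode="reflect")
    meansq = ndimage.uniform_filter(arr * arr, window, mode="reflect")
    var = np.maximum(meansq - mean * mean, 0.0)
    return np.sqrt(var)


def ace_enhance(image: CTSlice | np.ndarray, params: EnhanceParams | None = None):
    """Adaptive contrast enhancement with local gain on the high-pass part.

    The gain at each pixel is ``global_std / local_std`` clipped to
    ``[1, cg_max]`` — an amplification factor, never an attenuation — so a
    gain ceiling of 1 is the identity. The amplified high-pass part is added
    back to the low-pass part and the result clipped to the output range. A
    uniform image (zero global standard deviation) is returned unchanged.
    """
    params = params or EnhanceParams()
    arr = _as_pixels(image)
    global_std = float(arr.std())
    if global_std == 0.0:
        return _wrap_like(image, arr.copy())
    low, high = ace_decompose(arr, params.lowpass_sigma)
    local = _local_std(arr, params.ace_window)
    gain = np.clip(global_std / np.maximum(local, 1e-12), 1.0, params.cg_max)
    out = np.clip(low + gain * high, *params.output_range)
    return _wrap_like(image, out)


def _acer_single(arr: np.ndarray, params: EnhanceParams) -> np.ndarray:
    sharpened = ace_enhance(arr, params)
    return ssr_retinex(sharpened, params)


def acer(image: CTSlice | np.ndarray, params: EnhanceParams | None = None):
    """Full ACER enhancement: ACE sharpening followed by SSR.

    3-channel arrays are processed per channel and merged; CT slices are
    single-channel and processed once.
    """
    params = params or EnhanceParams()
    arr = _as_pixels(image)
    if arr.ndim == 3:
        out = np.stack([_acer_single(arr[..., c], params) for c in range(arr.shape[-1])], axis=-1)
        return out
    if arr.ndim != 2:
        raise ValueError(f"expected 2D or 3D image, got shape {arr.shape}")
    return _wrap_like(image, _acer_single(arr, params))
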