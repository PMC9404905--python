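"""Core image container and file I/O for axial lung CT slices.

A :class:`CTSlice` wraps a single 2D grayscale axial image. Pixels are kept
as ``float64`` internally regardless of the 8/16-bit source so the
enhancement stages can work in a continuous intensity domain; DICOM sources
are windowed to the 0–255 display range on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTSlice", "LobeMask", "as_labels", "read_slice", "write_png", "DEFAULT_HU_WINDOW"]

#: Default display window in Hounsfield units: lung parenchyma to soft tissue.
DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass
class CTSlice:
    """One grayscale axial CT slice.

    Parameters
    ----------
    pixels
        2D float array of intensities (any finite range; 0–255 by convention
        for 8-bit sources).
    spacing
        Optional (row, col) pixel spacing in mm/pixel.
    provenance
        Source path, or ``"synthetic"`` for generated phantoms.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] | None = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(f"slice too small: {self.pixels.shape} (minimum 16x16)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy_with(self, pixels: np.ndarray) -> "CTSlice":
        """New slice with replaced pixels, carrying metadata forward."""
        return CTSlice(pixels=pixels, spacing=self.spacing, provenance=self.provenance)


@dataclass
class LobeMask:
    """Integer label image assigning each pixel to background (0) or a lobe.

    ``lobe_table`` maps each positive label to a lobe name.
    """

    labels: np.ndarray
    lobe_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected a 2D label image, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("lobe labels must be integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.lobe_table)
        if self.lobe_table and unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from lobe_table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


def as_labels(mask: "LobeMask | np.ndarray") -> np.ndarray:
    """Accept a LobeMask or a bare label array; return the label array."""
    return mask.labels if isinstance(mask, LobeMask) else np.asarray(mask)


def _window_hu(hu: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"invalid HU window {window}")
    return np.clip((hu - lo) / (hi - lo), 0.0, 1.0) * 255.0


def read_slice(path: str | os.PathLike, hu_window: tuple[float, float] = DEFAULT_HU_WINDOW) -> CTSlice:
    """Read a CT slice from a grayscale PNG or a single-frame DICOM file.

    DICOM pixel data are rescaled with RescaleSlope/RescaleIntercept and
    windowed to 0–255 over ``hu_window``. Multi-channel PNGs are converted
    to luminance by channel averaging.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in {".dcm", ".dicom", ""}:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = _window_hu(arr * slope + intercept, hu_window)
        spacing = None
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        return CTSlice(pixels=arr, spacing=spacing, provenance=path)

    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.max(initial=0.0) > 255.0:  # 16-bit source
        arr = arr / 257.0
    return CTSlice(pixels=arr, provenance=path)


def write_png(path: str | os.PathLike, image: CTSlice | np.ndarray) -> None:
    """Write an image as 8-bit grayscale PNG, clipping to [0, 255]."""
    import imageio.v3 as iio

    arr = image.pixels if isinstance(image, CTSlice) else np.asarray(image)
    iio.imwrite(os.fspath(path), np.clip(np.round(arr), 0, 255).astype(np.uint8))
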