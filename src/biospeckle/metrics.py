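"""Summary statistics of speckle images used to validate the simulator.

These are diagnostics, not part of the roughness-estimation pipeline: mean
gray level, speckle contrast, bright-patch geometry (Otsu threshold +
connected components) and the autocorrelation grain size.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .simulate import SpeckleImage

__all__ = ["mean_gray", "speckle_contrast", "bright_patch_area",
           "autocorrelation_fwhm"]


def _pixels(image: SpeckleImage | np.ndarray) -> np.ndarray:
    if isinstance(image, SpeckleImage):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def mean_gray(image: SpeckleImage | np.ndarray) -> float:
    """Mean gray level over the whole frame."""
    return float(_pixels(image).mean())


def speckle_contrast(image: SpeckleImage | np.ndarray,
                     mask: np.ndarray | None = None) -> float:
    """Speckle contrast C = std(I) / mean(I); ~1 for fully developed speckle."""
    values = _pixels(image)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero-mean image has undefined contrast")
    return float(values.std() / mean)


def bright_patch_area(image: SpeckleImage | np.ndarray) -> float:
    """Mean area (px^2) of connected bright patches above the Otsu threshold."""
    values = _pixels(image)
    if values.min() == values.max():
        raise ValueError("constant image has no Otsu threshold")
    thresh = threshold_otsu(values)
    labelled = label(values > thresh, connectivity=2)
    areas = [r.area for r in regionprops(labelled)]
    if not areas:
        return 0.0
    return float(np.mean(areas))


def autocorrelation_fwhm(image: SpeckleImage | np.ndarray) -> float:
    """Full width at half maximum (px) of the central intensity
    autocorrelation peak, a standard estimate of the speckle grain size.

    Computed from the Wiener-Khinchin autocorrelation of the mean-subtracted
    intensity, averaging the widths of the central row and column profiles
    with linear interpolation at the half-maximum crossings.
    """
    values = _pixels(image)
    values = values - values.mean()
    spectrum = np.abs(np.fft.fft2(values)) ** 2
    acf = np.fft.fftshift(np.real(np.fft.ifft2(spectrum)))
    peak_r, peak_c = np.unravel_index(np.argmax(acf), acf.shape)
    peak = acf[peak_r, peak_c]
    if peak <= 0:
        raise ValueError("degenerate autocorrelation")

    def half_width(profile: np.ndarray, centre: int) -> float:
        half = profile[centre] / 2.0
        # walk right from the peak to the first crossing below half-max
        width = profile.size / 2.0
        for offset in range(1, profile.size - centre):
            value = profile[centre + offset]
            if value < half:
                prev = profile[centre + offset - 1]
                frac = (prev - half) / (prev - value)
                width = (offset - 1) + frac
                break
        return width

    row = half_width(acf[peak_r, :], peak_c)
    col = half_width(acf[:, peak_c], peak_r)
    return float(row + col)  # half-width right + half-width down ~ FWHM
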