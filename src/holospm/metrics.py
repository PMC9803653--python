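"""Optical characteristics of a speckle image.

Four statistics summarize how speckle texture responds to particle size and
concentration:

* **mean intensity gradient** — average magnitude of the forward finite
  difference of pixel intensity (unit-interval scale), over the interior
  (M-1) x (N-1) grid;
* **speckle size** — foreground area per connected speckle after
  thresholding at mean + sd of the pixel intensities (8-connectivity);
* **speckle width** — mean FWHM of the central horizontal/vertical profiles
  of the normalized autocovariance map (Wiener-Khinchin);
* **mean spatial frequency** — power-weighted centroid of |f| of the
  horizontal and vertical power-spectral-density profiles, DC excluded,
  averaged over the two axes, in cycles/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .simulate import Hologram

__all__ = [
    "SpeckleMetrics",
    "AutocovarianceMap",
    "UndefinedMetricError",
    "mean_intensity_gradient",
    "binarize_speckles",
    "speckle_size",
    "autocovariance",
    "speckle_width",
    "mean_spatial_frequency",
    "characterize",
    "characterize_stack",
]


class UndefinedMetricError(ValueError):
    """A statistic has no defined value on this image (e.g. no speckles)."""


@dataclass(frozen=True)
class SpeckleMetrics:
    mean_intensity_gradient: float
    speckle_size: float  # px area per speckle; NaN when undefined
    speckle_width: float  # px; NaN when undefined
    mean_spatial_frequency: float  # cycles/px; NaN when undefined


@dataclass(frozen=True)
class AutocovarianceMap:
    """Normalized autocovariance f(x, y), zero lag at the center pixel."""

    values: np.ndarray

    @property
    def center(self) -> tuple[int, int]:
        m, n = self.values.shape
        return (m // 2, n // 2)


def _as_array(image) -> np.ndarray:
    if isinstance(image, Hologram):
        return image.to_unit().intensity
    return np.asarray(image, dtype=float)


def mean_intensity_gradient(image) -> float:
    """Mean forward-difference gradient magnitude on the unit scale.

    sum_{x,y} sqrt((I(x+1,y)-I(x,y))^2 + (I(x,y+1)-I(x,y))^2) over the
    (M-1) x (N-1) interior, divided by (M-1)(N-1).
    """
    arr = _as_array(image)
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("image must be at least 2x2")
    dx = arr[1:, :-1] - arr[:-1, :-1]
    dy = arr[:-1, 1:] - arr[:-1, :-1]
    return float(np.sqrt(dx**2 + dy**2).sum() / ((m - 1) * (n - 1)))


def binarize_speckles(image) -> tuple[np.ndarray, float]:
    """Threshold at mean + sd of pixel intensities; foreground = above."""
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("empty image")
    threshold = float(arr.mean() + arr.std())
    return arr > threshold, threshold


def speckle_size(image) -> float:
    """Total foreground area divided by the number of connected speckles.

    Components are 8-connected, so diagonally touching grains count as one
    speckle.  Raises :class:`UndefinedMetricError` when nothing exceeds the
    threshold.
    """
    binary, _ = binarize_speckles(image)
    labeled, n_components = measure.label(binary, connectivity=2,
                                          return_num=True)
    if n_components == 0:
        raise UndefinedMetricError("no speckles above threshold")
    return float(binary.sum() / n_components)


def autocovariance(image) -> AutocovarianceMap:
    """Normalized circular autocovariance via the Wiener-Khinchin relation.

    f = (ifft2(|fft2(I)|^2) / (M N) - mean(I)^2) / var(I); f(0, 0) = 1 by
    construction.  The map is fftshifted so zero lag sits at the center.
    """
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("empty image")
    mean = arr.mean()
    var = np.mean(arr**2) - mean**2
    if var <= np.mean(arr**2) * 1e-14:
        raise UndefinedMetricError("zero-variance image")
    spectrum = np.fft.fft2(arr)
    autocorr = np.fft.ifft2(np.abs(spectrum) ** 2).real / arr.size
    values = np.fft.fftshift((autocorr - mean**2) / var)
    return AutocovarianceMap(values=values)


def _half_crossing(profile: np.ndarray) -> float:
    """Distance from lag 0 to the first 0.5 crossing, linearly interpolated."""
    below = np.nonzero(profile < 0.5)[0]
    if below.size == 0 or below[0] == 0:
        raise UndefinedMetricError("autocovariance never falls below half max")
    k = int(below[0])  # first lag below half max; profile[0] = 1 at zero lag
    y0, y1 = profile[k - 1], profile[k]
    return (k - 1) + (y0 - 0.5) / (y0 - y1)


def speckle_width(image) -> float:
    """Mean FWHM (px) of the central autocovariance profiles.

    The full width is twice the first outward half-max crossing of the
    central horizontal and vertical profiles (the circular autocovariance
    of a real image is symmetric in lag); the two are averaged.
    """
    acv = autocovariance(image).values
    ci, cj = acv.shape[0] // 2, acv.shape[1] // 2
    horiz = acv[ci, cj:]
    vert = acv[ci:, cj]
    fwhm_h = 2.0 * _half_crossing(horiz)
    fwhm_v = 2.0 * _half_crossing(vert)
    return float((fwhm_h + fwhm_v) / 2.0)


def mean_spatial_frequency(image) -> float:
    """Power-weighted mean |frequency| of the PSD profiles, in cycles/px.

    The 2D PSD is collapsed onto each frequency axis (summing over the
    other); each axis's centroid is sum(PSD |f|) / sum(PSD) with the f = 0
    bin excluded; an axis with no off-DC power contributes 0.  The two axis
    centroids are averaged.
    """
    arr = _as_array(image)
    if arr.size == 0 or not np.any(arr):
        raise ValueError("all-zero or empty image")
    psd = np.abs(np.fft.fft2(arr)) ** 2
    m, n = arr.shape
    total = psd.sum()
    centroids = []
    for axis, n_bins in ((0, n), (1, m)):
        profile = psd.sum(axis=axis)  # as a function of the other axis's freq
        freqs = np.abs(np.fft.fftfreq(n_bins))
        off_dc = freqs > 0
        power = profile[off_dc].sum()
        # an axis whose off-DC power is numerically zero contributes 0
        centroids.append(
            float((profile[off_dc] * freqs[off_dc]).sum() / power)
            if power > total * 1e-12 else 0.0)
    return float(np.mean(centroids))


def characterize(image) -> SpeckleMetrics:
    """All four statistics; members undefined on this image become NaN."""
    gradient = mean_intensity_gradient(image)
    try:
        size = speckle_size(image)
    except UndefinedMetricError:
        size = float("nan")
    try:
        width = speckle_width(image)
    except UndefinedMetricError:
        width = float("nan")
    try:
        freq = mean_spatial_frequency(image)
    except (UndefinedMetricError, ValueError):
        freq = float("nan")
    return SpeckleMetrics(gradient, size, width, freq)


def characterize_stack(frames: list[Hologram], branch: str = "") -> pd.DataFrame:
    """One row of metrics per frame, CSV-exportable."""
    rows = []
    for frame in frames:
        m = characterize(frame)
        rho_f, rho_c = frame.labels if frame.labels else (np.nan, np.nan)
        rows.append({
            "frame": frame.frame_index, "branch": branch,
            "rho_f": rho_f, "rho_c": rho_c,
            "gradient": m.mean_intensity_gradient,
            "size_px": m.speckle_size,
            "width_px": m.speckle_width,
            "mean_freq_cyc_per_px": m.mean_spatial_frequency,
        })
    return pd.DataFrame(rows)
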