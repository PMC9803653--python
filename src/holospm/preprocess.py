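"""Hologram -> trainable segments: background subtraction, Gaussian
frequency-band separation, intensity shifting, contrast enhancement, tiling.

The fine/coarse branches differ only in their parameters: the fine branch
keeps high spatial frequencies (small-particle speckle) with a Gaussian
high-pass mask and brightens the residual (S = 50, C = 7); the coarse branch
keeps low frequencies with the complementary low-pass mask (S = 0, C = 5).
Both use filter size R = 20 on a 700-px frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import Hologram

__all__ = [
    "PreprocParams",
    "FrequencyMask",
    "Segment",
    "SegmentSet",
    "FINE_BRANCH",
    "COARSE_BRANCH",
    "ensemble_background",
    "subtract_background",
    "build_frequency_mask",
    "apply_frequency_filter",
    "shift_intensity",
    "enhance_contrast",
    "segment_image",
    "run_preproc_chain",
]


@dataclass(frozen=True)
class PreprocParams:
    """Knobs of the image-processing chain.

    filter_size R is in frequency-grid pixel units; shift S in 8-bit counts;
    contrast C is a dimensionless gain about the image mean.
    """

    filter_size: float = 20.0
    filter_mode: str = "highpass"  # lowpass | highpass | none
    shift: float = 50.0
    contrast: float = 7.0
    tile_size: int = 70

    def __post_init__(self) -> None:
        if self.filter_size <= 0:
            raise ValueError("filter_size must be positive")
        if self.filter_mode not in ("lowpass", "highpass", "none"):
            raise ValueError("filter_mode must be lowpass|highpass|none")
        if not -255 <= self.shift <= 255:
            raise ValueError("shift must lie in [-255, 255]")
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")


#: Branch defaults: (HPF, S=50, C=7) for fine PM, (LPF, S=0, C=5) for coarse.
FINE_BRANCH = PreprocParams(filter_size=20.0, filter_mode="highpass",
                            shift=50.0, contrast=7.0, tile_size=70)
COARSE_BRANCH = PreprocParams(filter_size=20.0, filter_mode="lowpass",
                              shift=0.0, contrast=5.0, tile_size=70)


@dataclass(frozen=True)
class FrequencyMask:
    """Gaussian pass-filter values on the centered (u, v) frequency grid."""

    values: np.ndarray
    mode: str


@dataclass
class Segment:
    """One tile of a preprocessed frame, on the unit interval."""

    pixels: np.ndarray
    frame_index: int
    grid_position: tuple[int, int]
    labels: tuple[float, float] | None = None


@dataclass
class SegmentSet:
    """Ordered, disjoint, exhaustive tiles cut from one or more frames."""

    segments: list[Segment]
    tile_size: int

    def __len__(self) -> int:
        return len(self.segments)

    def as_matrix(self) -> np.ndarray:
        """(n_segments, tile_size^2) design matrix for the network."""
        return np.stack([s.pixels.ravel() for s in self.segments])

    def label_array(self, which: str = "fine") -> np.ndarray:
        idx = 0 if which == "fine" else 1
        return np.array([s.labels[idx] for s in self.segments])


def ensemble_background(frames: list[Hologram]) -> Hologram:
    """Pixelwise mean over consecutive frames (the static background)."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].intensity.shape
    if any(f.intensity.shape != shape for f in frames):
        raise ValueError("frames must share one shape")
    mean = np.mean([f.intensity for f in frames], axis=0)
    return replace(frames[0], intensity=mean, labels=None)


def subtract_background(frame: Hologram, background: Hologram) -> Hologram:
    """Difference image re-centered at mid-scale and clipped.

    Re-centering keeps the sign of the residual: speckle darker than the
    background survives below mid-scale instead of being clipped away.
    """
    if frame.intensity.shape != background.intensity.shape:
        raise ValueError("frame/background shape mismatch")
    mid = frame.max_value / 2.0
    diff = frame.intensity - background.intensity + mid
    return replace(frame, intensity=np.clip(diff, 0.0, frame.max_value))


def build_frequency_mask(shape: tuple[int, int], filter_size: float,
                         mode: str) -> FrequencyMask:
    """Gaussian LPF(u, v) = exp(-(u^2 + v^2) / (4 R^2)) or its complement.

    (u, v) are integer indices of the center-shifted frequency grid, zero at
    the center pixel (floor(M/2), floor(N/2)).
    """
    if filter_size <= 0:
        raise ValueError("filter_size must be positive")
    if mode not in ("lowpass", "highpass", "none"):
        raise ValueError("mode must be lowpass|highpass|none")
    m, n = shape
    u = np.arange(m)[:, None] - m // 2
    v = np.arange(n)[None, :] - n // 2
    lpf = np.exp(-(u**2 + v**2) / (4.0 * filter_size**2))
    if mode == "lowpass":
        values = lpf
    elif mode == "highpass":
        values = 1.0 - lpf
    else:
        values = np.ones((m, n))
    return FrequencyMask(values=values, mode=mode)


def apply_frequency_filter(image: Hologram, params: PreprocParams,
                           rescale: bool = True) -> Hologram:
    """FFT -> center-shift -> Gaussian mask -> inverse FFT -> real part.

    With ``rescale=True`` the result is clipped back to the hologram's
    declared intensity scale (high-pass residuals are signed around zero;
    clipping keeps the positive half, which the later intensity shift
    re-biases toward white).  ``rescale=False`` returns the raw filtered
    values, on which lowpass + highpass reconstructs the input exactly.
    """
    if params.filter_mode == "none":
        return image
    mask = build_frequency_mask(image.intensity.shape, params.filter_size,
                                params.filter_mode)
    spectrum = np.fft.fftshift(np.fft.fft2(image.intensity))
    filtered = np.fft.ifft2(np.fft.ifftshift(spectrum * mask.values))
    out = filtered.real
    if rescale:
        out = np.clip(out, 0.0, image.max_value)
    return replace(image, intensity=out)


def shift_intensity(image: Hologram, shift: float) -> Hologram:
    """Add S on the 8-bit scale and clip to [0, 255]."""
    img = image.to_uint8()
    return replace(img, intensity=np.clip(img.intensity + shift, 0.0, 255.0))


def enhance_contrast(image: Hologram, contrast: float) -> Hologram:
    """Linear gain about the image mean: out = mean + C (in - mean), clipped.

    C = 1 is the identity; C = 0 collapses the image to its mean; C > 1
    stretches the intensity distribution on the 8-bit scale.
    """
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    img = image.to_uint8()
    mean = img.intensity.mean()
    out = np.clip(mean + contrast * (img.intensity - mean), 0.0, 255.0)
    return replace(img, intensity=out)


def segment_image(image: Hologram, tile_size: int) -> SegmentSet:
    """Cut the frame into disjoint row-major tiles on the unit interval.

    A 700x700 frame with 70-px tiles yields the 10 x 10 = 100 segments each
    network input batch is built from.  Tiles are globally rescaled (by the
    declared full scale), so re-stitching them reproduces the frame.
    """
    m, n = image.intensity.shape
    if m % tile_size or n % tile_size:
        raise ValueError(f"tile_size {tile_size} must divide image dims {m}x{n}")
    unit = image.to_unit()
    segments = []
    for i in range(m // tile_size):
        for j in range(n // tile_size):
            tile = unit.intensity[i * tile_size:(i + 1) * tile_size,
                                  j * tile_size:(j + 1) * tile_size]
            segments.append(Segment(pixels=tile.copy(),
                                    frame_index=image.frame_index,
                                    grid_position=(i, j),
                                    labels=image.labels))
    return SegmentSet(segments=segments, tile_size=tile_size)


def run_preproc_chain(frames: list[Hologram],
                      params: PreprocParams | None = None,
                      branch: str | None = None,
                      background: Hologram | None = None) -> SegmentSet:
    """Background-subtract, filter, shift, contrast-enhance and tile a stack.

    ``branch`` selects the default parameter set ("fine" -> HPF/S=50/C=7,
    "coarse" -> LPF/S=0/C=5, both R=20); pass ``params`` to override.  The
    background defaults to the ensemble average of the stack itself.
    """
    if params is None:
        if branch == "fine":
            params = FINE_BRANCH
        elif branch == "coarse":
            params = COARSE_BRANCH
        else:
            raise ValueError("give params or branch='fine'|'coarse'")
    if background is None:
        background = ensemble_background(frames)
    all_segments: list[Segment] = []
    for frame in frames:
        img = subtract_background(frame, background)
        img = apply_frequency_filter(img, params)
        img = shift_intensity(img, params.shift)
        img = enhance_contrast(img, params.contrast)
        seg = segment_image(img, params.tile_size)
        all_segments.extend(seg.segments)
    return SegmentSet(segments=all_segments, tile_size=params.tile_size)
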