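"""Classifier front-ends: Morlet scalograms, the wavelet-Fourier matrix,
and raw segments.

Three representations of the same EEG segment feed the three detectors:

* **WS** -- a continuous wavelet transform (Morlet) over scales 1:5:500
  (100 scales, pseudo-frequencies 0.42-208 Hz at 256 Hz), rendered as a
  500x333 RGB image;
* **WF** -- an L x 3 matrix stacking (i) signed CWT coefficients at scale 80
  (~2.6 Hz, mid-delta), (ii) a 0.2-4.5 Hz Fourier band-limited
  reconstruction, (iii) the raw segment;
* **raw** -- the segment itself, for the 1-D network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from PIL import Image

from .core import FS_DEFAULT, EegSegment

WAVELET = "morl"
SCALES = np.arange(1, 500, 5)  # 1, 6, ..., 496 -> 100 scales
IMAGE_SIZE = (500, 333)  # (width, height) pixels
IMAGE_DPI = 300
WF_SCALE = 80
WF_BAND = (0.2, 4.5)
COLORMAP = "jet"


@dataclass
class Scalogram:
    """CWT magnitudes (|scales| x L) for one segment."""

    coefficients: np.ndarray
    scales: np.ndarray
    fs: float = FS_DEFAULT

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.scales.size:
            raise ValueError("one coefficient row per scale required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("scalogram coefficients must be finite")


@dataclass
class WfMatrix:
    """L x 3 dominant-feature matrix: [cwt@scale80, band-limited, raw]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 3:
            raise ValueError("WF matrix must be L x 3")


def morlet_pseudo_frequency(scale: float, fs: float = FS_DEFAULT) -> float:
    """Pseudo-frequency (Hz) of a Morlet CWT scale: Fc * fs / scale.

    With the standard Morlet centre frequency Fc = 0.8125, scale 1 at 256 Hz
    maps to 208 Hz and scale 500 to ~0.42 Hz.
    """
    if scale <= 0 or fs <= 0:
        raise ValueError("scale and fs must be positive")
    return float(pywt.scale2frequency(WAVELET, scale) * fs)


def compute_scalogram(
    segment: EegSegment | np.ndarray,
    scales: np.ndarray = SCALES,
    fs: float | None = None,
) -> Scalogram:
    """Morlet CWT magnitude map of a zero-meaned segment.

    A constant segment yields an all-zero map (valid, not an error).
    """
    x, fs = _as_array(segment, fs)
    x = x - x.mean()
    coeffs, _ = pywt.cwt(x, scales, WAVELET, method="fft")
    return Scalogram(coefficients=np.abs(coeffs), scales=np.asarray(scales), fs=fs)


def render_scalogram_image(
    scalogram: Scalogram,
    path=None,
    size: tuple[int, int] = IMAGE_SIZE,
) -> np.ndarray:
    """Render a scalogram to a fixed-size RGB raster (and optionally a PNG).

    Time runs along x (resampled to the target width), scale increases
    downward along y.  Intensities are min-max normalized per image and
    mapped through a fixed colormap, so identical inputs give byte-identical
    PNGs.  Returns the H x W x 3 uint8 array.
    """
    import matplotlib

    cmap = matplotlib.colormaps[COLORMAP]
    c = scalogram.coefficients
    rng = c.max() - c.min()
    norm = (c - c.min()) / rng if rng > 0 else np.zeros_like(c)
    rgba = cmap(norm)  # scales x L x 4 float
    rgb8 = (rgba[:, :, :3] * 255).round().astype(np.uint8)
    img = Image.fromarray(rgb8).resize(size, resample=Image.BILINEAR)
    if path is not None:
        img.save(path, format="PNG", dpi=(IMAGE_DPI, IMAGE_DPI))
    return np.asarray(img)


def band_limited_reconstruction(
    segment: EegSegment | np.ndarray,
    f_lo: float = WF_BAND[0],
    f_hi: float = WF_BAND[1],
    fs: float | None = None,
) -> np.ndarray:
    """Fourier band-pass by spectral masking.

    Forward real FFT; bins with frequency outside [f_lo, f_hi] (inclusive)
    are zeroed; inverse transform returns the real reconstruction.  Using
    the real FFT keeps the spectrum conjugate-symmetric by construction.
    """
    if f_lo >= f_hi:
        raise ValueError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    x, fs = _as_array(segment, fs)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    return np.fft.irfft(spec, x.size)


def compute_wf_matrix(
    segment: EegSegment | np.ndarray, fs: float | None = None
) -> WfMatrix:
    """Stack the three dominant-feature series into an L x 3 matrix.

    Column 0: signed Morlet CWT coefficients at scale 80 (mid-delta);
    column 1: 0.2-4.5 Hz band-limited reconstruction; column 2: the raw
    segment, untouched.
    """
    x, fs = _as_array(segment, fs)
    cwt80, _ = pywt.cwt(x, [WF_SCALE], WAVELET, method="fft")
    band = band_limited_reconstruction(x, fs=fs)
    return WfMatrix(matrix=np.column_stack([cwt80[0], band, x]))


def _as_array(
    segment: EegSegment | np.ndarray, fs: float | None
) -> tuple[np.ndarray, float]:
    if isinstance(segment, EegSegment):
        return np.asarray(segment.samples, dtype=np.float64), segment.fs
    return np.asarray(segment, dtype=np.float64), (fs or FS_DEFAULT)
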