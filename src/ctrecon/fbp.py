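"""Filtered back projection, the analytic baseline reconstructor.

Each view is convolved with the band-limited discrete ramp kernel
(optionally apodised with a Hann or Hamming window), then smeared back
across the image with linear interpolation and the pi/n_angles quadrature
weight. Filtering happens in the frequency domain after zero-padding to
the next power of two at least twice the detector count, which avoids
circular-convolution wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ImageGrid, pixel_centers
from .projection import MU_WATER, Sinogram, mu_to_hu

__all__ = ["FBPConfig", "ramp_kernel", "filter_sinogram", "back_project", "fbp_reconstruct"]

_WINDOWS = ("ramp", "hann", "hamming")


@dataclass(frozen=True)
class FBPConfig:
    """Reconstruction settings: apodisation window, output grid, pixel pitch."""

    filter_window: str = "hann"
    output_size: int = 512
    pixel_spacing: float = 220.0 / 512

    def __post_init__(self) -> None:
        if self.filter_window not in _WINDOWS:
            raise ValueError(f"filter_window must be one of {_WINDOWS}")
        if self.output_size < 8:
            raise ValueError("output_size must be at least 8 pixels")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


def ramp_kernel(n: int, spacing: float) -> np.ndarray:
    """Band-limited spatial ramp kernel h[-(n-1) .. (n-1)], length 2n - 1.

    h[0] = 1 / (4 s^2), h[m] = 0 for even m, h[m] = -1 / (pi m s)^2 for odd
    m, with s the detector spacing. This is the exact inverse-DFT of the
    ramp |f| truncated at the detector Nyquist frequency.
    """
    m = np.arange(-(n - 1), n)
    h = np.zeros(2 * n - 1)
    h[m == 0] = 1.0 / (4.0 * spacing**2)
    odd = m % 2 == 1
    h[odd] = -1.0 / (np.pi * m[odd] * spacing) ** 2
    return h


def _filter_response(n_detectors: int, spacing: float, window: str) -> np.ndarray:
    """Frequency response of the (apodised) ramp on the padded FFT grid."""
    pad = 1
    while pad < 2 * n_detectors:
        pad *= 2
    # exact DFT of the spatial kernel, wrap-around layout
    h = np.zeros(pad)
    kernel = ramp_kernel(n_detectors, spacing)
    center = n_detectors - 1
    h[: n_detectors] = kernel[center:]
    h[-(n_detectors - 1):] = kernel[:center]
    response = np.real(np.fft.fft(h))
    freq = np.fft.fftfreq(pad)  # cycles per sample, |freq| <= 0.5
    if window == "hann":
        response *= 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))
    elif window == "hamming":
        response *= 0.54 + 0.46 * np.cos(2.0 * np.pi * freq)
    # NB: the kernel's tiny residual DC (O(1/n) of the ramp peak) is kept;
    # it compensates truncation and removes the global grey-level offset
    # that a hard response[0] = 0 would introduce.
    return response


def filter_sinogram(sinogram: Sinogram, window: str = "hann") -> Sinogram:
    """Ramp-filter every view of a sinogram.

    The output has the same shape and geometry; values carry an extra
    1/length unit so that back projection integrates to attenuation.
    """
    if window not in _WINDOWS:
        raise ValueError(f"unknown filter window {window!r}; choose from {_WINDOWS}")
    geom = sinogram.geometry
    if geom.n_detectors < 2:
        raise ValueError("filtering needs at least 2 detector bins")
    response = _filter_response(geom.n_detectors, geom.detector_spacing, window)
    pad = response.size
    spectra = np.fft.fft(sinogram.values, n=pad, axis=1)
    filtered = np.real(np.fft.ifft(spectra * response[None, :], axis=1))
    filtered = filtered[:, : geom.n_detectors] * geom.detector_spacing
    return Sinogram(filtered, geom)


def back_project(sinogram: Sinogram, config: FBPConfig) -> ImageGrid:
    """Back-project (already filtered) views onto the output grid.

    pixel value = (pi / n_angles) * sum over views of the view's filtered
    profile linearly interpolated at t = x cos(theta) + y sin(theta).
    Returns an MU image.
    """
    geom = sinogram.geometry
    size = config.output_size
    xg, yg = pixel_centers(size, config.pixel_spacing)
    offsets = geom.detector_offsets
    accum = np.zeros((size, size))
    for a, theta in enumerate(geom.angles):
        t = xg * np.cos(theta) + yg * np.sin(theta)
        accum += np.interp(t, offsets, sinogram.values[a], left=0.0, right=0.0)
    accum *= np.pi / geom.n_angles
    return ImageGrid(accum, config.pixel_spacing, "MU")


def fbp_reconstruct(
    sinogram: Sinogram, config: FBPConfig, mu_water: float = MU_WATER
) -> ImageGrid:
    """Full filtered back projection; returns the image in Hounsfield units."""
    filtered = filter_sinogram(sinogram, config.filter_window)
    return mu_to_hu(back_project(filtered, config), mu_water)
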