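"""Hybrid Wiener-Gabor preprocessing for speckled ultrasound texture.

The enhancement runs in two stages.  A local-statistics Wiener filter first
suppresses acquisition noise: for each pixel the filter shrinks the deviation
from the local mean by the estimated signal-to-signal-plus-noise ratio,

    out = mu + max(var_local - var_noise, 0) / var_local * (in - mu),

which leaves flat regions at their mean and passes high-variance structure
through.  The denoised image is then convolved with a bank of Gabor kernels
— Gaussian-windowed complex sinusoids — spanning several spatial frequencies
and orientations, and the per-pixel response magnitudes are combined (max by
default) and rescaled to [0, 1].  Texture at any of the bank's scales and
orientations is brightened relative to smooth background, which is what the
downstream co-occurrence features feed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianKernelSpec",
    "GaborSpec",
    "GaborBank",
    "gaussian_kernel",
    "convolve2d",
    "wiener_filter",
    "gabor_kernel",
    "hwgf_preprocess",
]

_EPS = 1e-12


@dataclass(frozen=True)
class GaussianKernelSpec:
    """A sampled 2-D Gaussian kernel A*exp(-((f-f0)^2/2sf^2 + (g-g0)^2/2sg^2)).

    ``amplitude=None`` requests the normalizing constant (entries sum to 1).
    ``center=None`` places the peak at the kernel midpoint.
    Coordinates are (row, col), 0-based.
    """

    size: int = 3
    sigma_f: float = 0.5
    sigma_g: float = 0.5
    amplitude: float | None = None
    center: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 3, got {self.size}")
        if self.sigma_f <= 0 or self.sigma_g <= 0:
            raise ValueError(
                f"sigmas must be > 0, got ({self.sigma_f}, {self.sigma_g})"
            )


@dataclass(frozen=True)
class GaborSpec:
    """One Gabor kernel: frequency (cycles/pixel), orientation (radians),
    elliptical Gaussian envelope sigmas (pixels), amplitude, phase offset."""

    frequency: float
    orientation: float
    sigma1: float = 2.0
    sigma2: float = 2.0
    amplitude: float = 1.0
    phase: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.frequency <= 0.5:
            raise ValueError(
                f"frequency must lie in [0, 0.5] cycles/pixel (Nyquist), "
                f"got {self.frequency}"
            )
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError(
                f"envelope sigmas must be > 0, got ({self.sigma1}, {self.sigma2})"
            )


DEFAULT_FREQUENCIES = (0.1, 0.2, 0.3, 0.4)
DEFAULT_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class GaborBank:
    """Cross-product of frequencies and orientations, plus a combination rule."""

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    sigma1: float = 2.0
    sigma2: float = 2.0
    kernel_size: int = 13
    combine: str = "max"

    def validate(self) -> None:
        if len(self.frequencies) == 0 or len(self.orientations) == 0:
            raise ValueError("Gabor bank needs at least one frequency and orientation")
        for theta in self.orientations:
            if not 0.0 <= theta < np.pi:
                raise ValueError(
                    f"orientations must lie in [0, pi), got {theta}"
                )
        if self.combine not in ("max", "mean"):
            raise ValueError(f"combine must be 'max' or 'mean', got {self.combine!r}")
        for spec in self.specs():
            spec.validate()

    def specs(self) -> list[GaborSpec]:
        return [
            GaborSpec(frequency=f, orientation=t, sigma1=self.sigma1, sigma2=self.sigma2)
            for f in self.frequencies
            for t in self.orientations
        ]


def gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Sample the 2-D Gaussian on a size x size grid."""
    spec.validate()
    mid = (spec.size - 1) / 2.0
    f0, g0 = spec.center if spec.center is not None else (mid, mid)
    f, g = np.meshgrid(
        np.arange(spec.size, dtype=float),
        np.arange(spec.size, dtype=float),
        indexing="ij",
    )
    kernel = np.exp(
        -((f - f0) ** 2 / (2 * spec.sigma_f**2) + (g - g0) ** 2 / (2 * spec.sigma_g**2))
    )
    if spec.amplitude is None:
        kernel /= kernel.sum()
    else:
        kernel *= spec.amplitude
    return kernel


def convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size 2-D convolution with reflect boundary handling."""
    image = np.asarray(image)
    kernel = np.asarray(kernel)
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {image.shape}"
        )
    if np.iscomplexobj(kernel):
        real = ndimage.convolve(image, kernel.real, mode="reflect")
        imag = ndimage.convolve(image, kernel.imag, mode="reflect")
        return real + 1j * imag
    return ndimage.convolve(image, kernel, mode="reflect")


def wiener_filter(
    image: np.ndarray, window: int = 3, noise_variance: float | None = None
) -> np.ndarray:
    """Adaptive local-statistics Wiener denoiser.

    Local mean and variance are computed over a window x window neighborhood
    (reflect boundary).  When ``noise_variance`` is None it is estimated as
    the mean of the local variances, the usual choice when the noise floor
    is unknown.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    image = np.asarray(image, dtype=float)
    local_mean = ndimage.uniform_filter(image, size=window, mode="reflect")
    local_sq = ndimage.uniform_filter(image**2, size=window, mode="reflect")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    if noise_variance is None:
        noise_variance = float(local_var.mean())
    gain = np.maximum(local_var - noise_variance, 0.0) / np.maximum(local_var, _EPS)
    return local_mean + gain * (image - local_mean)


def gabor_kernel(spec: GaborSpec, size: int = 13) -> np.ndarray:
    """Complex Gabor kernel on a size x size grid centered at the midpoint.

    Coordinates are rotated into the (theta, theta+pi/2) frame:
    z1 = f cos(theta) + g sin(theta) runs along the carrier direction and
    z2 = -f sin(theta) + g cos(theta) across it.  The kernel is the
    elliptical Gaussian envelope exp(-0.5 (z1^2/s1^2 + z2^2/s2^2)) times the
    complex carrier exp(i (2 pi F z1 + phase)).
    """
    spec.validate()
    if size % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {size}")
    half = (size - 1) // 2
    f, g = np.meshgrid(
        np.arange(-half, half + 1, dtype=float),
        np.arange(-half, half + 1, dtype=float),
        indexing="ij",
    )
    c, s = np.cos(spec.orientation), np.sin(spec.orientation)
    z1 = f * c + g * s
    z2 = -f * s + g * c
    envelope = np.exp(-0.5 * (z1**2 / spec.sigma1**2 + z2**2 / spec.sigma2**2))
    carrier = np.exp(1j * (2 * np.pi * spec.frequency * z1 + spec.phase))
    return spec.amplitude * envelope * carrier


def gabor_responses(image: np.ndarray, bank: GaborBank) -> list[np.ndarray]:
    """Per-kernel response magnitudes of the bank on ``image``."""
    bank.validate()
    return [
        np.abs(convolve2d(image, gabor_kernel(spec, bank.kernel_size)))
        for spec in bank.specs()
    ]


def hwgf_preprocess(
    image: np.ndarray,
    wiener_window: int = 3,
    bank: GaborBank | None = None,
    noise_variance: float | None = None,
) -> np.ndarray:
    """Wiener denoising followed by Gabor-bank texture enhancement.

    Returns the per-pixel combination (``bank.combine``: max or mean) of the
    Gabor response magnitudes on the denoised image, min-max rescaled to
    [0, 1].  A flat response map (e.g. a constant input) comes back as the
    all-zeros image.
    """
    if bank is None:
        bank = GaborBank()
    denoised = wiener_filter(image, window=wiener_window, noise_variance=noise_variance)
    responses = np.stack(gabor_responses(denoised, bank))
    if bank.combine == "max":
        combined = responses.max(axis=0)
    else:
        combined = responses.mean(axis=0)
    lo, hi = combined.min(), combined.max()
    if hi - lo < _EPS:
        return np.zeros_like(combined)
    return (combined - lo) / (hi - lo)
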