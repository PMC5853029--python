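"""Physics-based forward model of defocus in a fluorescence microscope.

The point spread function (PSF) of a circular-aperture objective at defocus
depth ``z`` is computed from the scalar diffraction integral

    h(x, y, z) = | C * integral_0^1 J0(k (NA/n) r rho)
                   exp(-1/2 j k rho^2 z (NA/n)^2) rho d rho |^2

with ``k = 2*pi/lambda`` the wavenumber, ``NA`` the numerical aperture, ``n``
the immersion refractive index and ``r = sqrt(x^2 + y^2)`` the physical radial
distance in the image plane.  At ``z = 0`` the integral reduces to the Airy
pattern ``(2 J1(v)/v)^2``.  Convolving an in-focus image with ``h(.,.,z)``
manufactures a synthetically defocused image with known ground truth, which is
how labeled training data is produced without ever acquiring a real focal
stack.

Sensor noise is modeled as Poisson shot noise on photoelectrons, wrapped in
the camera's digital offset (black level) and gain (counts per electron).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special
from scipy.integrate import simpson

__all__ = [
    "OpticalParams",
    "PSFKernel",
    "SensorModel",
    "compute_psf",
    "defocus_image",
    "apply_poisson_noise",
    "generate_defocus_stack",
    "augment_gain_offset",
]

UINT16_MAX = 65535.0


@dataclass(frozen=True)
class OpticalParams:
    """Microscope forward-model constants.

    Parameters
    ----------
    numerical_aperture : float
        NA of the objective (dimensionless), must satisfy 0 < NA < n.
    refractive_index : float
        Immersion refractive index n (1.0 for air).
    wavelength_nm : float
        Emission wavelength in nanometres.
    z_step_um : float
        Axial spacing between consecutive defocus levels, in micrometres.
    pixel_size_um : float
        Physical size of one camera pixel in the sample plane, in
        micrometres per pixel.  The default 0.65 um/px is consistent with a
        6.5 um camera pixel at 20x magnification with 2x binning and with a
        blur-diameter range of roughly 3-30 pixels over the level range.
    n_levels : int
        Number of ordered defocus classes (level 0 = in focus).
    """

    numerical_aperture: float = 0.5
    refractive_index: float = 1.0
    wavelength_nm: float = 500.0
    z_step_um: float = 2.0
    pixel_size_um: float = 0.65
    n_levels: int = 11

    def __post_init__(self) -> None:
        if not (0.0 < self.numerical_aperture < self.refractive_index):
            raise ValueError(
                f"need 0 < NA < n, got NA={self.numerical_aperture}, "
                f"n={self.refractive_index}"
            )
        for name in ("wavelength_nm", "z_step_um", "pixel_size_um"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")

    @property
    def wavenumber(self) -> float:
        """Wavenumber k = 2*pi/lambda in rad/nm."""
        return 2.0 * math.pi / self.wavelength_nm

    def z_depths_um(self) -> np.ndarray:
        """Defocus depth of each level: 0, z_step, ..., (n_levels-1)*z_step."""
        return np.arange(self.n_levels) * self.z_step_um


@dataclass(frozen=True)
class PSFKernel:
    """A discrete, unit-sum 2-D blur kernel for one defocus depth."""

    weights: np.ndarray
    z_um: float
    params: OpticalParams = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
            raise ValueError("kernel must be square with odd side length")
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1 within 1e-9")
        object.__setattr__(self, "weights", w)

    @property
    def radius(self) -> int:
        return self.weights.shape[0] // 2


@dataclass(frozen=True)
class SensorModel:
    """Camera model: digital offset (black level) and gain (counts/e-)."""

    offset: float = 100.0
    gain: float = 2.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")


def default_kernel_radius(params: OpticalParams, z_um: float) -> int:
    """Kernel half-width: 1.5x the geometric blur radius plus margin.

    The geometric blur radius at depth z is z * NA/n; divide by the pixel
    size to get pixels.
    """
    geo = abs(z_um) * params.numerical_aperture / params.refractive_index
    return max(4, math.ceil(1.5 * geo / params.pixel_size_um) + 4)


def _psf_unnormalized(params: OpticalParams, z_um: float, radius: int,
                      n_nodes: int) -> np.ndarray:
    """Evaluate |integral|^2 on the pixel grid, before normalization."""
    k = params.wavenumber                      # rad/nm
    na_n = params.numerical_aperture / params.refractive_index
    side = 2 * radius + 1
    ax = (np.arange(side) - radius) * params.pixel_size_um * 1e3  # nm
    r = np.hypot(ax[:, None], ax[None, :]).ravel()                # nm
    z_nm = z_um * 1e3

    rho = np.linspace(0.0, 1.0, n_nodes)
    bessel = special.j0(k * na_n * r[:, None] * rho[None, :])
    phase = np.exp(-0.5j * k * rho**2 * z_nm * na_n**2)
    integrand = bessel * (phase * rho)[None, :]
    integral = simpson(integrand, x=rho, axis=1)
    return np.abs(integral).reshape(side, side) ** 2


def compute_psf(params: OpticalParams, z_um: float, radius: int | None = None,
                n_nodes: int = 201, check_truncation: bool = True) -> PSFKernel:
    """Compute the normalized defocus PSF kernel at depth ``z_um``.

    Each pixel is a fixed-order composite-Simpson quadrature (``n_nodes``
    over rho in [0, 1]) of the diffraction integral, squared modulus, then
    the kernel is normalized to unit sum.  The kernel is even in z: the
    integrand at -z is the complex conjugate of the one at +z and only the
    modulus survives.

    Raises a ``UserWarning`` when more than 10% of the unnormalized kernel
    mass falls outside the requested radius (truncation).
    """
    if not np.isfinite(z_um):
        raise ValueError(f"z must be finite, got {z_um}")
    if radius is None:
        radius = default_kernel_radius(params, z_um)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if n_nodes < 3:
        raise ValueError("need at least 3 quadrature nodes")

    raw = _psf_unnormalized(params, z_um, radius, n_nodes)
    if check_truncation:
        wide = _psf_unnormalized(params, z_um, radius + max(4, radius // 2),
                                 max(51, n_nodes // 2 * 2 + 1))
        lost = 1.0 - raw.sum() / wide.sum()
        if lost > 0.10:
            warnings.warn(
                f"kernel radius {radius} truncates {lost:.1%} of PSF mass "
                f"at z={z_um} um; increase radius",
                UserWarning, stacklevel=2)
    return PSFKernel(weights=raw / raw.sum(), z_um=z_um, params=params)


def airy_pattern(params: OpticalParams, radius: int) -> np.ndarray:
    """Closed-form in-focus PSF, (2 J1(v)/v)^2, normalized to unit sum.

    Independent reference for the z=0 limit of :func:`compute_psf`.
    """
    k = params.wavenumber
    na_n = params.numerical_aperture / params.refractive_index
    side = 2 * radius + 1
    ax = (np.arange(side) - radius) * params.pixel_size_um * 1e3
    v = k * na_n * np.hypot(ax[:, None], ax[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (2.0 * special.j1(v) / v) ** 2
    a[v == 0] = 1.0
    return a / a.sum()


def energy_diameter(kernel: PSFKernel | np.ndarray, fraction: float = 0.8) -> float:
    """Diameter (pixels) of the centred disk enclosing ``fraction`` of kernel mass."""
    w = kernel.weights if isinstance(kernel, PSFKernel) else np.asarray(kernel)
    radius = w.shape[0] // 2
    ax = np.arange(w.shape[0]) - radius
    r = np.hypot(ax[:, None], ax[None, :]).ravel()
    order = np.argsort(r)
    cum = np.cumsum(w.ravel()[order]) / w.sum()
    idx = np.searchsorted(cum, fraction)
    return 2.0 * r[order][min(idx, r.size - 1)]


def defocus_image(image: np.ndarray, kernel: PSFKernel) -> np.ndarray:
    """Convolve an image with a defocus kernel (reflective boundary).

    Reflective padding avoids dark edges that would mimic defocus.  Output
    has the input's shape; total intensity is conserved up to boundary
    effects because the kernel sums to one.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    w = kernel.weights
    if w.shape[0] > img.shape[0] or w.shape[1] > img.shape[1]:
        raise ValueError(
            f"kernel {w.shape} larger than image {img.shape}")
    pad = w.shape[0] // 2
    padded = np.pad(img, pad, mode="reflect")
    out = signal.fftconvolve(padded, w, mode="same")
    out = out[pad:pad + img.shape[0], pad:pad + img.shape[1]]
    return np.clip(out, 0.0, None)


def apply_poisson_noise(image: np.ndarray, sensor: SensorModel,
                        seed: int | np.random.Generator) -> np.ndarray:
    """Apply shot noise in photoelectron units.

    Converts counts to expected photoelectrons ``e = max(image - offset, 0)
    / gain``, samples Poisson(e) per pixel, and maps back through the gain
    and offset, clipping to the 16-bit range.  Pure function of
    (image, sensor, seed).
    """
    img = np.asarray(image, dtype=np.float64)
    if np.any(img < 0) or np.any(img > UINT16_MAX):
        raise ValueError("image values must lie in [0, 65535]")
    rng = np.random.default_rng(seed)
    electrons = np.maximum(img - sensor.offset, 0.0) / sensor.gain
    sample = rng.poisson(electrons).astype(np.float64)
    return np.clip(sample * sensor.gain + sensor.offset, 0.0, UINT16_MAX)


def generate_defocus_stack(in_focus: np.ndarray, params: OpticalParams,
                           sensor: SensorModel,
                           seed: int | np.random.Generator
                           ) -> list[tuple[np.ndarray, int]]:
    """Build the ordered synthetic defocus stack from one in-focus image.

    Level L is the input convolved with the PSF at z = L * z_step, then
    shot-noised; level 0 is the noised original.  Returns ``n_levels``
    pairs ``(image, level)`` ordered least to most defocused.
    """
    rng = np.random.default_rng(seed)
    stack: list[tuple[np.ndarray, int]] = []
    for level, z in enumerate(params.z_depths_um()):
        if level == 0:
            blurred = np.asarray(in_focus, dtype=np.float64)
        else:
            kernel = compute_psf(params, z, check_truncation=False)
            blurred = defocus_image(in_focus, kernel)
        stack.append((apply_poisson_noise(np.clip(blurred, 0, UINT16_MAX),
                                          sensor, rng), level))
    return stack


def augment_gain_offset(image: np.ndarray,
                        gain_range: tuple[float, float] = (0.2, 5.0),
                        offset_range: tuple[float, float] = (1.0, 1000.0),
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Photometric augmentation: random log-uniform gain and offset.

    Draws ``g`` log-uniform in ``gain_range`` and ``o`` log-uniform in
    ``offset_range`` and returns ``clip(image * g + o, 0, 65535)``.  This is
    what teaches the classifier to ignore brightness and black level over
    the 16-bit dynamic range.
    """
    for lo, hi in (gain_range, offset_range):
        if not (lo > 0 and hi > 0):
            raise ValueError("log-uniform range bounds must be positive")
        if not lo <= hi:
            raise ValueError("range must satisfy low <= high")
    rng = np.random.default_rng(seed)
    g = sample_log_uniform(rng, *gain_range)
    o = sample_log_uniform(rng, *offset_range)
    return np.clip(np.asarray(image, dtype=np.float64) * g + o, 0.0, UINT16_MAX)


def sample_log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    """One draw whose logarithm is uniform on [log low, log high]."""
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))
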