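"""Power log-log slope (PLLS): the classical spectral focus metric.

Defocus blur is a low-pass filter: it strips high spatial frequencies.
PLLS quantifies this by radially averaging the image's power spectral
density and fitting a line to log(power) versus log(frequency); the slope
— a single scalar, more negative for blurrier images — is the metric.
Because only the spectral *shape* matters, PLLS is invariant to
multiplicative gain (which shifts the intercept) and to additive offset
(the image mean is removed before the FFT).  It provides only a relative
ranking of images, which is why it needs a user-chosen threshold for any
in/out-of-focus decision — the limitation the patch classifier removes.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .patches_model import tile_patches

__all__ = ["RadialPSD", "radial_psd", "plls", "plls_patchwise"]

# OLS fit band in cycles/pixel; excludes the lowest frequencies (dominated
# by scene layout) and the corner frequencies beyond Nyquist on the axes.
DEFAULT_FIT_BAND = (0.05, 0.45)


@dataclass(frozen=True)
class RadialPSD:
    """Radially averaged power spectrum: frequencies in (0, 0.5], power >= 0."""

    frequencies: np.ndarray
    power: np.ndarray
    is_constant: bool = False


def radial_psd(image: np.ndarray, n_bins: int | None = None,
               window: str | None = None) -> RadialPSD:
    """Radially binned periodogram of a mean-subtracted image.

    The 2-D power spectrum |FFT|^2 is averaged in ``n_bins`` equal-width
    annuli of spatial-frequency magnitude over (0, 0.5] cycles/pixel; the
    DC term is excluded by the mean subtraction and the bin lower edge.
    ``window='hann'`` applies a separable Hann window first.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("image must be 2-D and at least 16 x 16")
    if n_bins is None:
        n_bins = max(8, min(img.shape) // 4)
    constant = bool(np.ptp(img) == 0)
    img = img - img.mean()
    if window == "hann":
        img = img * np.outer(np.hanning(img.shape[0]), np.hanning(img.shape[1]))
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    psd2 = np.abs(np.fft.fft2(img)) ** 2
    fy = np.fft.fftfreq(img.shape[0])
    fx = np.fft.fftfreq(img.shape[1])
    fmag = np.hypot(fy[:, None], fx[None, :]).ravel()
    sel = (fmag > 0) & (fmag <= 0.5)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    idx = np.clip(np.digitize(fmag[sel], edges) - 1, 0, n_bins - 1)
    power = np.bincount(idx, weights=psd2.ravel()[sel], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialPSD(frequencies=centers[occupied],
                     power=power[occupied] / counts[occupied],
                     is_constant=constant)


def plls(image: np.ndarray, fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
         n_bins: int | None = None, window: str | None = None) -> float:
    """OLS slope of log power vs log frequency over the fit band."""
    spec = radial_psd(image, n_bins=n_bins, window=window)
    if spec.is_constant:
        raise ValueError("PLLS undefined for a constant image")
    lo, hi = fit_band
    sel = (spec.frequencies >= lo) & (spec.frequencies <= hi) & (spec.power > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 usable frequency bins in the fit band")
    slope, _ = np.polyfit(np.log(spec.frequencies[sel]),
                          np.log(spec.power[sel]), 1)
    return float(slope)


def plls_patchwise(image: np.ndarray, patch_size: int = 84,
                   fit_band: tuple[float, float] = DEFAULT_FIT_BAND
                   ) -> tuple[list[tuple[float, int, int]], float]:
    """PLLS on each tile of the non-overlapping patch grid.

    Returns per-patch ``(slope, row, col)`` and the image score — the
    arithmetic mean of the finite patch slopes (constant patches are
    skipped).
    """
    slopes: list[tuple[float, int, int]] = []
    finite: list[float] = []
    for patch, row, col in tile_patches(image, patch_size):
        try:
            s = plls(patch, fit_band=fit_band)
        except ValueError:
            slopes.append((float("nan"), row, col))
            continue
        slopes.append((s, row, col))
        finite.append(s)
    if not finite:
        raise ValueError("all patches are constant; PLLS undefined")
    return slopes, float(np.mean(finite))
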