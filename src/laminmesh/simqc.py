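"""SIM quality control and resolution arithmetic.

Structured illumination microscopy (SIM) acquires frames under phase-shifted
sinusoidal illumination ``1 + cos(nu.x + phi_p)`` with equispaced phases
``phi_p = 2*pi*(p-1)/P``.  Averaging the phases of one angle cancels the
modulation exactly (the phase-sum identity), so a synthesized widefield image
falls out of the raw stack for free and makes the first sanity check on an
acquisition.  Further checks here: the DC-centered log-magnitude Fourier
display used to inspect reconstruction quality, the SIM/widefield band-ratio
image, and Rayleigh/Nyquist resolution calculators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from laminmesh.types import RasterImage, SIMRawStack


@dataclass
class ResolutionParams:
    """Optical parameters for Rayleigh-criterion resolution limits."""

    lambda_nm: float  # emission wavelength
    na: float  # numerical aperture
    eta: float = 1.52  # refractive index of the mounting medium

    def __post_init__(self) -> None:
        if not self.lambda_nm > 0:
            raise ValueError("lambda_nm must be positive")
        if not 0 < self.na <= self.eta:
            raise ValueError(
                f"need 0 < NA <= eta (physical aperture bound); got NA={self.na}, eta={self.eta}"
            )


@dataclass
class FourierImage:
    """DC-centered log-magnitude Fourier display of an image."""

    f_log: np.ndarray  # log(|FFT| + 1), always >= 0
    freq_per_nm: tuple  # (df_y, df_x) in cycles/nm per frequency pixel
    dc_centered: bool = True

    def cutoff_radius_px(self, cutoff_nm: float) -> float:
        """Radius in frequency pixels of a real-space resolution cutoff.

        A feature of period ``cutoff_nm`` sits at spatial frequency
        ``1/cutoff_nm``; with frequency pixel ``df = 1/(N*pixel_size)`` the
        radius is ``N*pixel_size/cutoff_nm`` (isotropic pixels assumed; the
        mean of the two axis scalings is used otherwise).
        """
        if cutoff_nm <= 0:
            raise ValueError("cutoff_nm must be positive")
        df = float(np.mean(self.freq_per_nm))
        return (1.0 / cutoff_nm) / df


@dataclass
class WidefieldResult:
    widefield: RasterImage
    per_angle: list  # list of RasterImage, one per illumination angle
    max_angle_relative_difference: float


def synthesize_widefield(stack: SIMRawStack, pixel_size_nm: float = 1.0) -> WidefieldResult:
    """Average phases per angle, then angles, to synthesize a widefield image.

    The per-angle widefields should be nearly identical (the same object is
    imaged at each angle); ``max_angle_relative_difference`` is the largest
    mean absolute difference between any two per-angle widefields relative to
    the overall widefield mean — a single QC number that should be ~0.
    """
    if stack.n_phases < 2:
        raise ValueError("phase averaging needs at least 2 phases")
    per_angle = stack.frames.mean(axis=1)  # (A, H, W)
    overall = per_angle.mean(axis=0)
    scale = np.abs(overall).mean()
    max_rel = 0.0
    A = per_angle.shape[0]
    for i in range(A):
        for j in range(i + 1, A):
            diff = np.abs(per_angle[i] - per_angle[j]).mean()
            max_rel = max(max_rel, diff / scale if scale > 0 else diff)
    return WidefieldResult(
        widefield=RasterImage(overall, pixel_size_nm),
        per_angle=[RasterImage(a, pixel_size_nm) for a in per_angle],
        max_angle_relative_difference=float(max_rel),
    )


def log_fourier(img: RasterImage) -> FourierImage:
    """DC-centered ``log(|FFT2| + 1)`` display of an image.

    No window is applied before the transform.
    """
    F = np.fft.fftshift(np.fft.fft2(img.pixels))
    f_log = np.log(np.abs(F) + 1.0)
    h, w = img.pixels.shape
    return FourierImage(
        f_log=f_log,
        freq_per_nm=(1.0 / (h * img.pixel_size_nm), 1.0 / (w * img.pixel_size_nm)),
    )


def widefield_reference(recon: RasterImage, widefield_resolution_nm: float) -> RasterImage:
    """Resolution-reduced copy of a reconstruction for the band ratio.

    Gaussian blur with sigma = R/2.355 (FWHM-matched to the widefield
    resolution R) in pixel units.
    """
    sigma_px = widefield_resolution_nm / 2.355 / recon.pixel_size_nm
    return RasterImage(
        ndimage.gaussian_filter(recon.pixels, sigma_px, mode="mirror"),
        recon.pixel_size_nm,
    )


def band_ratio(
    recon: RasterImage,
    reference: RasterImage | None = None,
    epsilon: float | None = None,
    widefield_resolution_nm: float = 250.0,
) -> RasterImage:
    """Pixelwise ratio of a SIM reconstruction over a widefield-scale reference.

    The ratio highlights where the reconstruction gained contrast over
    diffraction-limited imaging; it peaks on fiber centerlines and is reused
    by the meshwork audit.  ``reference`` defaults to a FWHM-matched Gaussian
    blur of ``recon``; ``epsilon`` regularizes the division and defaults to
    1e-6 times the 99th percentile of the reference.
    """
    if reference is None:
        reference = widefield_reference(recon, widefield_resolution_nm)
    if reference.pixels.shape != recon.pixels.shape:
        raise ValueError(
            f"shape mismatch: recon {recon.pixels.shape} vs reference {reference.pixels.shape}"
        )
    if epsilon is None:
        epsilon = 1e-6 * float(np.percentile(reference.pixels, 99))
    out = RasterImage(recon.pixels / (reference.pixels + epsilon), recon.pixel_size_nm)
    out.epsilon = epsilon  # provenance for the QC report
    return out


# ---------------------------------------------------------------------------
# Rayleigh / Nyquist arithmetic
# ---------------------------------------------------------------------------

def rayleigh_lateral(p: ResolutionParams) -> float:
    """Lateral Rayleigh resolution ``0.61 * lambda / NA`` in nm."""
    return 0.61 * p.lambda_nm / p.na


def rayleigh_axial(p: ResolutionParams) -> float:
    """Axial Rayleigh resolution ``2 * eta * lambda / NA**2`` in nm."""
    return 2.0 * p.eta * p.lambda_nm / p.na**2


def nyquist_pixel_bound(resolution_nm: float) -> float:
    """Strict upper bound on pixel (or z-step) size: half the resolution."""
    if not resolution_nm > 0:
        raise ValueError("resolution_nm must be positive")
    return resolution_nm / 2.0
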