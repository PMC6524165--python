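"""Even-order steerable ridge filtering, orientation maps, non-maximum suppression.

The order-M ridge detector (M even, default 4) combines even directional
derivatives of an isotropic Gaussian taken *perpendicular* to the candidate
ridge orientation.  Writing the unit perpendicular as v = (-sin t, cos t),

    k_t = sum_{n even, 2 <= n <= M} c_n sigma^n (d/dv)^n G_sigma,
    c_n = (-1)^(n/2) (1/4)^((n-2)/2)   (so c_2 = -1, c_4 = +1/4, ...)

Each (d/dv)^n term expands binomially into x/y Gaussian-derivative basis
kernels, so the response at *any* orientation is a fixed linear combination
of the basis responses: the filter is exactly steerable.  As a function of
orientation the response is a trigonometric polynomial with even harmonics
up to M (period pi), fully determined by M+1 samples over [0, pi).

The second-derivative term carries the ridge sensitivity; the damped
higher-order terms sharpen orientation selectivity.  The damping weight 1/4
is chosen so the cross-sectional profile has essentially no positive side
lobes (< 0.5% of the central peak at matched fiber scale) — a pure M-th
derivative would ring, and non-maximum suppression would convert its side
lobes into phantom centerlines parallel to every real fiber.

A bright fiber of Gaussian cross-section yields a positive response maximized
when t equals the fiber orientation; a constant image yields zero (the kernels
have zero mean).  Non-maximum suppression then keeps a pixel only if its
response is >= the two values bilinearly interpolated one pixel away on either
side along the perpendicular, thinning each ridge to its centerline.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import ndimage

from laminmesh.types import NMSMap, OrientationField, RasterImage


@dataclass
class SteerableFilterConfig:
    order: int = 4
    sigma_px: float = 2.0
    n_sampled_angles: int = 9

    def __post_init__(self) -> None:
        if self.order % 2 != 0 or self.order < 2:
            raise ValueError(
                f"ridge detection requires an even order >= 2, got {self.order}"
            )
        if not self.sigma_px > 0:
            raise ValueError("sigma_px must be positive")
        if self.n_sampled_angles < self.order + 1:
            raise ValueError(
                f"need at least order+1={self.order + 1} sampled angles for exact "
                f"steering, got {self.n_sampled_angles}"
            )


def _gaussian_derivative_1d(n: int, sigma: float, radius: int) -> np.ndarray:
    """Samples of d^n/dx^n of a unit-mass 1D Gaussian on [-radius, radius].

    Uses d^n/dx^n e^(-u^2) = (-1)^n H_n(u) e^(-u^2) with u = x/(sigma*sqrt(2))
    and physicists' Hermite polynomials H_n.
    """
    x = np.arange(-radius, radius + 1, dtype=float)
    u = x / (sigma * np.sqrt(2.0))
    # H_n by the recurrence H_{k+1} = 2u H_k - 2k H_{k-1}
    h_prev, h = np.ones_like(u), 2.0 * u
    if n == 0:
        hermite = h_prev
    elif n == 1:
        hermite = h
    else:
        for k in range(1, n):
            h_prev, h = h, 2.0 * u * h - 2.0 * k * h_prev
        hermite = h
    g = np.exp(-(u**2)) / (np.sqrt(2.0 * np.pi) * sigma)
    return ((-1.0) ** n) * hermite * g / (sigma * np.sqrt(2.0)) ** n


class FilterBank:
    """Steerable ridge-filter bank: basis kernels, sampled-angle kernels, mean filter."""

    # damping of successive derivative orders; see module docstring
    ORDER_DAMPING = 0.25

    def __init__(self, cfg: SteerableFilterConfig):
        self.cfg = cfg
        M, sigma = cfg.order, cfg.sigma_px
        self.radius = int(np.ceil(4.0 * sigma)) + 1
        self._g = {n: _gaussian_derivative_1d(n, sigma, self.radius) for n in range(M + 1)}
        # flat basis: one kernel per (derivative order n, x/y split j);
        # sigma^n-normalized and mean-removed so every steered kernel has
        # exactly zero DC response on the grid
        self.orders = list(range(2, M + 1, 2))
        self.order_weights = {
            n: ((-1.0) ** (n // 2)) * self.ORDER_DAMPING ** ((n - 2) // 2)
            for n in self.orders
        }
        self.terms = []  # (n, j) per basis kernel
        self.basis = []
        for n in self.orders:
            scale = sigma**n
            for j in range(n + 1):
                k = scale * np.outer(self._g[j], self._g[n - j])  # [row=y, col=x]
                # remove residual DC analytically (the product of 1D means
                # commutes, keeping the basis exactly symmetric under x/y swap)
                dc = scale * (self._g[j].mean() * self._g[n - j].mean())
                self.terms.append((n, j))
                self.basis.append(k - dc)
        self.angles = np.arange(cfg.n_sampled_angles) * np.pi / cfg.n_sampled_angles
        self.kernels = [self.kernel_at(t) for t in self.angles]

    def steering_coefficients(self, theta) -> np.ndarray:
        """Per-basis-term coefficients such that k_theta = sum_i c_i * basis[i]."""
        s, c = -np.sin(theta), np.cos(theta)
        return np.array(
            [
                self.order_weights[n] * comb(n, j) * s ** (n - j) * c**j
                for n, j in self.terms
            ]
        )

    def kernel_at(self, theta: float) -> np.ndarray:
        """Ridge kernel oriented at ``theta`` (even-symmetric, zero mean)."""
        coeffs = self.steering_coefficients(theta)
        out = np.zeros_like(self.basis[0])
        for cj, b in zip(coeffs, self.basis):
            out += cj * b
        return out

    def mean_kernel(self) -> np.ndarray:
        """Orientation average of the bank: an isotropic annular bandpass.

        The angular average of sin^a cos^b over uniform orientation is
        (a-1)!!(b-1)!!/(a+b)!! for a, b even (else zero), turning each
        directional derivative into a Laplacian-power-of-Gaussian term; for
        the pure 4th-derivative part this is 3/8 (Gxxxx + Gyyyy) + 3/4 Gxxyy.
        The symmetric grouping (b_{n,j} + b_{n,n-j}) keeps the array
        bit-exactly invariant under 90-degree rotation.
        """

        def dfact(n: int) -> int:
            out = 1
            while n > 1:
                out *= n
                n -= 2
            return out

        def avg(n: int, j: int) -> float:
            a, b = n - j, j
            if a % 2 or b % 2:
                return 0.0
            return dfact(a - 1) * dfact(b - 1) / dfact(a + b)

        index = {t: b for t, b in zip(self.terms, self.basis)}
        out = np.zeros_like(self.basis[0])
        for n in self.orders:
            wn = self.order_weights[n]
            for j in range(0, n // 2):
                w = wn * comb(n, j) * avg(n, j)
                if w:
                    out += w * (index[(n, j)] + index[(n, n - j)])
            out += wn * comb(n, n // 2) * avg(n, n // 2) * index[(n, n // 2)]
        return out

    def basis_responses(self, image: np.ndarray) -> list:
        """Convolutions of the image with every basis kernel (mirror padding)."""
        return [ndimage.convolve(image, b, mode="mirror") for b in self.basis]


def build_filter_bank(cfg: SteerableFilterConfig | None = None) -> FilterBank:
    return FilterBank(cfg or SteerableFilterConfig())


def steer_response(sampled_responses, theta, order: int = 4):
    """Interpolate the orientation response at arbitrary ``theta``.

    ``sampled_responses`` are responses (scalars or arrays) at equispaced
    angles ``k*pi/N``; the response is band-limited (harmonics up to the
    filter order in theta, i.e. up to order/2 in phi = 2*theta), so the
    trigonometric interpolation is exact for N >= order+1.  ``theta`` may be a
    scalar or an array broadcastable against the samples.
    """
    R = np.asarray(sampled_responses, dtype=float)
    N = R.shape[0]
    if N < order + 1:
        raise ValueError(
            f"steering an order-{order} response needs at least {order + 1} "
            f"sampled angles, got {N}"
        )
    # Fourier series in phi = 2*theta over one period (pi in theta)
    C = np.fft.rfft(R, axis=0) / N  # harmonics m = 0 .. N//2 in phi
    theta = np.asarray(theta, dtype=float)
    phi = 2.0 * theta
    out = C[0].real * np.ones_like(phi) if np.ndim(C[0]) == 0 else C[0].real + np.zeros_like(phi)
    n_harm = C.shape[0]
    for m in range(1, n_harm):
        fac = 1.0 if (N % 2 == 0 and m == N // 2) else 2.0
        out = out + fac * (C[m].real * np.cos(m * phi) - C[m].imag * np.sin(m * phi))
    return out


def _response_at(theta, basis_responses, bank: FilterBank):
    """Evaluate the steered response at a per-pixel angle array (or scalar)."""
    s, c = -np.sin(theta), np.cos(theta)
    out = np.zeros(np.broadcast(theta, basis_responses[0]).shape)
    for (n, j), r in zip(bank.terms, basis_responses):
        out += bank.order_weights[n] * comb(n, j) * s ** (n - j) * c**j * r
    return out


def detect_orientations(
    img: RasterImage,
    cfg: SteerableFilterConfig | None = None,
    n_dense: int = 181,
) -> OrientationField:
    """Best ridge orientation and maximal response at every pixel.

    The orientation response is a band-limited trigonometric polynomial, so
    the maximum is located by a dense angular scan (``n_dense`` angles over
    [0, pi)) followed by one parabolic refinement step, then re-evaluated
    analytically at the refined angle.
    """
    cfg = cfg or SteerableFilterConfig()
    bank = FilterBank(cfg)
    h, w = img.pixels.shape
    ksize = 2 * bank.radius + 1
    if h < ksize or w < ksize:
        raise ValueError(
            f"image {h}x{w} smaller than the {ksize}x{ksize} filter kernel; "
            "reduce sigma_px or supply a larger image"
        )
    basis_r = bank.basis_responses(img.pixels)

    thetas = np.arange(n_dense) * np.pi / n_dense
    best = np.full((h, w), -np.inf)
    best_t = np.zeros((h, w))
    for t in thetas:
        R = _response_at(t, basis_r, bank)
        better = R > best
        best[better] = R[better]
        best_t[better] = t
    # parabolic refinement around the dense-grid argmax
    dt = np.pi / n_dense
    r_minus = _response_at(best_t - dt, basis_r, bank)
    r_plus = _response_at(best_t + dt, basis_r, bank)
    denom = r_minus - 2.0 * best + r_plus
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * dt * (r_minus - r_plus) / denom, 0.0)
    shift = np.clip(shift, -dt, dt)
    theta_star = np.mod(best_t + shift, np.pi)
    theta_star[theta_star >= np.pi] -= np.pi  # guard the mod's closed endpoint
    response = _response_at(theta_star, basis_r, bank)
    # refinement can only improve on the grid maximum; guard round-off
    worse = response < best
    response[worse] = best[worse]
    theta_star[worse] = best_t[worse]
    return OrientationField(response=response, theta=theta_star, config=cfg)


def nonmax_suppress(field: OrientationField) -> NMSMap:
    """Suppress pixels that are not maximal across their ridge.

    A pixel survives when its (positive) response is >= both values
    bilinearly interpolated at unit-distance offsets along the perpendicular
    (-sin t, cos t) to its orientation; ties are kept so plateaus are not
    deleted.  Everything else is zeroed.
    """
    R, theta = field.response, field.theta
    h, w = R.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    # perpendicular offset in (row, col) = (cos t, -sin t)
    dr, dc = np.cos(theta), -np.sin(theta)
    side1 = ndimage.map_coordinates(R, [rows + dr, cols + dc], order=1, mode="nearest")
    side2 = ndimage.map_coordinates(R, [rows - dr, cols - dc], order=1, mode="nearest")
    keep = (R >= side1) & (R >= side2) & (R > 0)
    values = np.where(keep, R, 0.0)
    return NMSMap(values=values, theta=theta)


def suppress_parallel_ridges(nms: NMSMap, radius_px: float) -> NMSMap:
    """Drop centerlines shadowed by a stronger parallel centerline.

    Two ridges closer than the detector's resolution (~2x the effective
    sigma) cannot both be real: the weaker one is the side response of the
    stronger.  A surviving NMS pixel is zeroed when a strictly larger NMS
    value lies within ``radius_px`` along its perpendicular on either side
    (bilinear sampling at unit steps; ties are kept so genuinely equal
    parallel fibers survive).
    """
    if radius_px < 2:
        return NMSMap(values=nms.values.copy(), theta=nms.theta.copy())
    V, theta = nms.values, nms.theta
    h, w = V.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = np.cos(theta), -np.sin(theta)
    shadowed = np.zeros(V.shape, dtype=bool)
    for k in range(2, int(np.floor(radius_px)) + 1):
        for sign in (1.0, -1.0):
            other = ndimage.map_coordinates(
                V, [rows + sign * k * dr, cols + sign * k * dc], order=1, mode="nearest"
            )
            shadowed |= other > V
    values = np.where(shadowed, 0.0, V)
    return NMSMap(values=values, theta=theta.copy())
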