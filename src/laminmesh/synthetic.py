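"""Ground-truth phantom generators.

Real nuclear-lamina micrographs cannot ship with the package, so every
pipeline stage is exercised on synthetic data with analytic ground truth:

* meshwork phantoms — Poisson seed points in an elliptical "nucleus"; the
  truth fibers are the Voronoi edges of the seeds clipped to the nucleus plus
  the nucleus boundary ring (the lamina rim is itself a fiber bundle, and the
  nucleus must be enclosed by fibers for masking to work).  Fibers are
  rasterized with a Gaussian cross-section over a constant background, with
  optional Poisson (shot) or Gaussian (read) noise;
* raw SIM stacks — the phantom under phase-shifted sinusoidal illumination
  ``1 + m*cos(nu.x + phi_p)`` at several angles, blurred by a Gaussian PSF;
* localization scatters — points sampled along the truth fibers at a Poisson
  linear density, displaced by the localization precision, plus uniform
  background points.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon

from laminmesh.types import LocalizationSet, RasterImage, SIMRawStack


@dataclass
class MeshPhantomParams:
    """Study conditions for the meshwork phantom.

    Defaults emulate a SIM-scale field: 256x256 px at 32 nm pixels, a nucleus
    of ~7.4 x 5.4 um, ~14 meshwork faces of a few um^2 (the scale reported
    for sparse lamin meshworks), and a fiber peak 50x the background level.
    Lamin fibers are far thinner than the SIM resolution limit, so their
    imaged cross-section is PSF-limited: FWHM ~ 115 nm, i.e. sigma ~ 48 nm.
    """

    shape: tuple = (256, 256)
    pixel_size_nm: float = 32.0
    center_px: tuple = (128.0, 128.0)  # (row, col)
    semi_axes_px: tuple = (95.0, 115.0)  # (row, col) ellipse semi-axes
    n_seeds_mean: float = 14.0  # Poisson mean of Voronoi seed count
    fiber_sigma_nm: float = 48.0  # Gaussian cross-section sigma (FWHM ~ 115 nm)
    peak_intensity: float = 1000.0
    background: float = 20.0
    noise: str = "none"  # none | poisson | gaussian
    gaussian_noise_sigma: float = 10.0
    boundary_ring: bool = True

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.n_seeds_mean <= 0 or self.fiber_sigma_nm <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("n_seeds_mean, fiber_sigma_nm, pixel_size_nm must be > 0")


@dataclass
class PhantomTruth:
    """Analytic ground truth of a meshwork phantom (pixel coordinates, (row, col))."""

    seeds_px: np.ndarray  # (n, 2) Voronoi seed points
    segments_px: list  # list of (k, 2) float arrays: truth fiber polylines
    junctions_px: np.ndarray  # (m, 2) float: Voronoi vertices + boundary crossings
    nucleus_polygon_px: np.ndarray  # (v, 2) boundary ring vertices
    n_faces: int  # number of enclosed meshwork faces (= seed count)
    params: MeshPhantomParams = None  # type: ignore[assignment]
    seed: int = 0

    @property
    def total_segment_length_px(self) -> float:
        return sum(
            float(np.hypot(*np.diff(s, axis=0).T).sum()) for s in self.segments_px
        )


@dataclass
class IlluminationModel:
    """Sinusoidal structured illumination: ``1 + m*cos(2*pi*nu*u + phi_p)``."""

    nu_cycles_per_nm: float = 1.0 / 230.0
    angles_rad: tuple = (0.0, np.pi / 3.0, 2.0 * np.pi / 3.0)
    n_phases: int = 3
    modulation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("need at least 2 equispaced phases")

    @property
    def phases(self) -> np.ndarray:
        p = np.arange(1, self.n_phases + 1)
        return 2.0 * np.pi * (p - 1) / self.n_phases


def _ellipse_polygon(center, semi, n=256) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    rows = center[0] + semi[0] * np.sin(t)
    cols = center[1] + semi[1] * np.cos(t)
    return Polygon(np.stack([rows, cols], axis=1))


def _clipped_voronoi_segments(seeds: np.ndarray, nucleus: Polygon) -> list:
    """Voronoi edges of the seeds clipped to the nucleus polygon.

    Unbounded ridges are closed with a far point along the standard outward
    direction before clipping.
    """
    vor = Voronoi(seeds)
    center = seeds.mean(axis=0)
    span = 4.0 * max(np.ptp(seeds[:, 0]), np.ptp(seeds[:, 1]), 1.0)
    segments = []
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            a, b = vor.vertices[v1], vor.vertices[v2]
        else:
            vfin = vor.vertices[v2 if v1 < 0 else v1]
            tangent = seeds[p2] - seeds[p1]
            tangent = tangent / np.hypot(*tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = 0.5 * (seeds[p1] + seeds[p2])
            if np.dot(midpoint - center, normal) < 0:
                normal = -normal
            a, b = vfin, vfin + normal * span
        piece = LineString([a, b]).intersection(nucleus)
        if piece.is_empty:
            continue
        geoms = getattr(piece, "geoms", [piece])
        for geom in geoms:
            if isinstance(geom, LineString) and geom.length > 0:
                segments.append(np.asarray(geom.coords, dtype=float))
    return segments


def _rasterize_segments(
    shape, segments, sigma_px: float, peak: float
) -> np.ndarray:
    """Draw fibers with Gaussian cross-section; overlaps take the maximum."""
    img = np.zeros(shape)
    h, w = shape
    reach = int(np.ceil(4.0 * sigma_px)) + 1
    for seg in segments:
        for a, b in zip(seg[:-1], seg[1:]):
            r0 = max(int(np.floor(min(a[0], b[0]))) - reach, 0)
            r1 = min(int(np.ceil(max(a[0], b[0]))) + reach + 1, h)
            c0 = max(int(np.floor(min(a[1], b[1]))) - reach, 0)
            c1 = min(int(np.ceil(max(a[1], b[1]))) + reach + 1, w)
            if r0 >= r1 or c0 >= c1:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                d2 = (rr - a[0]) ** 2 + (cc - a[1]) ** 2
            else:
                t = ((rr - a[0]) * ab[0] + (cc - a[1]) * ab[1]) / denom
                t = np.clip(t, 0.0, 1.0)
                d2 = (rr - (a[0] + t * ab[0])) ** 2 + (cc - (a[1] + t * ab[1])) ** 2
            patch = peak * np.exp(-d2 / (2.0 * sigma_px**2))
            np.maximum(img[r0:r1, c0:c1], patch, out=img[r0:r1, c0:c1])
    return img


def make_mesh_phantom(
    params: MeshPhantomParams | None = None, seed: int = 0
) -> tuple[RasterImage, PhantomTruth]:
    """Generate a meshwork phantom image plus its analytic truth."""
    params = params or MeshPhantomParams()
    rng = np.random.default_rng(seed)
    nucleus = _ellipse_polygon(params.center_px, params.semi_axes_px)

    n = int(rng.poisson(params.n_seeds_mean))
    if n < 3:
        raise ValueError(
            f"drew {n} seed points (mean {params.n_seeds_mean}); a meshwork needs >= 3"
        )
    seeds = []
    cr, cc = params.center_px
    ar, ac = params.semi_axes_px
    while len(seeds) < n:
        r = cr + (2.0 * rng.random() - 1.0) * ar
        c = cc + (2.0 * rng.random() - 1.0) * ac
        if ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 0.92**2:
            seeds.append((r, c))
    seeds = np.asarray(seeds)

    segments = _clipped_voronoi_segments(seeds, nucleus)
    ring = np.asarray(nucleus.exterior.coords, dtype=float)
    if params.boundary_ring:
        segments = segments + [ring]

    # truth junctions: Voronoi vertices inside the nucleus + boundary crossings
    vor = Voronoi(seeds)
    inside = [v for v in vor.vertices if nucleus.contains(Point(v))]
    boundary_pts = []
    boundary = nucleus.exterior
    for seg in segments[: len(segments) - (1 if params.boundary_ring else 0)]:
        for endpoint in (seg[0], seg[-1]):
            if boundary.distance(Point(endpoint)) < 1e-6:
                boundary_pts.append(endpoint)
    junctions = np.asarray(inside + boundary_pts, dtype=float).reshape(-1, 2)

    sigma_px = params.fiber_sigma_nm / params.pixel_size_nm
    img = params.background + _rasterize_segments(
        params.shape, segments, sigma_px, params.peak_intensity
    )
    if params.noise == "poisson":
        img = rng.poisson(img).astype(float)
    elif params.noise == "gaussian":
        img = img + rng.normal(0.0, params.gaussian_noise_sigma, size=img.shape)
    truth = PhantomTruth(
        seeds_px=seeds,
        segments_px=segments,
        junctions_px=junctions,
        nucleus_polygon_px=ring,
        n_faces=n,
        params=params,
        seed=seed,
    )
    return RasterImage(img, params.pixel_size_nm), truth


def make_sim_raw(
    phantom: RasterImage,
    model: IlluminationModel | None = None,
    psf_sigma_px: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SIMRawStack:
    """Simulate raw SIM frames of an object under sinusoidal illumination."""
    model = model or IlluminationModel()
    rng = np.random.default_rng(seed)
    h, w = phantom.pixels.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    x_nm = cols * phantom.pixel_size_nm
    y_nm = rows * phantom.pixel_size_nm
    frames = np.empty((len(model.angles_rad), model.n_phases, h, w))
    for ai, ang in enumerate(model.angles_rad):
        u = x_nm * np.cos(ang) + y_nm * np.sin(ang)
        for pi, phi in enumerate(model.phases):
            pattern = 1.0 + model.modulation * np.cos(
                2.0 * np.pi * model.nu_cycles_per_nm * u + phi
            )
            frame = phantom.pixels * pattern
            if psf_sigma_px > 0:
                frame = ndimage.gaussian_filter(frame, psf_sigma_px, mode="mirror")
            if noise_sigma > 0:
                frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
            frames[ai, pi] = frame
    return SIMRawStack(frames)


def make_localizations(
    truth: PhantomTruth,
    linear_density_per_nm: float = 0.05,
    precision_sigma_nm: float = 15.0,
    background_per_um2: float = 1.0,
    seed: int = 0,
) -> LocalizationSet:
    """Sample fluorophore localizations along the truth fibers.

    Points are placed along each truth polyline at a Poisson linear density,
    displaced isotropically by the localization precision; uniform background
    points are added at ``background_per_um2`` over the nucleus area.
    Coordinates are in nm with pixel centers at (k + 0.5) * pixel_size.
    """
    if linear_density_per_nm < 0 or background_per_um2 < 0:
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    px = truth.params.pixel_size_nm
    nucleus = Polygon(truth.nucleus_polygon_px)
    area_um2 = nucleus.area * px**2 / 1e6
    total_len_nm = truth.total_segment_length_px * px
    expected = linear_density_per_nm * total_len_nm + background_per_um2 * area_um2
    if expected <= 0:
        raise ValueError("zero expected localizations; raise a density")

    pts = []
    for seg in truth.segments_px:
        steps = np.diff(seg, axis=0)
        seg_lens = np.hypot(steps[:, 0], steps[:, 1])
        length_nm = seg_lens.sum() * px
        k = rng.poisson(linear_density_per_nm * length_nm)
        if k == 0:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
        s = rng.random(k) * cum[-1]
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_lens) - 1)
        frac = (s - cum[idx]) / np.where(seg_lens[idx] > 0, seg_lens[idx], 1.0)
        pos = seg[idx] + frac[:, None] * steps[idx]
        pts.append(pos)

    n_bg = rng.poisson(background_per_um2 * area_um2)
    if n_bg > 0:
        minr, minc, maxr, maxc = (
            truth.nucleus_polygon_px[:, 0].min(),
            truth.nucleus_polygon_px[:, 1].min(),
            truth.nucleus_polygon_px[:, 0].max(),
            truth.nucleus_polygon_px[:, 1].max(),
        )
        bg = []
        while len(bg) < n_bg:
            r = minr + rng.random() * (maxr - minr)
            c = minc + rng.random() * (maxc - minc)
            if nucleus.contains(Point([r, c])):
                bg.append((r, c))
        pts.append(np.asarray(bg))

    if not pts:
        raise ValueError("no localizations drawn; raise a density")
    rc = np.vstack(pts)  # (n, 2) in (row, col) px
    xy_nm = np.stack([(rc[:, 1] + 0.5) * px, (rc[:, 0] + 0.5) * px], axis=1)
    if precision_sigma_nm > 0:
        xy_nm = xy_nm + rng.normal(0.0, precision_sigma_nm, size=xy_nm.shape)
    return LocalizationSet(points=xy_nm)
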