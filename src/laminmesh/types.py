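"""Core data containers shared across the pipeline.

Conventions fixed package-wide (see docs/methods.md):

* pixel arrays are indexed ``(row, column) = (y, x)``, 0-based, y increasing
  downward, with pixel centers at integer coordinates;
* localization coordinates are continuous and in nanometers; a point maps to
  the pixel ``floor(x_nm / pixel_size_nm)`` (half-open bins);
* orientation angles are in radians in ``[0, pi)``, measured from the +x
  (column) axis toward +y (row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ORIGIN_CONVENTION = "upper-left,0-based,(row,col)=(y,x)"


@dataclass
class RasterImage:
    """A 2D grayscale image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite intensities (arbitrary units).
    pixel_size_nm : float
        Edge length of one pixel in nanometers; must be positive.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    origin: str = ORIGIN_CONVENTION

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def require_pipeline_size(self, minimum: int = 8) -> "RasterImage":
        """Entry gate for the filtering pipeline: both dimensions >= ``minimum``."""
        h, w = self.pixels.shape
        if h < minimum or w < minimum:
            raise ValueError(
                f"image {h}x{w} too small for pipeline entry (minimum {minimum})"
            )
        return self


@dataclass
class SIMRawStack:
    """Raw structured-illumination frames indexed (angle, phase, y, x)."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be 4D (angle, phase, y, x); got shape {self.frames.shape}"
            )
        if self.n_angles < 1:
            raise ValueError("need at least one illumination angle")
        if self.n_phases < 2:
            raise ValueError("need at least two phases per angle")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_angles(self) -> int:
        return self.frames.shape[0]

    @property
    def n_phases(self) -> int:
        return self.frames.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[2:]


@dataclass
class LocalizationSet:
    """Fluorophore coordinates (nm) from single-molecule localization microscopy."""

    points: np.ndarray  # (n, 2) columns (x_nm, y_nm)
    frame: Optional[np.ndarray] = None
    photons: Optional[np.ndarray] = None
    n_dropped: int = 0  # rows discarded on read for non-finite coordinates

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (n, 2); got shape {self.points.shape}")
        if len(self.points) < 1:
            raise ValueError("a LocalizationSet needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        for name in ("frame", "photons"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.points):
                raise ValueError(f"{name} length does not match points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in nm; contains every point."""
        xmin, ymin = self.points.min(axis=0)
        xmax, ymax = self.points.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)


@dataclass
class OrientationField:
    """Per-pixel best ridge orientation and maximal steerable response."""

    response: np.ndarray  # R(x, y) at the best orientation
    theta: np.ndarray  # theta*(x, y) in [0, pi)
    config: object = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.response.shape != self.theta.shape:
            raise ValueError("response and theta must share a shape")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response contains non-finite values")
        if np.any((self.theta < 0) | (self.theta >= np.pi)):
            raise ValueError("theta must lie in [0, pi)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.response.shape


@dataclass
class NMSMap:
    """Non-maximum-suppressed response: zero off ridge centerlines."""

    values: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.values.shape != self.theta.shape:
            raise ValueError("values and theta must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def support(self) -> np.ndarray:
        return self.values > 0


@dataclass
class Skeleton:
    """Binary candidate ridge pixels with companion orientations.

    ``extensions`` flags pixels added by orientation-guided endpoint extension
    (they are re-validated during meshwork auditing).
    """

    mask: np.ndarray
    theta: np.ndarray
    extensions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.extensions is None:
            self.extensions = np.zeros_like(self.mask)
        self.extensions = np.asarray(self.extensions, dtype=bool)
        if not (self.mask.shape == self.theta.shape == self.extensions.shape):
            raise ValueError("mask, theta and extensions must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class MeshEdge:
    """An ordered pixel path between two endpoints.

    ``endpoints`` holds junction ids, or ``None`` for a free-standing end.
    """

    id: int
    path: list  # list of (row, col) int tuples, ordered endpoint to endpoint
    endpoints: tuple  # (Optional[int], Optional[int])
    has_extension: bool = False
    attrs: dict = field(default_factory=dict)

    @property
    def length_px(self) -> float:
        """Path length: unit steps count 1, diagonal steps sqrt(2)."""
        if len(self.path) < 2:
            return 0.0
        p = np.asarray(self.path, dtype=float)
        steps = np.abs(np.diff(p, axis=0))
        return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())

    @property
    def core(self) -> list:
        """Path pixels that are detected skeleton, excluding the synthetic
        Bresenham link pixels joining the path to its junction nodes."""
        n_head = self.attrs.get("n_head", 0)
        n_tail = self.attrs.get("n_tail", 0)
        end = len(self.path) - n_tail
        out = self.path[n_head:end]
        return out if out else self.path


@dataclass
class MeshFace:
    """A region enclosed by meshwork edges."""

    id: int
    pixels: np.ndarray  # (k, 2) rows of (row, col)
    edge_ids: list
    touches_mask_boundary: bool = False

    @property
    def area_px(self) -> int:
        return len(self.pixels)


@dataclass
class MeshGraph:
    """Object-based meshwork: junction nodes, edge paths, enclosed faces."""

    junctions: list  # list of (row, col) int tuples
    edges: list  # list of MeshEdge
    faces: list = field(default_factory=list)  # list of MeshFace
    shape: tuple = None  # type: ignore[assignment]
    pixel_size_nm: float = 1.0

    def junction_degrees(self) -> np.ndarray:
        """Number of incident edge endpoints per junction."""
        deg = np.zeros(len(self.junctions), dtype=int)
        for e in self.edges:
            for j in e.endpoints:
                if j is not None:
                    deg[j] += 1
        return deg

    def rasterize(self) -> np.ndarray:
        """Boolean raster of every edge-path pixel and junction pixel."""
        out = np.zeros(self.shape, dtype=bool)
        for e in self.edges:
            for r, c in e.path:
                out[r, c] = True
        deg = self.junction_degrees()
        for jid, (r, c) in enumerate(self.junctions):
            if deg[jid] > 0:
                out[r, c] = True
        return out

    def with_edges(self, keep: list) -> "MeshGraph":
        """A copy of this graph restricted to the given edges (faces dropped)."""
        return MeshGraph(
            junctions=list(self.junctions),
            edges=list(keep),
            faces=[],
            shape=self.shape,
            pixel_size_nm=self.pixel_size_nm,
        )
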