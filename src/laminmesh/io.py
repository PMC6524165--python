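"""Reading and writing the raster and tabular formats the pipeline touches.

TIFF is the only mandated raster format (single- or multi-page grayscale);
localization tables are delimited text with named x/y columns in nanometers
(ThunderSTORM-style ``"x [nm]", "y [nm]"`` headers by default).  Meshwork
graphs export to JSON and GraphML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from laminmesh.types import LocalizationSet, MeshGraph, RasterImage

logger = logging.getLogger(__name__)

DEFAULT_X_COLUMN = "x [nm]"
DEFAULT_Y_COLUMN = "y [nm]"


class FormatError(ValueError):
    """Unreadable or unsupported input file."""


def read_raster(path, pixel_size_nm: float, page: int = 0) -> RasterImage:
    """Read one grayscale page of a TIFF file as a :class:`RasterImage`.

    Integer data are promoted to float; ``page`` selects a 0-based page of a
    multi-page stack.  ``pixel_size_nm`` always wins over file metadata: the
    caller's calibration is authoritative.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            n = len(tif.pages)
            if not 0 <= page < n:
                raise FormatError(f"page {page} out of range for {n}-page file {path}")
            arr = tif.pages[page].asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises assorted types for bad files
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3:
        raise FormatError(
            f"{path} page {page} has {arr.shape[-1]} samples per pixel; "
            "convert RGB/multichannel input to grayscale first"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path} page {page} is not a 2D image (shape {arr.shape})")
    return RasterImage(pixels=arr.astype(float), pixel_size_nm=pixel_size_nm)


def write_raster(path, image: RasterImage, dtype=None) -> None:
    """Write a :class:`RasterImage` to a single-page TIFF."""
    data = image.pixels if dtype is None else image.pixels.astype(dtype)
    tifffile.imwrite(str(path), data)


def write_stack(path, frames: np.ndarray, dtype=None) -> None:
    """Write a (pages, h, w) array as a true multi-page TIFF."""
    frames = np.asarray(frames)
    if dtype is not None:
        frames = frames.astype(dtype)
    with tifffile.TiffWriter(str(path)) as writer:
        for page in frames:
            writer.write(page, contiguous=False)


def read_stack(path, pixel_size_nm: float) -> list[RasterImage]:
    """Read every page of a multi-page TIFF."""
    with tifffile.TiffFile(str(path)) as tif:
        n = len(tif.pages)
    return [read_raster(path, pixel_size_nm, page=p) for p in range(n)]


def read_localizations(
    path,
    x_column: str = DEFAULT_X_COLUMN,
    y_column: str = DEFAULT_Y_COLUMN,
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = ",",
) -> LocalizationSet:
    """Read a delimited molecule list with x/y coordinates in nm.

    ``column_map`` may rename arbitrary vendor headers onto the default
    schema, e.g. ``{"Xc": "x [nm]", "Yc": "y [nm]"}``.  Rows with non-finite
    coordinates are dropped and the count logged.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in (x_column, y_column):
        if col not in df.columns:
            raise FormatError(
                f"missing column {col!r} in {path}; have {list(df.columns)}"
            )
    xy = df[[x_column, y_column]].to_numpy(dtype=float)
    finite = np.isfinite(xy).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d rows with non-finite coordinates from %s", n_dropped, path)
    df = df.loc[finite]
    xy = xy[finite]
    if len(xy) == 0:
        raise FormatError(f"no finite localizations in {path}")

    def _optional(name: str) -> Optional[np.ndarray]:
        return df[name].to_numpy() if name in df.columns else None

    return LocalizationSet(
        points=xy,
        frame=_optional("frame"),
        photons=_optional("intensity [photon]"),
        n_dropped=n_dropped,
    )


def write_localizations(
    path,
    locs: LocalizationSet,
    x_column: str = DEFAULT_X_COLUMN,
    y_column: str = DEFAULT_Y_COLUMN,
    decimals: int = 4,
) -> None:
    """Write a localization table in the default CSV dialect."""
    df = pd.DataFrame({x_column: locs.points[:, 0], y_column: locs.points[:, 1]})
    if locs.frame is not None:
        df["frame"] = locs.frame
    if locs.photons is not None:
        df["intensity [photon]"] = locs.photons
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def nm_to_pixel(x_nm: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Map continuous nm coordinates onto the pixel grid (half-open bins)."""
    return np.floor(np.asarray(x_nm, dtype=float) / pixel_size_nm).astype(int)


# ---------------------------------------------------------------------------
# Meshwork graph export
# ---------------------------------------------------------------------------

def graph_to_json_dict(g: MeshGraph) -> dict:
    return {
        "pixel_size_nm": g.pixel_size_nm,
        "shape": list(g.shape) if g.shape is not None else None,
        "junctions": [[int(r), int(c)] for r, c in g.junctions],
        "edges": [
            {
                "id": int(e.id),
                "path": [[int(r), int(c)] for r, c in e.path],
                "endpoints": [None if j is None else int(j) for j in e.endpoints],
                "has_extension": bool(e.has_extension),
                "attrs": {k: _jsonable(v) for k, v in e.attrs.items()},
            }
            for e in g.edges
        ],
        "faces": [
            {
                "id": int(f.id),
                "area_px": int(f.area_px),
                "edge_ids": [int(i) for i in f.edge_ids],
                "touches_mask_boundary": bool(f.touches_mask_boundary),
            }
            for f in g.faces
        ],
    }


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_graph_json(path, g: MeshGraph) -> None:
    Path(path).write_text(json.dumps(graph_to_json_dict(g), indent=1))


def read_graph_json(path) -> MeshGraph:
    from laminmesh.types import MeshEdge, MeshFace

    d = json.loads(Path(path).read_text())
    edges = [
        MeshEdge(
            id=e["id"],
            path=[tuple(p) for p in e["path"]],
            endpoints=tuple(e["endpoints"]),
            has_extension=e.get("has_extension", False),
            attrs=e.get("attrs", {}),
        )
        for e in d["edges"]
    ]
    faces = [
        MeshFace(
            id=f["id"],
            pixels=np.zeros((f["area_px"], 2), dtype=int),
            edge_ids=f["edge_ids"],
            touches_mask_boundary=f["touches_mask_boundary"],
        )
        for f in d.get("faces", [])
    ]
    return MeshGraph(
        junctions=[tuple(j) for j in d["junctions"]],
        edges=edges,
        faces=faces,
        shape=tuple(d["shape"]) if d.get("shape") else None,
        pixel_size_nm=d["pixel_size_nm"],
    )


def write_graph_graphml(path, g: MeshGraph) -> None:
    """Topology + scalar attributes as GraphML (pixel paths elided)."""
    G = nx.MultiGraph()
    for jid, (r, c) in enumerate(g.junctions):
        G.add_node(jid, row=int(r), col=int(c))
    free = len(g.junctions)  # synthetic node ids for free endpoints
    for e in g.edges:
        ends = []
        for j in e.endpoints:
            if j is None:
                G.add_node(free, free_end=True)
                ends.append(free)
                free += 1
            else:
                ends.append(j)
        G.add_edge(
            ends[0],
            ends[1],
            id=int(e.id),
            length_px=float(e.length_px),
            length_nm=float(e.length_px * g.pixel_size_nm),
        )
    nx.write_graphml(G, str(path))
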