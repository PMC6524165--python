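"""Shared fixtures: phantoms and pipeline runs are expensive, so session-scope them."""

from __future__ import annotations

import numpy as np
import pytest

from laminmesh import pipeline, synthetic
from laminmesh.types import RasterImage


@pytest.fixture(scope="session")
def phantom_params():
    return synthetic.MeshPhantomParams()


@pytest.fixture(scope="session")
def mesh_phantom(phantom_params):
    """One deterministic noise-free meshwork phantom with truth."""
    return synthetic.make_mesh_phantom(phantom_params, seed=1)


@pytest.fixture(scope="session")
def audited_phantom(mesh_phantom):
    """Full pipeline (segment + audit) on the session phantom."""
    img, truth = mesh_phantom
    return pipeline.segment_and_audit(img), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_image(rng):
    return RasterImage(rng.random((64, 64)), 32.0)


def junction_recall(graph, truth, tol_px: float = 3.0) -> np.ndarray:
    """Boolean hit array: truth junctions with a detected junction within tol."""
    deg = graph.junction_degrees()
    det = np.asarray(graph.junctions, dtype=float)[deg > 0]
    tj = np.asarray(truth.junctions_px, dtype=float)
    if len(det) == 0:
        return np.zeros(len(tj), dtype=bool)
    d = np.sqrt(((tj[:, None, :] - det[None, :, :]) ** 2).sum(-1)).min(axis=1)
    return d <= tol_px


def interior_faces(graph) -> list:
    return [f for f in graph.faces if not f.touches_mask_boundary]
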