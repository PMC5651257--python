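"""Geometric error between triangulated surfaces.

The error metric is the symmetric vertex-set Hausdorff distance: the largest
distance from any vertex of one surface to its closest vertex on the other,
taken over both directions.  Face lists are ignored — the comparison is
between vertex clouds, with no assumption of vertex correspondence.  An
index-matched variant (max distance between same-index vertices) is provided
for meshes that share a template parameterization, but is not used by the
default pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .surface_io import TriSurface


def _vertices(surface) -> np.ndarray:
    v = surface.vertices if isinstance(surface, TriSurface) else np.asarray(surface, float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ValueError(f"need a non-empty (n, 3) vertex array, got {v.shape}")
    return v


def directed_hausdorff_vertex(a, b) -> float:
    """max over vertices of A of the distance to the closest vertex of B."""
    va, vb = _vertices(a), _vertices(b)
    d, _ = cKDTree(vb).query(va, k=1)
    return float(np.max(d))


def hausdorff_vertex(a, b) -> float:
    """Symmetric vertex-set Hausdorff distance in mm."""
    return max(directed_hausdorff_vertex(a, b), directed_hausdorff_vertex(b, a))


def index_matched_max_error(a, b) -> float:
    """Max distance between corresponding (same-index) vertices."""
    va, vb = _vertices(a), _vertices(b)
    if va.shape != vb.shape:
        raise ValueError(
            f"index-matched error needs equal vertex counts, got {va.shape[0]} "
            f"and {vb.shape[0]}"
        )
    return float(np.max(np.linalg.norm(va - vb, axis=1)))
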