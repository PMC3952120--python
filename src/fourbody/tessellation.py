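"""Delaunay tessellation of atomic coordinates and the edge-length filter.

The Delaunay tessellation partitions the convex hull of the atom positions
into tetrahedra whose circumspheres contain no other atom, so each simplex is
an objective quadruplet of nearest-neighbour atoms.  Simplices spanning the
sparse outside of the hull can still pair atoms that are far apart, so any
tetrahedron with an edge longer than a cutoff (8 Angstrom by default) is
discarded before scoring; the surviving count N is the normalization used by
the topological score.

Qhull (via scipy.spatial) computes the triangulation.  Comparisons against the
cutoff are exact (no tolerance): a tetrahedron is retained iff all six edges
are <= cutoff in double precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import DegeneracyError

logger = logging.getLogger(__name__)

#: Default edge-length cutoff in Angstrom.
DEFAULT_CUTOFF = 8.0

# Vertex index pairs forming the 6 edges of a tetrahedron.
_EDGE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass(frozen=True)
class Tetrahedron:
    """One Delaunay simplex: four atom indices and its longest edge length."""

    vertex_indices: tuple[int, int, int, int]
    max_edge: float
    quadruplet_key: str | None = None

    def __post_init__(self):
        if len(set(self.vertex_indices)) != 4:
            raise ValueError("a tetrahedron needs four distinct vertices")


@dataclass
class Tessellation:
    """Edge-filtered tessellation; ``n_retained`` is the score normalizer N."""

    tetrahedra: list[Tetrahedron]
    n_raw: int
    cutoff: float

    @property
    def n_retained(self) -> int:
        return len(self.tetrahedra)


def tessellate(coords, jitter: bool = False, jitter_seed: int = 0) -> np.ndarray:
    """Compute Delaunay simplices of 3D points; returns an (m, 4) index array.

    Parameters
    ----------
    coords : array-like, shape (n, 3)
        Atomic positions in Angstrom; needs at least 4 non-coplanar points.
    jitter : bool
        If the input is degenerate (coplanar or otherwise non-triangulable),
        retry once after adding a deterministic perturbation of at most
        1e-6 Angstrom per coordinate.  Crystallographic coordinates rounded to
        three decimals can be exactly degenerate; the perturbation is far below
        coordinate precision and is logged when used.
    jitter_seed : int
        Seed for the perturbation stream (only used when ``jitter`` fires).

    Raises
    ------
    DegeneracyError
        Fewer than 4 points, non-finite coordinates, or degenerate geometry
        (with ``jitter=False``).
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegeneracyError(f"expected (n, 3) coordinates, got shape {pts.shape}")
    if len(pts) < 4:
        raise DegeneracyError(f"need at least 4 points to tessellate, got {len(pts)}")
    if not np.all(np.isfinite(pts)):
        raise DegeneracyError("coordinates contain non-finite values")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        reason = str(exc).splitlines()[0]
        if not jitter:
            raise DegeneracyError(
                f"degenerate point configuration (coplanar or coincident): {reason}"
            ) from exc
        rng = np.random.default_rng(jitter_seed)
        logger.warning(
            "degenerate input (%s); retrying with deterministic <=1e-6 A jitter", reason
        )
        try:
            tri = Delaunay(pts + rng.uniform(-1e-6, 1e-6, size=pts.shape))
        except QhullError as exc2:
            raise DegeneracyError(
                f"degenerate even after perturbation: {str(exc2).splitlines()[0]}"
            ) from exc2
    return np.sort(tri.simplices, axis=1)


def max_edge_length(vertex_indices, coords) -> float:
    """Longest of the six pairwise distances among a simplex's vertices."""
    pts = np.asarray(coords, dtype=float)[list(vertex_indices)]
    return max(float(np.linalg.norm(pts[i] - pts[j])) for i, j in _EDGE_PAIRS)


def filter_tetrahedra(simplices, coords, cutoff: float = DEFAULT_CUTOFF) -> Tessellation:
    """Discard every simplex having at least one edge longer than ``cutoff``.

    A tetrahedron with a removed edge is no longer a simplex, so the whole
    tetrahedron is dropped; retention at exactly the cutoff length.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    pts = np.asarray(coords, dtype=float)
    simplices = np.asarray(simplices, dtype=int)
    kept: list[Tetrahedron] = []
    for simplex in simplices:
        verts = pts[simplex]
        longest = max(
            float(np.linalg.norm(verts[i] - verts[j])) for i, j in _EDGE_PAIRS
        )
        if longest <= cutoff:
            kept.append(Tetrahedron(tuple(int(v) for v in simplex), longest))
    # canonical order: identical simplex sets sum identically downstream,
    # independent of Qhull's traversal order
    kept.sort(key=lambda t: t.vertex_indices)
    return Tessellation(tetrahedra=kept, n_raw=int(len(simplices)), cutoff=cutoff)


def tessellate_structure(structure, cutoff: float = DEFAULT_CUTOFF,
                         jitter: bool = False) -> Tessellation:
    """Tessellate a filtered Structure and apply the edge filter in one step."""
    coords = structure.coordinates()
    return filter_tetrahedra(tessellate(coords, jitter=jitter), coords, cutoff)
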