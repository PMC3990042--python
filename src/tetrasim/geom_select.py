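"""Element selection with bounding primitives.

Components of a tetrahedral geometry are identified as groups of element
indices.  For elements buried inside a mesh, direct (visual) range
selection cannot reach past the skin, so selection is done indirectly: a
convex bounding primitive (axis-aligned box, sphere or cylinder) is laid
over the mesh and every element is tested for containment.

"Coordinate matching" of an element against the primitive is ambiguous
for elements straddling the boundary, so the test point set is explicit:

``barycenter``
    the element's barycenter lies inside (default — matches the
    voxel-assignment intuition of one test point per element);
``all_vertices``
    every vertex of the element lies inside;
``any_vertex``
    at least one vertex lies inside.

Containment is inclusive, with an absolute slack of ``1e-12`` times the
primitive's characteristic scale so points exactly on an analytic surface
select deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import MeshError, Tetmesh

__all__ = [
    "AxisBox",
    "Sphere",
    "Cylinder",
    "SELECTION_MODES",
    "select_tets",
    "select_tris",
    "skin_triangles",
    "inner_tets",
    "point_in_tet",
    "union_ids",
    "intersect_ids",
    "difference_ids",
]

SELECTION_MODES = ("barycenter", "all_vertices", "any_vertex")

REL_TOL = 1e-12


@dataclass(frozen=True)
class AxisBox:
    """Axis-aligned box given by min and max corners (metres)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise MeshError("box corners must be 3D points")
        if not (lo < hi).all():
            raise MeshError("box min corner must be < max corner componentwise")

    @property
    def scale(self) -> float:
        return float(np.linalg.norm(np.asarray(self.hi) - np.asarray(self.lo)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        tol = REL_TOL * self.scale
        lo = np.asarray(self.lo) - tol
        hi = np.asarray(self.hi) + tol
        return ((p >= lo) & (p <= hi)).all(axis=1)


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise MeshError("sphere radius must be positive")

    @property
    def scale(self) -> float:
        return float(self.radius)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        tol = REL_TOL * self.scale
        d = np.linalg.norm(p - np.asarray(self.center, float), axis=1)
        return d <= self.radius + tol


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder between two axis endpoints, with given radius."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise MeshError("cylinder radius must be positive")
        if np.allclose(self.p0, self.p1):
            raise MeshError("cylinder endpoints must be distinct")

    @property
    def scale(self) -> float:
        length = float(np.linalg.norm(np.subtract(self.p1, self.p0)))
        return max(length, float(self.radius))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        tol = REL_TOL * self.scale
        a = np.asarray(self.p0, float)
        axis = np.asarray(self.p1, float) - a
        L2 = float(axis @ axis)
        rel = p - a
        s = rel @ axis  # axial parameter scaled by L2, in [0, L2] inside
        radial = np.linalg.norm(rel - np.outer(s / L2, axis), axis=1)
        return (
            (s >= -tol * np.sqrt(L2))
            & (s <= L2 + tol * np.sqrt(L2))
            & (radial <= self.radius + tol)
        )


def _test_points(coords: np.ndarray, mode: str):
    """Per-element boolean reduction for a containment mask over vertices."""
    if mode not in SELECTION_MODES:
        raise MeshError(
            f"unknown selection mode {mode!r}; expected one of {SELECTION_MODES}"
        )


def _select(mesh, elems, barycenters, bound, mode):
    _test_points(None, mode)
    if mode == "barycenter":
        mask = bound.contains(barycenters)
    else:
        nv = elems.shape[1]
        per_vertex = bound.contains(
            mesh.vertices[elems.ravel()]
        ).reshape(-1, nv)
        mask = per_vertex.all(axis=1) if mode == "all_vertices" else per_vertex.any(axis=1)
    return [int(i) for i in np.flatnonzero(mask)]


def select_tets(mesh: Tetmesh, bound, mode: str = "barycenter") -> list[int]:
    """Internal ids (sorted) of tets matched by the bounding primitive."""
    return _select(mesh, mesh.tets, mesh.tet_barycenters, bound, mode)


def select_tris(mesh: Tetmesh, bound, mode: str = "barycenter") -> list[int]:
    """Internal ids (sorted) of labeled triangles matched by the primitive."""
    if mesh.n_tris == 0:
        _test_points(None, mode)
        return []
    return _select(mesh, mesh.tris, mesh.tri_barycenters, bound, mode)


def skin_triangles(mesh: Tetmesh) -> list[int]:
    """Triangles on the outside of the mesh: faces incident to exactly one tet.

    Faces without a triangle label are labeled on the fly, so the returned
    ids are always valid ``mesh.tris`` indices.
    """
    return mesh.ensure_tris(mesh.skin_faces())


def inner_tets(mesh: Tetmesh, bound) -> list[int]:
    """Tets fully inside ``bound`` that do not touch the mesh skin.

    Selection uses ``all_vertices`` mode, then removes every tet incident
    to a skin face — including incidence through a single shared vertex,
    so the result contains only elements completely covered by others.
    """
    selected = select_tets(mesh, bound, mode="all_vertices")
    skin_vertices = np.zeros(mesh.n_vertices, dtype=bool)
    skin_vertices[np.unique(mesh.skin_faces())] = True
    return [t for t in selected if not skin_vertices[mesh.tets[t]].any()]


# Composite regions are expressed as set algebra on id lists, so any
# union / intersection / difference of convex primitives can be selected
# without a constructive-solid-geometry engine.


def union_ids(*id_lists) -> list[int]:
    """Sorted union of element-id lists."""
    out: set[int] = set()
    for ids in id_lists:
        out.update(int(i) for i in ids)
    return sorted(out)


def intersect_ids(first, *rest) -> list[int]:
    """Sorted intersection of element-id lists."""
    out = {int(i) for i in first}
    for ids in rest:
        out &= {int(i) for i in ids}
    return sorted(out)


def difference_ids(base, *removed) -> list[int]:
    """Sorted ids of ``base`` not present in any of ``removed``."""
    out = {int(i) for i in base}
    for ids in removed:
        out -= {int(i) for i in ids}
    return sorted(out)


def point_in_tet(p, tet_coords, tol: float = 1e-12) -> bool:
    """Inclusive point-in-tetrahedron test via barycentric coordinates.

    True iff every barycentric coordinate of ``p`` with respect to the tet
    is ``>= -tol``.  Raises for degenerate (coplanar) tets.
    """
    c = np.asarray(tet_coords, dtype=float)
    m = (c[1:] - c[0]).T
    det = np.linalg.det(m)
    if abs(det) < 1e-30:
        raise MeshError("degenerate tetrahedron in point_in_tet")
    lam = np.linalg.solve(m, np.asarray(p, float) - c[0])
    bary = np.concatenate([[1.0 - lam.sum()], lam])
    return bool((bary >= -tol).all())
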