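"""Tetrahedral mesh data model.

A :class:`Tetmesh` holds vertices, tetrahedra and (optionally labeled)
triangles together with derived geometry — element volumes and areas,
barycenters, and the face-adjacency relation — plus the containers that a
spatial reaction-diffusion simulation is built on: named compartments
(sets of tetrahedra forming a 3D volume), patches (sets of triangles
forming a membrane between one or two compartments) and ROI datasets
(named, ordered element lists reused for injection, recording or
filtering).  All coordinates are metres; volumes m^3; areas m^2.

Internal element indices are contiguous and 0-based.  Indices used by the
source mesh file are kept only inside per-element-class :class:`IndexMap`
objects, so that selections can be translated back to the generator's
numbering when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeshError",
    "IndexMap",
    "Compartment",
    "Patch",
    "ROI",
    "Tetmesh",
    "tet_volume",
    "triangle_area",
    "build_tetmesh",
    "add_roi",
    "get_roi",
    "make_compartment",
    "make_patch",
]

#: relative volume tolerance below which a tet counts as degenerate,
#: scaled by (bounding-box diagonal)^3 so the guard is unit-free
DEGENERACY_REL_TOL = 1e-18


class MeshError(ValueError):
    """Invalid mesh construction, lookup or component definition."""


def tet_volume(c0, c1, c2, c3) -> float:
    """Volume of the tetrahedron spanned by four 3D points.

    Computed as ``|det(c1-c0, c2-c0, c3-c0)| / 6``; returns 0.0 for
    coplanar input (the caller decides whether that is an error).
    """
    c0 = np.asarray(c0, dtype=float)
    m = np.stack([np.asarray(c, dtype=float) - c0 for c in (c1, c2, c3)])
    return abs(float(np.linalg.det(m))) / 6.0


def triangle_area(c0, c1, c2) -> float:
    """Area of the triangle spanned by three 3D points."""
    c0 = np.asarray(c0, dtype=float)
    v1 = np.asarray(c1, dtype=float) - c0
    v2 = np.asarray(c2, dtype=float) - c0
    return 0.5 * float(np.linalg.norm(np.cross(v1, v2)))


class IndexMap:
    """Bijection between source-file element ids and internal contiguous ids.

    One map exists per element class (``"vertex"``, ``"triangle"``,
    ``"tetrahedron"``).  Internal ids are assigned in insertion order and
    are contiguous ``0..n-1``.
    """

    ELEMENT_CLASSES = ("vertex", "triangle", "tetrahedron")

    def __init__(self, element_class: str, source_ids=None):
        if element_class not in self.ELEMENT_CLASSES:
            raise MeshError(f"unknown element class {element_class!r}")
        self.element_class = element_class
        self._to_internal: dict[int, int] = {}
        self._to_source: list[int] = []
        if source_ids is not None:
            for sid in source_ids:
                self.add(int(sid))

    def add(self, source_id: int) -> int:
        """Register a source id, returning the internal id assigned to it."""
        if source_id in self._to_internal:
            raise MeshError(
                f"duplicate source {self.element_class} id {source_id}"
            )
        internal = len(self._to_source)
        self._to_internal[source_id] = internal
        self._to_source.append(source_id)
        return internal

    def to_internal(self, source_id: int) -> int:
        try:
            return self._to_internal[source_id]
        except KeyError:
            raise MeshError(
                f"unknown source {self.element_class} id {source_id}"
            ) from None

    def to_source(self, internal_id: int) -> int:
        if not 0 <= internal_id < len(self._to_source):
            raise MeshError(
                f"unknown internal {self.element_class} id {internal_id}"
            )
        return self._to_source[internal_id]

    def __len__(self) -> int:
        return len(self._to_source)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IndexMap)
            and self.element_class == other.element_class
            and self._to_source == other._to_source
        )

    @property
    def source_ids(self) -> list[int]:
        return list(self._to_source)


@dataclass
class Compartment:
    """A named 3D region: a set of tetrahedra plus attached volume systems."""

    name: str
    tet_indices: np.ndarray  # sorted internal tet ids
    volume: float  # m^3, sum over member tets
    volume_system_ids: list[str] = field(default_factory=list)

    def __contains__(self, tet: int) -> bool:
        i = np.searchsorted(self.tet_indices, tet)
        return i < len(self.tet_indices) and self.tet_indices[i] == tet


@dataclass
class Patch:
    """A named membrane: triangles between an inner and optional outer compartment."""

    name: str
    tri_indices: np.ndarray  # sorted internal tri ids
    inner_compartment: str
    outer_compartment: str | None
    area: float  # m^2, sum over member tris
    surface_system_ids: list[str] = field(default_factory=list)
    # per member triangle (aligned with tri_indices): the tet behind each side
    inner_tets: np.ndarray | None = None
    outer_tets: np.ndarray | None = None  # -1 where the patch has no outer side


@dataclass
class ROI:
    """Named, ordered list of element indices of one element class."""

    name: str
    element_class: str
    indices: list[int]


class Tetmesh:
    """Tetrahedral mesh with derived geometry and simulation containers.

    Construct through :func:`build_tetmesh`, which validates the input,
    normalizes tet orientation and computes every derived field.
    """

    def __init__(self, vertices, tets, tris, index_maps):
        self.vertices: np.ndarray = vertices  # (nv, 3) float64
        self.tets: np.ndarray = tets  # (nt, 4) int64, positive orientation
        self.tris: np.ndarray = tris  # (nr, 3) int64, labeled triangles
        self.index_maps: dict[str, IndexMap] = index_maps
        self.compartments: dict[str, Compartment] = {}
        self.patches: dict[str, Patch] = {}
        self.rois: dict[str, ROI] = {}

        self._compute_derived()

    # -- derived geometry -------------------------------------------------

    #: local face k of a tet is the triple of vertices excluding vertex k
    _FACE_LOCAL = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])

    def _compute_derived(self):
        v, t = self.vertices, self.tets
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
        self.tet_volumes = np.abs(signed)
        self.tet_barycenters = v[t].mean(axis=1)

        # face incidence, vectorized: 4 faces per tet, keyed by the sorted
        # vertex triple; an interior face appears twice, a skin face once
        faces = np.sort(t[:, self._FACE_LOCAL].reshape(-1, 3), axis=1)
        uniq, inv, counts = np.unique(
            faces, axis=0, return_inverse=True, return_counts=True
        )
        if counts.max(initial=0) > 2:
            bad = uniq[int(np.argmax(counts))]
            raise MeshError(
                f"face {tuple(bad)} shared by {counts.max()} tets; "
                "mesh is non-manifold"
            )
        self._unique_faces = uniq  # (nf, 3) sorted vertex triples
        self._face_counts = counts

        order = np.argsort(inv, kind="stable")
        starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
        self.tet_neighbors = np.full((len(t), 4), -1, dtype=np.int64)
        self.face_of_neighbor = np.full((len(t), 4), -1, dtype=np.int64)
        shared = np.flatnonzero(counts == 2)
        fa, fb = order[starts[shared]], order[starts[shared] + 1]
        ta, ka = fa // 4, fa % 4
        tb, kb = fb // 4, fb % 4
        self.tet_neighbors[ta, ka] = tb
        self.tet_neighbors[tb, kb] = ta
        self.face_of_neighbor[ta, ka] = kb
        self.face_of_neighbor[tb, kb] = ka
        self._face_tets_cache: dict | None = None

        self._tri_lookup: dict[tuple[int, int, int], int] = {}
        self._recompute_tri_geometry()
        for ri, tri in enumerate(self.tris):
            self._tri_lookup[tuple(sorted(tri))] = ri

        # per-tet compartment id (-1 unassigned); parallel name list
        self.tet_compartment = np.full(len(t), -1, dtype=np.int64)
        self._compartment_names: list[str] = []

    def _recompute_tri_geometry(self):
        r = self.tris
        if len(r):
            v = self.vertices
            e1 = v[r[:, 1]] - v[r[:, 0]]
            e2 = v[r[:, 2]] - v[r[:, 0]]
            self.tri_areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
            self.tri_barycenters = v[r].mean(axis=1)
        else:
            self.tri_areas = np.zeros(0)
            self.tri_barycenters = np.zeros((0, 3))

    # -- triangles --------------------------------------------------------

    def tri_id(self, verts) -> int | None:
        """Internal id of the labeled triangle with these vertices, or None."""
        return self._tri_lookup.get(tuple(sorted(int(x) for x in verts)))

    def ensure_tris(self, vert_triples) -> list[int]:
        """Return tri ids for the given vertex triples, labeling new ones.

        Triangles not present in the input file are auto-created here when
        a patch or skin query references a tet face (TetGen/Gmsh files
        often omit surface elements).
        """
        ids, new = [], []
        for verts in vert_triples:
            key = tuple(sorted(int(x) for x in verts))
            ri = self._tri_lookup.get(key)
            if ri is None:
                ri = len(self.tris) + len(new)
                self._tri_lookup[key] = ri
                new.append(key)
            ids.append(ri)
        if new:
            self.tris = np.vstack([self.tris, np.asarray(new, dtype=np.int64)])
            self._recompute_tri_geometry()
            imap = self.index_maps["triangle"]
            next_source = max(imap.source_ids, default=-1) + 1
            for k in range(len(new)):
                imap.add(next_source + k)
        return ids

    def tris_of_tet_faces(self, tet: int) -> list[tuple[int, int, int]]:
        """Sorted vertex triples of the four faces of a tet."""
        verts = self.tets[tet]
        return [tuple(sorted(np.delete(verts, k))) for k in range(4)]

    def face_incidence(self):
        """Mapping sorted-vertex-triple -> list of (tet, local face).

        Built lazily from the vectorized face arrays; used by patch
        construction and containment queries on small meshes.
        """
        if self._face_tets_cache is None:
            face_tets: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
            faces = np.sort(
                self.tets[:, self._FACE_LOCAL].reshape(-1, 3), axis=1
            )
            for row in range(len(faces)):
                key = tuple(faces[row].tolist())
                face_tets.setdefault(key, []).append((row // 4, row % 4))
            self._face_tets_cache = face_tets
        return self._face_tets_cache

    def skin_faces(self) -> np.ndarray:
        """Sorted vertex triples of faces incident to exactly one tet."""
        return self._unique_faces[self._face_counts == 1]

    # -- containers -------------------------------------------------------

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes.sum())

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_tris(self) -> int:
        return len(self.tris)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def _check_indices(self, element_class: str, indices) -> list[int]:
        n = {
            "vertex": self.n_vertices,
            "triangle": self.n_tris,
            "tetrahedron": self.n_tets,
        }[element_class]
        out = []
        for i in indices:
            i = int(i)
            if not 0 <= i < n:
                raise MeshError(
                    f"{element_class} index {i} out of range [0, {n})"
                )
            out.append(i)
        return out


def build_tetmesh(vertices, tets, tris=None, index_maps=None) -> Tetmesh:
    """Build a validated :class:`Tetmesh` from raw arrays.

    Parameters
    ----------
    vertices : (nv, 3) array of vertex coordinates in metres.
    tets : (nt, 4) array of vertex indices, 4 distinct per row.
    tris : optional (nr, 3) array of labeled triangle vertex indices.
    index_maps : optional dict of element class -> :class:`IndexMap`
        recording the source file's numbering; identity maps are created
        for classes not supplied.

    Tets are reoriented for positive signed volume.  Degenerate tets
    (volume below ``1e-18`` times the cubed bounding-box diagonal) and
    duplicated tets are rejected.
    """
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    tets = np.ascontiguousarray(tets, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3 or len(vertices) < 4:
        raise MeshError("vertices must be an (n>=4, 3) array")
    if tets.ndim != 2 or tets.shape[1] != 4 or len(tets) == 0:
        raise MeshError("tets must be an (n>=1, 4) array")
    if tets.min() < 0 or tets.max() >= len(vertices):
        bad = tets[(tets < 0) | (tets >= len(vertices))][0]
        raise MeshError(f"tet references out-of-range vertex id {bad}")
    rows = np.sort(tets, axis=1)
    if (rows[:, 1:] == rows[:, :-1]).any():
        i = int(np.argmax((rows[:, 1:] == rows[:, :-1]).any(axis=1)))
        raise MeshError(f"tet {tets[i].tolist()} repeats a vertex")
    if len(np.unique(rows, axis=0)) != len(rows):
        raise MeshError("duplicated tet (same four vertices appear twice)")

    # orientation fix: swap last two vertices where signed volume < 0
    a = vertices[tets[:, 1]] - vertices[tets[:, 0]]
    b = vertices[tets[:, 2]] - vertices[tets[:, 0]]
    c = vertices[tets[:, 3]] - vertices[tets[:, 0]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    flip = signed < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()

    diag = float(np.linalg.norm(vertices.max(axis=0) - vertices.min(axis=0)))
    tol = DEGENERACY_REL_TOL * diag**3
    vols = np.abs(signed)
    if (vols <= tol).any():
        i = int(np.argmax(vols <= tol))
        raise MeshError(
            f"degenerate tet {i} (volume {vols[i]:.3e} m^3 <= tolerance {tol:.3e})"
        )

    if tris is None:
        tris = np.zeros((0, 3), dtype=np.int64)
    else:
        tris = np.ascontiguousarray(tris, dtype=np.int64)
        if len(tris) and (tris.min() < 0 or tris.max() >= len(vertices)):
            raise MeshError("tri references out-of-range vertex id")

    maps = dict(index_maps or {})
    for cls, n in (
        ("vertex", len(vertices)),
        ("triangle", len(tris)),
        ("tetrahedron", len(tets)),
    ):
        if cls not in maps:
            maps[cls] = IndexMap(cls, range(n))
        elif len(maps[cls]) != n:
            raise MeshError(
                f"{cls} index map has {len(maps[cls])} entries, expected {n}"
            )
    return Tetmesh(vertices, tets, tris, maps)


# -- ROI operations -------------------------------------------------------


def add_roi(mesh: Tetmesh, name: str, element_class: str, indices) -> ROI:
    """Store a named element list on the mesh; order is preserved."""
    if element_class not in IndexMap.ELEMENT_CLASSES:
        raise MeshError(f"unknown element class {element_class!r}")
    if name in mesh.rois:
        raise MeshError(f"ROI {name!r} already exists")
    roi = ROI(name, element_class, mesh._check_indices(element_class, indices))
    mesh.rois[name] = roi
    return roi


def get_roi(mesh: Tetmesh, name: str) -> ROI:
    try:
        return mesh.rois[name]
    except KeyError:
        raise MeshError(f"no ROI named {name!r}") from None


# -- compartments and patches ---------------------------------------------


def make_compartment(
    mesh: Tetmesh, name: str, tet_indices, volume_system_ids=()
) -> Compartment:
    """Register a compartment and attach its volume-system ids.

    Tetrahedra may belong to at most one compartment; overlap with an
    existing compartment is an error.
    """
    if name in mesh.compartments:
        raise MeshError(f"compartment {name!r} already exists")
    ids = np.unique(
        np.asarray(mesh._check_indices("tetrahedron", tet_indices), dtype=np.int64)
    )
    if len(ids) == 0:
        raise MeshError(f"compartment {name!r} has no tetrahedra")
    owned = mesh.tet_compartment[ids]
    if (owned >= 0).any():
        clash = mesh._compartment_names[int(owned[owned >= 0][0])]
        raise MeshError(
            f"compartment {name!r} overlaps existing compartment {clash!r}"
        )
    comp = Compartment(
        name=name,
        tet_indices=ids,
        volume=float(mesh.tet_volumes[ids].sum()),
        volume_system_ids=list(volume_system_ids),
    )
    mesh.tet_compartment[ids] = len(mesh._compartment_names)
    mesh._compartment_names.append(name)
    mesh.compartments[name] = comp
    return comp


def make_patch(
    mesh: Tetmesh,
    name: str,
    tri_indices,
    inner: str,
    outer: str | None = None,
    surface_system_ids=(),
) -> Patch:
    """Register a patch between ``inner`` and optionally ``outer``.

    Every member triangle must be the face of exactly one tet of the inner
    compartment; if ``outer`` is given, the tet on the other side must
    belong to it.  Triangles whose two incident tets lie in the same
    compartment are rejected — a membrane must separate distinct regions.
    """
    if name in mesh.patches:
        raise MeshError(f"patch {name!r} already exists")
    if inner not in mesh.compartments:
        raise MeshError(f"unknown inner compartment {inner!r}")
    if outer is not None and outer not in mesh.compartments:
        raise MeshError(f"unknown outer compartment {outer!r}")
    ids = np.asarray(mesh._check_indices("triangle", tri_indices), dtype=np.int64)
    ids = np.unique(ids)
    if len(ids) == 0:
        raise MeshError(f"patch {name!r} has no triangles")

    inner_comp = mesh.compartments[inner]
    inner_tets = np.full(len(ids), -1, dtype=np.int64)
    outer_tets = np.full(len(ids), -1, dtype=np.int64)
    for n_, ri in enumerate(ids):
        key = tuple(sorted(mesh.tris[ri].tolist()))
        incident = mesh.face_incidence().get(key, [])
        in_inner = [ti for ti, _ in incident if ti in inner_comp]
        others = [ti for ti, _ in incident if ti not in inner_comp]
        if len(in_inner) != 1:
            raise MeshError(
                f"patch {name!r}: triangle {ri} has {len(in_inner)} incident "
                f"tets in inner compartment {inner!r}, expected exactly 1"
            )
        inner_tets[n_] = in_inner[0]
        if outer is not None:
            outer_comp = mesh.compartments[outer]
            if len(others) != 1 or others[0] not in outer_comp:
                raise MeshError(
                    f"patch {name!r}: triangle {ri} is not a face of outer "
                    f"compartment {outer!r}"
                )
            outer_tets[n_] = others[0]
        elif others:
            raise MeshError(
                f"patch {name!r}: triangle {ri} has a tet on its outer side "
                "but no outer compartment was given"
            )
    patch = Patch(
        name=name,
        tri_indices=ids,
        inner_compartment=inner,
        outer_compartment=outer,
        area=float(mesh.tri_areas[ids].sum()),
        surface_system_ids=list(surface_system_ids),
        inner_tets=inner_tets,
        outer_tets=outer_tets,
    )
    mesh.patches[name] = patch
    return patch
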