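"""Mesh file input/output.

Readers for three common ASCII tetrahedral-mesh formats — Abaqus ``.inp``
(``*NODE`` / ``*ELEMENT TYPE=C3D4``), TetGen ``.node``/``.ele`` pairs and
Gmsh ``.msh`` version 2.2 — plus a package-defined XML archive that
persists a fully prepared :class:`~tetrasim.mesh_core.Tetmesh` with its
compartments, patches, biochemical-system associations, ROI datasets and
index maps.

Readers return a :class:`RawMesh` that preserves the source file's own
element numbering; :func:`raw_to_tetmesh` converts it into a validated
``Tetmesh`` whose :class:`~tetrasim.mesh_core.IndexMap` objects record
the source-to-internal bijection.

Coordinates in the XML archive are serialized with ``repr`` so floats
round-trip bit-exactly; a second save of a loaded archive reproduces the
first file byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .mesh_core import (
    IndexMap,
    MeshError,
    Tetmesh,
    add_roi,
    build_tetmesh,
    make_compartment,
    make_patch,
)

__all__ = [
    "MeshIOError",
    "RawMesh",
    "read_abaqus",
    "write_abaqus",
    "read_tetgen",
    "read_gmsh",
    "raw_to_tetmesh",
    "save_archive",
    "load_archive",
]


class MeshIOError(MeshError):
    """Malformed or unsupported mesh file."""


@dataclass
class RawMesh:
    """Mesh exactly as read from a source file, with its own numbering."""

    format_name: str
    vertex_ids: list[int]
    vertex_coords: np.ndarray  # (n, 3), aligned with vertex_ids
    tet_ids: list[int]
    tets: list[tuple[int, int, int, int]]  # source vertex ids
    tri_ids: list[int] = field(default_factory=list)
    tris: list[tuple[int, int, int]] = field(default_factory=list)
    tri_labels: list[int] = field(default_factory=list)  # e.g. Gmsh physical tags

    def __post_init__(self):
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float).reshape(-1, 3)
        declared = set(self.vertex_ids)
        for eid, conn in zip(
            self.tet_ids + self.tri_ids, list(self.tets) + list(self.tris)
        ):
            for v in conn:
                if v not in declared:
                    raise MeshIOError(
                        f"element {eid} references undeclared vertex {v}"
                    )

    def __eq__(self, other):
        return (
            isinstance(other, RawMesh)
            and self.vertex_ids == other.vertex_ids
            and np.array_equal(self.vertex_coords, other.vertex_coords)
            and self.tet_ids == other.tet_ids
            and self.tets == other.tets
            and self.tri_ids == other.tri_ids
            and self.tris == other.tris
        )


def raw_to_tetmesh(raw: RawMesh) -> Tetmesh:
    """Build a Tetmesh from a RawMesh, recording source ids in index maps."""
    vmap = IndexMap("vertex", raw.vertex_ids)
    tmap = IndexMap("tetrahedron", raw.tet_ids)
    rmap = IndexMap("triangle", raw.tri_ids)
    tets = [[vmap.to_internal(v) for v in conn] for conn in raw.tets]
    tris = (
        np.asarray([[vmap.to_internal(v) for v in conn] for conn in raw.tris])
        if raw.tris
        else None
    )
    return build_tetmesh(
        raw.vertex_coords,
        tets,
        tris,
        index_maps={"vertex": vmap, "tetrahedron": tmap, "triangle": rmap},
    )


# -- Abaqus ---------------------------------------------------------------

_ABAQUS_TET_TYPES = {"C3D4"}
_ABAQUS_TRI_TYPES = {"S3", "STRI3", "S3R"}


def read_abaqus(path) -> RawMesh:
    """Read an ASCII Abaqus ``.inp`` file (4-node tets, 3-node tris only).

    Keywords are matched case-insensitively; ``**`` comment lines are
    skipped.  Element types other than ``C3D4`` (tet) or ``S3``-family
    (tri) raise an unsupported-type error naming the offending line.
    Continuation lines are not supported.
    """
    vertex_ids: list[int] = []
    coords: list[list[float]] = []
    tet_ids: list[int] = []
    tets: list[tuple] = []
    tri_ids: list[int] = []
    tris: list[tuple] = []
    section = None  # None | "node" | "tet" | "tri" | "skip"

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                keyword = line.split(",")[0].strip().upper()
                if keyword == "*NODE":
                    section = "node"
                elif keyword == "*ELEMENT":
                    opts = {}
                    for part in line.split(",")[1:]:
                        if "=" in part:
                            k, v = part.split("=", 1)
                            opts[k.strip().upper()] = v.strip().upper()
                    etype = opts.get("TYPE", "")
                    if etype in _ABAQUS_TET_TYPES:
                        section = "tet"
                    elif etype in _ABAQUS_TRI_TYPES:
                        section = "tri"
                    else:
                        raise MeshIOError(
                            f"{path}:{lineno}: unsupported Abaqus element "
                            f"type {etype!r} (supported: C3D4 tets, S3 tris)"
                        )
                else:
                    section = "skip"
                continue
            fields = [f.strip() for f in line.split(",") if f.strip()]
            if section == "node":
                if len(fields) != 4:
                    raise MeshIOError(
                        f"{path}:{lineno}: expected 'id, x, y, z' node record"
                    )
                vertex_ids.append(int(fields[0]))
                coords.append([float(x) for x in fields[1:]])
            elif section == "tet":
                if len(fields) != 5:
                    raise MeshIOError(
                        f"{path}:{lineno}: C3D4 element needs 4 vertices "
                        "(continuation lines are not supported)"
                    )
                tet_ids.append(int(fields[0]))
                tets.append(tuple(int(x) for x in fields[1:]))
            elif section == "tri":
                if len(fields) != 4:
                    raise MeshIOError(
                        f"{path}:{lineno}: S3 element needs 3 vertices"
                    )
                tri_ids.append(int(fields[0]))
                tris.append(tuple(int(x) for x in fields[1:]))
            elif section is None:
                raise MeshIOError(
                    f"{path}:{lineno}: data before any *NODE/*ELEMENT section"
                )
    if not vertex_ids:
        raise MeshIOError(f"{path}: no *NODE section found")
    return RawMesh(
        "abaqus", vertex_ids, np.asarray(coords), tet_ids, tets, tri_ids, tris
    )


def write_abaqus(raw: RawMesh, path) -> None:
    """Write a RawMesh as a minimal ASCII Abaqus ``.inp`` file."""
    with open(path, "w") as fh:
        fh.write("*NODE\n")
        for vid, c in zip(raw.vertex_ids, raw.vertex_coords):
            fh.write(
                f"{vid}, {float(c[0])!r}, {float(c[1])!r}, {float(c[2])!r}\n"
            )
        if raw.tet_ids:
            fh.write("*ELEMENT, TYPE=C3D4\n")
            for eid, conn in zip(raw.tet_ids, raw.tets):
                fh.write(f"{eid}, " + ", ".join(str(v) for v in conn) + "\n")
        if raw.tri_ids:
            fh.write("*ELEMENT, TYPE=S3\n")
            for eid, conn in zip(raw.tri_ids, raw.tris):
                fh.write(f"{eid}, " + ", ".join(str(v) for v in conn) + "\n")


# -- TetGen ---------------------------------------------------------------


def _tetgen_records(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def read_tetgen(node_path, ele_path) -> RawMesh:
    """Read a TetGen ``.node``/``.ele`` pair.

    The first-line headers (counts, dimension, attribute and
    boundary-marker flags) are honoured; 0- versus 1-based numbering is
    detected from the first node id.
    """
    records = _tetgen_records(node_path)
    try:
        lineno, header = next(records)
    except StopIteration:
        raise MeshIOError(f"{node_path}: empty file") from None
    n_nodes, dim = int(header[0]), int(header[1])
    if dim != 3:
        raise MeshIOError(f"{node_path}:{lineno}: dimension {dim} != 3")
    vertex_ids, coords = [], []
    for lineno, rec in records:
        if len(rec) < 4:
            raise MeshIOError(f"{node_path}:{lineno}: short node record")
        vertex_ids.append(int(rec[0]))
        coords.append([float(x) for x in rec[1:4]])
    if len(vertex_ids) != n_nodes:
        raise MeshIOError(
            f"{node_path}: header declares {n_nodes} nodes, found "
            f"{len(vertex_ids)}"
        )

    records = _tetgen_records(ele_path)
    try:
        lineno, header = next(records)
    except StopIteration:
        raise MeshIOError(f"{ele_path}: empty file") from None
    n_ele, nodes_per = int(header[0]), int(header[1])
    if nodes_per != 4:
        raise MeshIOError(
            f"{ele_path}:{lineno}: {nodes_per} nodes per tet; only 4 supported"
        )
    tet_ids, tets = [], []
    for lineno, rec in records:
        if len(rec) < 5:
            raise MeshIOError(f"{ele_path}:{lineno}: short element record")
        tet_ids.append(int(rec[0]))
        tets.append(tuple(int(x) for x in rec[1:5]))
    if len(tet_ids) != n_ele:
        raise MeshIOError(
            f"{ele_path}: header declares {n_ele} tets, found {len(tet_ids)}"
        )
    return RawMesh("tetgen", vertex_ids, np.asarray(coords), tet_ids, tets)


# -- Gmsh -----------------------------------------------------------------


def read_gmsh(path) -> RawMesh:
    """Read a Gmsh ``.msh`` MSH 2.2 ASCII file.

    Element type 4 (4-node tet) and type 2 (3-node tri) are imported; the
    first tag of a triangle (its physical group) is kept as a label.
    Binary files and other MSH versions raise an explicit error.
    """
    lines = Path(path).read_text(errors="replace").splitlines()
    i = 0

    def expect(token):
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or lines[i].strip() != token:
            raise MeshIOError(f"{path}: expected {token!r} at line {i + 1}")
        i += 1

    expect("$MeshFormat")
    fmt = lines[i].split()
    i += 1
    if len(fmt) < 3 or fmt[0] not in ("2.2", "2.1", "2.0"):
        raise MeshIOError(
            f"{path}: unsupported MSH version {fmt[0] if fmt else '?'}; "
            "only ASCII MSH 2.x is supported"
        )
    if fmt[1] != "0":
        raise MeshIOError(f"{path}: binary MSH files are not supported")
    expect("$EndMeshFormat")

    expect("$Nodes")
    n_nodes = int(lines[i].strip())
    i += 1
    vertex_ids, coords = [], []
    for _ in range(n_nodes):
        rec = lines[i].split()
        i += 1
        vertex_ids.append(int(rec[0]))
        coords.append([float(x) for x in rec[1:4]])
    expect("$EndNodes")

    expect("$Elements")
    n_ele = int(lines[i].strip())
    i += 1
    tet_ids, tets, tri_ids, tris, tri_labels = [], [], [], [], []
    for _ in range(n_ele):
        rec = [int(x) for x in lines[i].split()]
        i += 1
        eid, etype, ntags = rec[0], rec[1], rec[2]
        tags = rec[3 : 3 + ntags]
        conn = rec[3 + ntags :]
        if etype == 4:
            if len(conn) != 4:
                raise MeshIOError(f"{path}: tet element {eid} has {len(conn)} nodes")
            tet_ids.append(eid)
            tets.append(tuple(conn))
        elif etype == 2:
            tri_ids.append(eid)
            tris.append(tuple(conn))
            tri_labels.append(tags[0] if tags else 0)
        # other element types (points, lines, ...) carry no 3D geometry here
    expect("$EndElements")
    return RawMesh(
        "gmsh", vertex_ids, np.asarray(coords), tet_ids, tets, tri_ids, tris,
        tri_labels,
    )


# -- XML archive ----------------------------------------------------------

ARCHIVE_VERSION = "1"


def _float_text(arr: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(x)) for x in row) for row in arr)


def _int_text(arr) -> str:
    return "\n".join(" ".join(str(int(x)) for x in row) for row in np.atleast_2d(arr))


def _id_list(values) -> str:
    return " ".join(str(int(v)) for v in values)


def save_archive(mesh: Tetmesh, path) -> None:
    """Persist a prepared Tetmesh, with all its components, to XML.

    The document holds vertices (repr-exact decimals), tet/tri
    connectivity, compartments with their volume-system ids, patches with
    surface-system ids, ROI datasets, and the per-class index maps.
    """
    root = ET.Element("tetmesh", version=ARCHIVE_VERSION)
    ET.SubElement(root, "vertices", n=str(mesh.n_vertices)).text = _float_text(
        mesh.vertices
    )
    ET.SubElement(root, "tets", n=str(mesh.n_tets)).text = _int_text(mesh.tets)
    tris_el = ET.SubElement(root, "tris", n=str(mesh.n_tris))
    if mesh.n_tris:
        tris_el.text = _int_text(mesh.tris)

    comps = ET.SubElement(root, "compartments")
    for comp in mesh.compartments.values():
        el = ET.SubElement(
            comps,
            "compartment",
            name=comp.name,
            vsys=",".join(comp.volume_system_ids),
        )
        el.text = _id_list(comp.tet_indices)
    patches = ET.SubElement(root, "patches")
    for patch in mesh.patches.values():
        attrs = dict(
            name=patch.name,
            inner=patch.inner_compartment,
            ssys=",".join(patch.surface_system_ids),
        )
        if patch.outer_compartment is not None:
            attrs["outer"] = patch.outer_compartment
        el = ET.SubElement(patches, "patch", **attrs)
        el.text = _id_list(patch.tri_indices)
    rois = ET.SubElement(root, "rois")
    for roi in mesh.rois.values():
        el = ET.SubElement(rois, "roi", name=roi.name, cls=roi.element_class)
        el.text = _id_list(roi.indices)
    maps = ET.SubElement(root, "indexmaps")
    for cls, imap in sorted(mesh.index_maps.items()):
        el = ET.SubElement(maps, "indexmap", cls=cls)
        el.text = _id_list(imap.source_ids)

    ET.indent(root)
    data = ET.tostring(root, encoding="unicode") + "\n"
    Path(path).write_text(data)


def _require(el, tag):
    child = el.find(tag)
    if child is None:
        raise MeshIOError(f"archive missing <{tag}> under <{el.tag}>")
    return child


def _parse_ints(text, width):
    if text is None or not text.strip():
        return np.zeros((0, width), dtype=np.int64)
    vals = np.array([int(x) for x in text.split()], dtype=np.int64)
    if len(vals) % width:
        raise MeshIOError(f"element count not a multiple of {width}")
    return vals.reshape(-1, width)


def load_archive(path) -> Tetmesh:
    """Load a Tetmesh archive written by :func:`save_archive`."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise MeshIOError(f"{path}: not well-formed XML ({exc})") from None
    if root.tag != "tetmesh":
        raise MeshIOError(f"{path}: root element is <{root.tag}>, not <tetmesh>")
    if root.get("version") != ARCHIVE_VERSION:
        raise MeshIOError(
            f"{path}: unsupported archive version {root.get('version')!r}"
        )

    vtext = _require(root, "vertices").text or ""
    vertices = np.array(
        [[float(x) for x in row.split()] for row in vtext.strip().splitlines()]
    )
    tets = _parse_ints(_require(root, "tets").text, 4)
    tris = _parse_ints(_require(root, "tris").text, 3)

    maps = {}
    for el in _require(root, "indexmaps"):
        cls = el.get("cls")
        ids = [int(x) for x in (el.text or "").split()]
        maps[cls] = IndexMap(cls, ids)
    mesh = build_tetmesh(vertices, tets, tris if len(tris) else None, maps or None)

    def split_ids(attr):
        return [s for s in (attr or "").split(",") if s]

    for el in _require(root, "compartments"):
        make_compartment(
            mesh,
            el.get("name"),
            [int(x) for x in (el.text or "").split()],
            split_ids(el.get("vsys")),
        )
    for el in _require(root, "patches"):
        make_patch(
            mesh,
            el.get("name"),
            [int(x) for x in (el.text or "").split()],
            inner=el.get("inner"),
            outer=el.get("outer"),
            surface_system_ids=split_ids(el.get("ssys")),
        )
    for el in _require(root, "rois"):
        add_roi(
            mesh,
            el.get("name"),
            el.get("cls"),
            [int(x) for x in (el.text or "").split()],
        )
    return mesh
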