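"""Programmatic generation of the tetrahedral geometries used in examples.

Real studies obtain meshes from an external generator; this module
replaces that step with voxel-based tetrahedralization of implicit
solids, which is dependency-free and conforming by construction: the
solid's inside test is evaluated at voxel centers, and each inside voxel
is split into six tetrahedra (Kuhn subdivision), so neighbouring voxels
always share faces exactly.

Provided solids:

* axis-aligned boxes (test fixtures),
* dendritic shafts with simplified spines — a cylinder with randomly
  placed spines, each a spherical head on a cylindrical neck — used for
  the anomalous-diffusion example,
* a nested two-ball geometry (an inner store inside an outer volume with
  the membrane patch between them), the toy analogue of an ER inside a
  spine head.

All dimensions are metres.  Generation is deterministic for a fixed
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .geom_select import Cylinder, select_tets
from .mesh_core import (
    MeshError,
    Tetmesh,
    add_roi,
    build_tetmesh,
    make_compartment,
    make_patch,
)

__all__ = [
    "SpinyDendriteSpec",
    "GeneratedMesh",
    "box_mesh",
    "voxel_mesh",
    "spiny_dendrite_mesh",
    "injection_zone_roi",
    "nested_sphere_mesh",
]

# Kuhn subdivision of the unit cube: one tet per permutation of the axes,
# walking from corner (0,0,0) to (1,1,1); all six share the main diagonal,
# which makes the subdivision conforming across identically split cells.
_KUHN_OFFSETS = []
for _perm in itertools.permutations(range(3)):
    _corner = np.zeros(3, dtype=np.int64)
    _tet = [_corner.copy()]
    for _ax in _perm:
        _corner = _corner.copy()
        _corner[_ax] = 1
        _tet.append(_corner)
    _KUHN_OFFSETS.append(np.stack(_tet))
_KUHN_OFFSETS = np.stack(_KUHN_OFFSETS)  # (6, 4, 3) in {0,1}


def _tets_from_voxel_mask(mask: np.ndarray, origin, spacing) -> Tetmesh:
    """Tetrahedralize the True voxels of a 3D mask into a conforming mesh."""
    nx, ny, nz = mask.shape
    vox = np.argwhere(mask)  # (m, 3) integer voxel coords
    if len(vox) == 0:
        raise MeshError("voxelization produced an empty solid")

    # global grid-vertex id for corner (i, j, k)
    sy, sz = (ny + 1) * (nz + 1), nz + 1

    # corners per tet: voxel coord + Kuhn offset -> grid id
    corner = vox[:, None, None, :] + _KUHN_OFFSETS[None, :, :, :]  # (m,6,4,3)
    gid = corner[..., 0] * sy + corner[..., 1] * sz + corner[..., 2]
    tets_g = gid.reshape(-1, 4)

    used, tets = np.unique(tets_g, return_inverse=True)
    tets = tets.reshape(-1, 4)
    gi, gj, gk = used // sy, (used % sy) // sz, used % sz
    verts = np.stack([gi, gj, gk], axis=1) * np.asarray(spacing, float)
    verts = verts + np.asarray(origin, float)
    return build_tetmesh(verts, tets)


def box_mesh(dims, divisions) -> Tetmesh:
    """Box of size ``dims`` split into ``divisions`` cells per axis,
    six tets per cell."""
    dims = np.asarray(dims, dtype=float)
    divisions = np.asarray(divisions, dtype=int)
    if (dims <= 0).any():
        raise MeshError("box dims must be positive")
    if (divisions < 1).any():
        raise MeshError("divisions must be >= 1 per axis")
    mask = np.ones(tuple(divisions), dtype=bool)
    return _tets_from_voxel_mask(mask, (0.0, 0.0, 0.0), dims / divisions)


def voxel_mesh(inside, lo, hi, voxel_size: float) -> Tetmesh:
    """Voxelize an implicit solid over the box [lo, hi].

    ``inside(points)`` maps an (n, 3) array to booleans; it is evaluated
    at voxel centers.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    axes = [lo[k] + (np.arange(shape[k]) + 0.5) * voxel_size for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    mask = np.asarray(inside(grid.reshape(-1, 3))).reshape(tuple(shape))
    return _tets_from_voxel_mask(mask, lo, (voxel_size,) * 3)


# -- spiny dendrite --------------------------------------------------------


@dataclass(frozen=True)
class SpinyDendriteSpec:
    """Parameters of the simplified spiny-dendrite solid.

    The shaft is a cylinder of length ``shaft_length`` and diameter
    ``shaft_diameter`` along the x axis.  ``round(spine_density *
    shaft_length)`` spines — spherical head on cylindrical neck, radially
    oriented — are attached at axial positions and azimuths drawn from
    the seeded RNG, with rejection of placements whose head centers come
    within two head radii of an accepted spine.

    Spine head/neck dimensions default to values typical of hippocampal
    pyramidal-cell spines (head radius 0.3 um, neck radius 0.1 um, neck
    length 0.5 um); they are package defaults, adjustable per spec.
    ``voxel_size`` defaults to one eighth of the shaft diameter, which
    resolves the default neck with two voxels across.
    """

    shaft_length: float = 20e-6
    shaft_diameter: float = 0.7e-6
    spine_density: float = 0.0  # spines per metre of shaft
    head_radius: float = 0.3e-6
    neck_radius: float = 0.1e-6
    neck_length: float = 0.5e-6
    voxel_size: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.shaft_length <= 0 or self.shaft_diameter <= 0:
            raise MeshError("shaft dimensions must be positive")
        if self.spine_density < 0:
            raise MeshError("spine density must be >= 0")
        if not self.neck_radius < self.head_radius < self.shaft_diameter:
            raise MeshError(
                "expected neck_radius < head_radius < shaft_diameter"
            )
        if self.voxel_size is not None and self.voxel_size <= 0:
            raise MeshError("voxel_size must be positive")

    @property
    def resolved_voxel_size(self) -> float:
        return (
            self.voxel_size
            if self.voxel_size is not None
            else self.shaft_diameter / 8.0
        )

    @property
    def spine_count(self) -> int:
        return int(round(self.spine_density * self.shaft_length))


@dataclass
class GeneratedMesh:
    """A generated mesh plus the metadata tests and analyses rely on."""

    mesh: Tetmesh
    spine_count: int
    spine_anchors: np.ndarray  # (n, 3) anchor points on the shaft surface
    axis_origin: np.ndarray
    axis_direction: np.ndarray  # unit vector
    shaft_length: float
    shaft_radius: float
    spec: SpinyDendriteSpec | None = None
    extras: dict = field(default_factory=dict)


def _place_spines(spec: SpinyDendriteSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Axial positions and azimuths of the spines, by rejection sampling.

    Placement is uniform in axial position (with one head radius of
    clearance at each end) and azimuth; a candidate is rejected when its
    head center lies within two head radii of an accepted head center, so
    heads never overlap.
    """
    n = spec.spine_count
    if n == 0:
        return np.zeros(0), np.zeros(0)
    clearance = spec.head_radius
    if spec.shaft_length <= 2 * clearance:
        raise MeshError("shaft too short for spine head clearance")
    r_head = (
        spec.shaft_diameter / 2.0 + spec.neck_length + spec.head_radius
    )
    axial, azim, centers = [], [], []
    max_tries = 1000 * n
    tries = 0
    while len(axial) < n:
        tries += 1
        if tries > max_tries:
            raise MeshError(
                f"could not place {n} non-overlapping spines after "
                f"{max_tries} attempts; spine density too high"
            )
        a = rng.uniform(clearance, spec.shaft_length - clearance)
        th = rng.uniform(0.0, 2.0 * np.pi)
        c = np.array([a, r_head * np.cos(th), r_head * np.sin(th)])
        if centers:
            d2 = np.sum((np.asarray(centers) - c) ** 2, axis=1)
            if d2.min() < (2 * spec.head_radius) ** 2:
                continue
        axial.append(a)
        azim.append(th)
        centers.append(c)
    return np.asarray(axial), np.asarray(azim)


def spiny_dendrite_mesh(spec: SpinyDendriteSpec) -> GeneratedMesh:
    """Generate a (possibly spiny) dendrite mesh with the "shaft" ROI.

    The solid is the union of the shaft cylinder with every spine neck
    and head; it is voxelized at ``spec.resolved_voxel_size`` and split
    into six tets per inside voxel.  The ROI ``"shaft"`` collects the
    tets whose barycenter lies inside the analytic shaft cylinder, and a
    compartment ``"dendrite"`` covering every tet is registered.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    axial, azim = _place_spines(spec, rng)
    L = spec.shaft_length
    r_shaft = spec.shaft_diameter / 2.0
    h = spec.resolved_voxel_size

    reach = r_shaft + spec.neck_length + 2 * spec.head_radius
    half = reach if spec.spine_count else r_shaft
    # pad by one voxel so boundary voxel centers fall outside cleanly
    lo = np.array([-h, -half - h, -half - h])
    hi = np.array([L + h, half + h, half + h])

    dirs = np.stack(
        [np.zeros_like(azim), np.cos(azim), np.sin(azim)], axis=1
    )
    bases = np.stack(
        [axial, r_shaft * np.cos(azim), r_shaft * np.sin(azim)], axis=1
    )
    heads = bases + (spec.neck_length + spec.head_radius) * dirs

    def inside(points):
        p = np.asarray(points)
        mask = (
            (p[:, 0] >= 0.0)
            & (p[:, 0] <= L)
            & (p[:, 1] ** 2 + p[:, 2] ** 2 <= r_shaft**2)
        )
        for base, d, head in zip(bases, dirs, heads):
            near = np.flatnonzero(
                np.abs(p[:, 0] - base[0]) <= reach
            )  # cheap axial prefilter
            q = p[near]
            rel = q - base
            s = rel @ d
            rad2 = np.sum((rel - np.outer(s, d)) ** 2, axis=1)
            neck = (
                (s >= 0.0)
                & (s <= spec.neck_length)
                & (rad2 <= spec.neck_radius**2)
            )
            headm = np.sum((q - head) ** 2, axis=1) <= spec.head_radius**2
            mask[near] |= neck | headm
        return mask

    mesh = voxel_mesh(inside, lo, hi, h)

    shaft_cyl = Cylinder((0.0, 0.0, 0.0), (L, 0.0, 0.0), r_shaft)
    add_roi(mesh, "shaft", "tetrahedron", select_tets(mesh, shaft_cyl))
    make_compartment(mesh, "dendrite", range(mesh.n_tets))
    return GeneratedMesh(
        mesh=mesh,
        spine_count=spec.spine_count,
        spine_anchors=bases,
        axis_origin=np.zeros(3),
        axis_direction=np.array([1.0, 0.0, 0.0]),
        shaft_length=L,
        shaft_radius=r_shaft,
        spec=spec,
    )


def injection_zone_roi(
    gen: GeneratedMesh, zone_length: float = 0.7e-6, zone_diameter: float = 0.7e-6
):
    """Register the central cylindrical injection zone as ROI "injection_zone".

    The zone is a cylinder centered at the shaft midpoint, aligned with
    the shaft axis; member tets are those whose barycenter falls inside.
    """
    if zone_length > gen.shaft_length or zone_diameter / 2.0 > gen.shaft_radius + 1e-15:
        raise MeshError("injection zone does not fit inside the shaft")
    mid = gen.axis_origin + gen.axis_direction * (gen.shaft_length / 2.0)
    half = gen.axis_direction * (zone_length / 2.0)
    cyl = Cylinder(tuple(mid - half), tuple(mid + half), zone_diameter / 2.0)
    ids = select_tets(gen.mesh, cyl)
    if not ids:
        raise MeshError(
            "injection zone selected no tets; zone smaller than the local "
            "voxel resolution"
        )
    return add_roi(gen.mesh, "injection_zone", "tetrahedron", ids)


# -- nested spheres --------------------------------------------------------


def nested_sphere_mesh(
    outer_radius: float,
    inner_radius: float,
    voxel_size: float,
    inner_name: str = "inner",
    outer_name: str = "outer",
    patch_name: str = "interface",
    inner_vsys=(),
    outer_vsys=(),
    patch_ssys=(),
) -> Tetmesh:
    """Ball-in-ball geometry with two compartments and the membrane patch.

    The outer ball is voxelized; tets are classified by barycenter radius
    into the inner store and the surrounding volume, and the faces with
    one incident tet on each side become the interface patch (triangle
    labels are created on demand).
    """
    if not 0 < inner_radius < outer_radius:
        raise MeshError("expected 0 < inner_radius < outer_radius")
    if inner_radius < 2 * voxel_size:
        raise MeshError(
            "inner_radius below 2 voxels; increase resolution"
        )
    R = outer_radius

    def inside(points):
        p = np.asarray(points)
        return np.sum(p**2, axis=1) <= R**2

    mesh = voxel_mesh(inside, (-R - voxel_size,) * 3, (R + voxel_size,) * 3, voxel_size)

    r_bary = np.linalg.norm(mesh.tet_barycenters, axis=1)
    inner_ids = np.flatnonzero(r_bary <= inner_radius)
    outer_ids = np.flatnonzero(r_bary > inner_radius)
    if len(inner_ids) == 0 or len(outer_ids) == 0:
        raise MeshError("compartment classification produced an empty region")
    make_compartment(mesh, inner_name, inner_ids, inner_vsys)
    make_compartment(mesh, outer_name, outer_ids, outer_vsys)

    # interface faces: one incident tet per class
    is_inner = np.zeros(mesh.n_tets, dtype=bool)
    is_inner[inner_ids] = True
    nbrs = mesh.tet_neighbors
    iface = []
    for ti in inner_ids:
        for k in range(4):
            tj = nbrs[ti, k]
            if tj >= 0 and not is_inner[tj]:
                verts = np.delete(mesh.tets[ti], k)
                iface.append(tuple(sorted(verts.tolist())))
    iface.sort()
    tri_ids = mesh.ensure_tris(iface)
    make_patch(mesh, patch_name, tri_ids, inner=inner_name, outer=outer_name,
               surface_system_ids=patch_ssys)
    return mesh
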