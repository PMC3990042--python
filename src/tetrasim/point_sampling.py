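"""Render-point generation for voxel-based stochastic simulations.

A subvolume solver knows how many molecules each element holds, never
where inside the element they sit.  For display, each dynamic visual
component therefore generates, at every update, exactly one uniformly
distributed random position per molecule inside its element — unless the
component's :class:`RenderPolicy` caps the total (``max_points``) or the
per-element density (``max_density``, points/m^3 for tets, points/m^2
for triangles), in which case element ``e`` emits
``min(count_e, floor(density * measure_e))`` points.  With
``auto_adjust`` the density is rescaled once per update by the ratio of
``max_points`` to the uncapped total before the caps are applied.

Uniform sampling in a simplex uses exact barycentric constructions (no
rejection): sorted uniforms for a tetrahedron, the square-root
construction for a triangle.

Multi-state channel species on membranes are the one exception to
regeneration: each channel copy keeps a permanent position from its
initialization; state transitions relabel it in place, and only a
surface-diffusion hop moves a position (resampled in the destination
triangle).

Components are assembled into displays with a many-to-many association:
a component shared by several displays is generated once per update and
referenced by each (single instance of internal data).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import MeshError
from .ssa_engine import SimState

__all__ = [
    "RenderPolicy",
    "PointCloud",
    "VisualComponent",
    "Display",
    "Scene",
    "sample_in_tet",
    "sample_in_tri",
    "generate_points",
    "channel_positions",
    "write_csv",
    "write_ply",
    "STATIC_KINDS",
    "DYNAMIC_KINDS",
]

STATIC_KINDS = ("compartment_mesh", "patch_mesh")
DYNAMIC_KINDS = (
    "compartment_species",
    "patch_species",
    "tet_species",
    "tri_species",
    "patch_channel",
    "tri_channel",
)


class RenderError(ValueError):
    """Render policy violation or invalid component configuration."""


@dataclass
class RenderPolicy:
    """Point-generation caps for one visual component."""

    max_points: int = 10**9
    max_density: float | None = None  # points/m^3 (tets) or points/m^2 (tris)
    auto_adjust: bool = False

    def __post_init__(self):
        if self.max_points < 1:
            raise RenderError("max_points must be >= 1")
        if self.max_density is not None and self.max_density <= 0:
            raise RenderError("max_density must be positive when set")


@dataclass
class PointCloud:
    """Generated render points for one species of one component."""

    species: str
    positions: np.ndarray  # (n, 3) metres
    elements: np.ndarray  # source element id per point
    t: float  # generation timestamp, s

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class VisualComponent:
    """One independently configurable piece of a visualization.

    ``target`` names a compartment/patch/ROI or is an explicit element-id
    list, depending on ``kind``; ``species`` is a species id for species
    components or a channel-state-set id for channel components.
    ``appearance`` is opaque metadata (color, point size) passed through
    to exporters.
    """

    id: str
    kind: str
    target: object = None
    species: str | None = None
    policy: RenderPolicy = field(default_factory=RenderPolicy)
    appearance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in STATIC_KINDS + DYNAMIC_KINDS:
            raise RenderError(f"unknown component kind {self.kind!r}")
        if self.kind in DYNAMIC_KINDS and self.species is None:
            raise RenderError(
                f"dynamic component {self.id!r} needs a species/state set"
            )
        self._channel_registry = None  # persistent channel copies

    @property
    def is_dynamic(self) -> bool:
        return self.kind in DYNAMIC_KINDS


@dataclass
class Display:
    id: str
    component_ids: list[str] = field(default_factory=list)


# -- simplex samplers ------------------------------------------------------


def sample_in_tet(tet_coords, rng, n: int | None = None) -> np.ndarray:
    """Uniform random point(s) in a tetrahedron.

    Three U(0,1) draws are sorted into ``s1 <= s2 <= s3``; the barycentric
    weights ``(s1, s2-s1, s3-s2, 1-s3)`` are then uniform over the simplex.
    Returns shape (3,) for ``n=None``, else (n, 3).
    """
    c = np.asarray(tet_coords, dtype=float)
    if c.shape != (4, 3):
        raise MeshError("tet_coords must be (4, 3)")
    if abs(np.linalg.det(c[1:] - c[0])) < 1e-300:
        raise MeshError("degenerate tetrahedron")
    m = 1 if n is None else n
    s = np.sort(rng.random((m, 3)), axis=1)
    w = np.column_stack([s[:, 0], s[:, 1] - s[:, 0], s[:, 2] - s[:, 1], 1.0 - s[:, 2]])
    pts = w @ c
    return pts[0] if n is None else pts


def sample_in_tri(tri_coords, rng, n: int | None = None) -> np.ndarray:
    """Uniform random point(s) in a triangle (3D coordinates).

    Uses the square-root construction: with ``u1, u2 ~ U(0,1)``, the
    barycentric weights ``(1-sqrt(u1), u2*sqrt(u1), 1-sum)`` are uniform.
    """
    c = np.asarray(tri_coords, dtype=float)
    if c.shape != (3, 3):
        raise MeshError("tri_coords must be (3, 3)")
    if np.linalg.norm(np.cross(c[1] - c[0], c[2] - c[0])) < 1e-300:
        raise MeshError("degenerate triangle")
    m = 1 if n is None else n
    u = rng.random((m, 2))
    r = np.sqrt(u[:, 0])
    v1 = 1.0 - r
    v2 = u[:, 1] * r
    w = np.column_stack([v1, v2, 1.0 - v1 - v2])
    pts = w @ c
    return pts[0] if n is None else pts


def _sample_many_tets(mesh, elem_ids, per_elem, rng):
    """Vectorized uniform sampling: ``per_elem[i]`` points in tet ``elem_ids[i]``."""
    reps = np.repeat(elem_ids, per_elem)
    if len(reps) == 0:
        return np.zeros((0, 3)), reps
    corners = mesh.vertices[mesh.tets[reps]]  # (n, 4, 3)
    s = np.sort(rng.random((len(reps), 3)), axis=1)
    w = np.column_stack(
        [s[:, 0], s[:, 1] - s[:, 0], s[:, 2] - s[:, 1], 1.0 - s[:, 2]]
    )
    return np.einsum("nk,nkd->nd", w, corners), reps


def _sample_many_tris(mesh, elem_ids, per_elem, rng):
    reps = np.repeat(elem_ids, per_elem)
    if len(reps) == 0:
        return np.zeros((0, 3)), reps
    corners = mesh.vertices[mesh.tris[reps]]  # (n, 3, 3)
    u = rng.random((len(reps), 2))
    r = np.sqrt(u[:, 0])
    w = np.column_stack([1.0 - r, u[:, 1] * r, r * (1.0 - u[:, 1])])
    return np.einsum("nk,nkd->nd", w, corners), reps


# -- component targets -----------------------------------------------------


def _component_elements(component: VisualComponent, state: SimState):
    """Resolve a component's target to ("tet"|"tri", element-id array)."""
    mesh = state.mesh
    kind, tgt = component.kind, component.target
    if kind in ("compartment_mesh", "compartment_species"):
        if tgt not in mesh.compartments:
            raise RenderError(f"unknown compartment {tgt!r}")
        return "tet", mesh.compartments[tgt].tet_indices
    if kind in ("patch_mesh", "patch_species", "patch_channel"):
        if tgt not in mesh.patches:
            raise RenderError(f"unknown patch {tgt!r}")
        return "tri", mesh.patches[tgt].tri_indices
    # tet_species / tri_species / tri_channel: ROI name or explicit id list
    want = "tetrahedron" if kind == "tet_species" else "triangle"
    if isinstance(tgt, str):
        if tgt not in mesh.rois:
            raise RenderError(f"unknown ROI {tgt!r}")
        roi = mesh.rois[tgt]
        if roi.element_class != want:
            raise RenderError(
                f"component {component.id!r} needs a {want} ROI, got "
                f"{roi.element_class}"
            )
        ids = np.asarray(roi.indices)
    else:
        ids = np.asarray(list(tgt), dtype=np.int64)
    return ("tet" if want == "tetrahedron" else "tri"), ids


def _element_counts(state: SimState, kind, elem_ids, species):
    s = state._sidx(species)
    if kind == "tet":
        slots = elem_ids * state.n_species + s
    else:
        slots = state.n_tet_slots + elem_ids * state.n_species + s
    return state.counts[slots]


# -- point generation ------------------------------------------------------


def _capped_counts(counts, measures, policy: RenderPolicy):
    """Apply the max-points / max-density reduction to per-element counts."""
    total = int(counts.sum())
    density = policy.max_density
    if total > policy.max_points:
        if policy.auto_adjust:
            base = density if density is not None else total / measures.sum()
            density = base * (policy.max_points / total)
        elif density is None:
            raise RenderError(
                f"{total} molecules exceed max_points={policy.max_points} "
                "and no density cap or auto-adjust is configured"
            )
    if density is None:
        return counts
    caps = np.floor(density * measures).astype(np.int64)
    return np.minimum(counts, caps)


def generate_points(
    component: VisualComponent, state: SimState, rng
) -> PointCloud:
    """Fresh render points for one dynamic species component.

    Below the caps this emits exactly one point per molecule; otherwise
    per-element counts are reduced per the component's policy (see module
    docstring).
    """
    if not component.is_dynamic:
        raise RenderError(f"component {component.id!r} is static")
    if component.kind in ("patch_channel", "tri_channel"):
        return channel_positions(component, state, rng)
    kind, elem_ids = _component_elements(component, state)
    counts = _element_counts(state, kind, elem_ids, component.species)
    mesh = state.mesh
    measures = (
        mesh.tet_volumes[elem_ids] if kind == "tet" else mesh.tri_areas[elem_ids]
    )
    emit = _capped_counts(counts, measures, component.policy)
    sampler = _sample_many_tets if kind == "tet" else _sample_many_tris
    pts, elems = sampler(mesh, elem_ids, emit, rng)
    return PointCloud(component.species, pts, elems, state.t)


def channel_positions(
    component: VisualComponent, state: SimState, rng
) -> PointCloud:
    """Persistent positions for a multi-state channel component.

    On first call every channel copy (over all member states) receives a
    uniform position in its triangle.  Later calls keep positions fixed
    and only reconcile per-triangle totals: a surface-diffusion hop
    removes one copy from the source triangle and samples one in the
    destination.  State labels are reassigned per triangle to match the
    current per-state counts.  A change in the global channel total
    outside transitions raises a consistency error.
    """
    if component.kind not in ("patch_channel", "tri_channel"):
        raise RenderError(f"component {component.id!r} is not a channel component")
    cs = state.model.channel_state_sets.get(component.species)
    if cs is None:
        raise RenderError(f"unknown channel state set {component.species!r}")
    kind, elem_ids = _component_elements(component, state)
    per_state = {
        sid: _element_counts(state, "tri", elem_ids, sid) for sid in cs.states
    }
    totals = np.sum([per_state[sid] for sid in cs.states], axis=0)

    reg = component._channel_registry
    if reg is None:
        pts, elems = _sample_many_tris(state.mesh, elem_ids, totals, rng)
        reg = {"positions": pts, "elements": elems, "total": int(totals.sum())}
        component._channel_registry = reg
    else:
        if int(totals.sum()) != reg["total"]:
            raise RenderError(
                "channel copy total changed outside state transitions "
                f"({reg['total']} -> {int(totals.sum())})"
            )
        # reconcile per-triangle totals after surface-diffusion hops
        old_per_tri = {int(e): 0 for e in elem_ids}
        for e in reg["elements"]:
            old_per_tri[int(e)] += 1
        keep = np.ones(len(reg["elements"]), dtype=bool)
        new_elems, new_pts = [], []
        for row, e in enumerate(elem_ids):
            e = int(e)
            diff = int(totals[row]) - old_per_tri[e]
            if diff < 0:  # copies left this triangle
                idx = np.flatnonzero((reg["elements"] == e) & keep)[: -diff]
                keep[idx] = False
            elif diff > 0:  # copies arrived: sample in destination
                tri = state.mesh.vertices[state.mesh.tris[e]]
                new_pts.append(np.atleast_2d(sample_in_tri(tri, rng, diff)))
                new_elems.append(np.full(diff, e, dtype=np.int64))
        positions = reg["positions"][keep]
        elements = reg["elements"][keep]
        if new_pts:
            positions = np.vstack([positions, *new_pts])
            elements = np.concatenate([elements, *new_elems])
        reg["positions"], reg["elements"] = positions, elements

    # state labels per triangle, reassigned to match current counts
    labels = np.empty(len(reg["elements"]), dtype=object)
    for row, e in enumerate(elem_ids):
        idx = np.flatnonzero(reg["elements"] == int(e))
        pos = 0
        for sid in cs.states:
            k = int(per_state[sid][row])
            labels[idx[pos : pos + k]] = sid
            pos += k
    reg["labels"] = labels
    return PointCloud(component.species, reg["positions"].copy(),
                      reg["elements"].copy(), state.t)


# -- displays and snapshots ------------------------------------------------


class Scene:
    """Registry of visual components and displays (many-to-many)."""

    def __init__(self):
        self.components: dict[str, VisualComponent] = {}
        self.displays: dict[str, Display] = {}

    def add_component(self, component: VisualComponent) -> VisualComponent:
        if component.id in self.components:
            raise RenderError(f"component {component.id!r} already registered")
        self.components[component.id] = component
        return component

    def assemble_display(self, display_id: str, component_ids) -> Display:
        """Create a display referencing registered components by id."""
        for cid in component_ids:
            if cid not in self.components:
                raise RenderError(f"unknown component id {cid!r}")
        disp = Display(display_id, list(component_ids))
        self.displays[display_id] = disp
        return disp

    def snapshot(self, state: SimState, rng, displays=None):
        """One synchronized update of every referenced component.

        Each dynamic component is generated exactly once even when it
        appears in several displays; the same :class:`PointCloud` object
        is referenced from each.  Static components contribute their
        geometry (element ids) unchanged.

        Returns ``{display_id: {component_id: PointCloud | static dict}}``.
        """
        if displays is None:
            displays = list(self.displays)
        needed = []
        for did in displays:
            if did not in self.displays:
                raise RenderError(f"unknown display {did!r}")
            needed += self.displays[did].component_ids
        cache = {}
        for cid in dict.fromkeys(needed):  # unique, order-preserving
            comp = self.components[cid]
            if comp.is_dynamic:
                cache[cid] = generate_points(comp, state, rng)
            else:
                kind, ids = _component_elements(comp, state)
                cache[cid] = {"kind": comp.kind, "element_class": kind,
                              "elements": ids}
        return {
            did: {cid: cache[cid] for cid in self.displays[did].component_ids}
            for did in displays
        }


# -- exporters -------------------------------------------------------------


def write_csv(clouds, path) -> None:
    """Write point clouds as CSV rows (x, y, z, element, species, t)."""
    if isinstance(clouds, PointCloud):
        clouds = [clouds]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "element", "species", "t"])
        for pc in clouds:
            for p, e in zip(pc.positions, pc.elements):
                w.writerow([repr(float(p[0])), repr(float(p[1])),
                            repr(float(p[2])), int(e), pc.species,
                            repr(float(pc.t))])


def write_ply(cloud: PointCloud, path) -> None:
    """Write one point cloud as an ASCII PLY vertex list."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment species {cloud.species} t {cloud.t!r}\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for p in cloud.positions:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
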