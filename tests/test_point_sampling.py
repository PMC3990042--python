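"""Simplex samplers, render-point policies, channels and displays."""

import numpy as np
import pytest
from scipy import stats

from tetrasim.biomodel import (
    ChannelStateSet,
    SurfaceReaction,
    SurfaceSystem,
    build_model,
)
from tetrasim.geom_select import point_in_tet
from tetrasim.mesh_core import add_roi, make_compartment
from tetrasim.point_sampling import (
    PointCloud,
    RenderError,
    RenderPolicy,
    Scene,
    VisualComponent,
    channel_positions,
    generate_points,
    sample_in_tet,
    sample_in_tri,
    write_csv,
    write_ply,
)
from tetrasim.ssa_engine import build_solver, set_count
from tetrasim.synthetic_geometry import box_mesh, nested_sphere_mesh

from conftest import UNIT_TET_VERTS

ALPHA = 1e-3
N_SAMPLES = 100_000


class TestSampleInTet:
    def test_containment(self, rng):
        pts = sample_in_tet(UNIT_TET_VERTS, rng, 2000)
        for p in pts:
            assert point_in_tet(p, UNIT_TET_VERTS, tol=1e-12)

    def test_mean_is_centroid(self, rng):
        """E[X] is the centroid; per-coordinate CLT bound at 4 sigma."""
        pts = sample_in_tet(UNIT_TET_VERTS, rng, N_SAMPLES)
        # barycentric weights are Dirichlet(1,1,1,1): var of each coord
        sigma = pts.std(axis=0, ddof=1) / np.sqrt(len(pts))
        assert (np.abs(pts.mean(axis=0) - 0.25) < 4 * sigma).all()

    def test_barycentric_marginals_are_beta(self, rng):
        """Each barycentric weight of a uniform sample is Beta(1, 3)."""
        pts = sample_in_tet(UNIT_TET_VERTS, rng, N_SAMPLES)
        w = np.column_stack([1 - pts.sum(axis=1), pts])  # weights on unit tet
        for k in range(4):
            p = stats.kstest(w[:, k], stats.beta(1, 3).cdf).pvalue
            assert p > ALPHA

    def test_subtet_occupancy_chi_square(self, rng):
        """Corner sub-tets of the midpoint subdivision hold 1/8 each."""
        pts = sample_in_tet(UNIT_TET_VERTS, rng, N_SAMPLES)
        w = np.column_stack([1 - pts.sum(axis=1), pts])
        corner = w >= 0.5  # at most one weight can reach 1/2
        cells = np.where(corner.any(axis=1), corner.argmax(axis=1), 4)
        observed = np.bincount(cells, minlength=5)
        expected = N_SAMPLES * np.array([1 / 8] * 4 + [1 / 2])
        p = stats.chisquare(observed, expected).pvalue
        assert p > ALPHA

    def test_degenerate_rejected(self, rng):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]], float)
        with pytest.raises(Exception, match="degenerate"):
            sample_in_tet(flat, rng)


TRI = np.array([[0.0, 0.0, 1.0], [2.0, 0.0, 1.0], [0.0, 1.0, 1.0]])


class TestSampleInTri:
    def test_in_plane_and_inside(self, rng):
        pts = sample_in_tri(TRI, rng, 2000)
        assert np.allclose(pts[:, 2], 1.0, atol=1e-12)
        # barycentric coordinates of the right triangle all non-negative
        assert (pts[:, 0] >= -1e-12).all() and (pts[:, 1] >= -1e-12).all()
        assert (pts[:, 0] / 2.0 + pts[:, 1] <= 1 + 1e-12).all()

    def test_mean_is_centroid(self, rng):
        pts = sample_in_tri(TRI, rng, N_SAMPLES)
        sigma = pts.std(axis=0, ddof=1) / np.sqrt(len(pts))
        centroid = TRI.mean(axis=0)
        assert (np.abs(pts.mean(axis=0) - centroid) <= 4 * sigma + 1e-15).all()

    def test_barycentric_marginals_are_beta(self, rng):
        pts = sample_in_tri(TRI, rng, N_SAMPLES)
        w1 = pts[:, 0] / 2.0  # weight of vertex (2,0)
        w2 = pts[:, 1]  # weight of vertex (0,1)
        w0 = 1 - w1 - w2
        for w in (w0, w1, w2):
            assert stats.kstest(w, stats.beta(1, 2).cdf).pvalue > ALPHA

    def test_subtriangle_chi_square(self, rng):
        """Midpoint subdivision: 3 corner triangles + center, 1/4 each."""
        pts = sample_in_tri(TRI, rng, N_SAMPLES)
        w1 = pts[:, 0] / 2.0
        w2 = pts[:, 1]
        w = np.column_stack([1 - w1 - w2, w1, w2])
        corner = w >= 0.5
        cells = np.where(corner.any(axis=1), corner.argmax(axis=1), 3)
        observed = np.bincount(cells, minlength=4)
        p = stats.chisquare(observed).pvalue
        assert p > ALPHA


@pytest.fixture
def simple_state(diffusion_model):
    mesh = box_mesh((3e-6, 1e-6, 1e-6), (3, 1, 1))
    make_compartment(mesh, "c", range(mesh.n_tets), ["vsys"])
    return build_solver(diffusion_model, mesh, seed=0)


class TestGeneratePoints:
    def test_exact_counts_below_caps(self, simple_state, rng):
        set_count(simple_state, ("tet", 0), "A", 3)
        set_count(simple_state, ("tet", 1), "A", 5)
        comp = VisualComponent("c", "compartment_species", target="c", species="A")
        pc = generate_points(comp, simple_state, rng)
        assert len(pc) == 8
        per = np.bincount(pc.elements, minlength=simple_state.mesh.n_tets)
        assert per[0] == 3 and per[1] == 5 and per[2:].sum() == 0

    def test_zero_molecules_empty_cloud(self, simple_state, rng):
        comp = VisualComponent("c", "compartment_species", target="c", species="A")
        assert len(generate_points(comp, simple_state, rng)) == 0

    def test_points_inside_their_elements(self, simple_state, rng):
        set_count(simple_state, ("tet", 4), "A", 50)
        comp = VisualComponent("c", "compartment_species", target="c", species="A")
        pc = generate_points(comp, simple_state, rng)
        mesh = simple_state.mesh
        for p, e in zip(pc.positions, pc.elements):
            assert point_in_tet(p, mesh.vertices[mesh.tets[e]], tol=1e-12)

    def test_auto_adjust_respects_cap_arithmetic(self, simple_state, rng):
        """Cap oracle: emitted[e] <= min(count[e], floor(adjusted_density * V_e))."""
        set_count(simple_state, ("tet", 0), "A", 10**6)
        n_max = 10**4
        comp = VisualComponent(
            "c", "compartment_species", target="c", species="A",
            policy=RenderPolicy(max_points=n_max, auto_adjust=True),
        )
        pc = generate_points(comp, simple_state, rng)
        assert len(pc) <= n_max
        mesh = simple_state.mesh
        total = 10**6
        vols = mesh.tet_volumes
        base_density = total / vols.sum()
        adjusted = base_density * (n_max / total)
        caps = np.floor(adjusted * vols)
        per = np.bincount(pc.elements, minlength=mesh.n_tets)
        assert (per <= caps + 1e-9).all()

    def test_predefined_density_cap(self, simple_state, rng):
        mesh = simple_state.mesh
        set_count(simple_state, ("tet", 0), "A", 1000)
        density = 10 / float(mesh.tet_volumes[0])  # allow ~10 points in tet 0
        comp = VisualComponent(
            "c", "compartment_species", target="c", species="A",
            policy=RenderPolicy(max_points=10**9, max_density=density),
        )
        pc = generate_points(comp, simple_state, rng)
        per = np.bincount(pc.elements, minlength=mesh.n_tets)
        caps = np.floor(density * mesh.tet_volumes)
        assert (per <= caps).all()

    def test_overflow_without_policy_raises(self, simple_state, rng):
        set_count(simple_state, ("tet", 0), "A", 100)
        comp = VisualComponent(
            "c", "compartment_species", target="c", species="A",
            policy=RenderPolicy(max_points=10, auto_adjust=False),
        )
        with pytest.raises(RenderError, match="max_points"):
            generate_points(comp, simple_state, rng)

    def test_determinism_given_seed_and_state(self, simple_state):
        set_count(simple_state, ("tet", 1), "A", 20)
        comp = VisualComponent("c", "compartment_species", target="c", species="A")
        a = generate_points(comp, simple_state, np.random.default_rng(5))
        b = generate_points(comp, simple_state, np.random.default_rng(5))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.elements, b.elements)


@pytest.fixture
def channel_state():
    """Nested spheres with a two-state channel on the interface patch."""
    mesh = nested_sphere_mesh(1e-6, 0.4e-6, 1e-6 / 8, patch_ssys=["ssys"])
    model = build_model(
        species=["R", "R_open"],
        surface_reactions=[
            SurfaceReaction("open", (("R", "surface"),), (("R_open", "surface"),), 1.0),
            SurfaceReaction("close", (("R_open", "surface"),), (("R", "surface"),), 1.0),
        ],
        channel_state_sets=[ChannelStateSet("chan", ("R", "R_open"), "R")],
        surface_systems=[SurfaceSystem("ssys", reactions=("open", "close"))],
    )
    state = build_solver(model, mesh, seed=3)
    patch = mesh.patches["interface"]
    # 30 channels on the first 10 triangles, 3 each
    for tri in patch.tri_indices[:10]:
        state.counts[state.tri_slot(int(tri), "R")] = 3
    state.refresh_propensities()
    return state


class TestChannelPositions:
    def test_positions_persist_without_diffusion(self, channel_state, rng):
        comp = VisualComponent(
            "ch", "patch_channel", target="interface", species="chan"
        )
        first = channel_positions(comp, channel_state, rng)
        # relabel some channels (a state transition, same triangle totals)
        tri = int(channel_state.mesh.patches["interface"].tri_indices[0])
        channel_state.counts[channel_state.tri_slot(tri, "R")] -= 1
        channel_state.counts[channel_state.tri_slot(tri, "R_open")] += 1
        second = channel_positions(comp, channel_state, rng)
        assert np.array_equal(first.positions, second.positions)
        assert np.array_equal(first.elements, second.elements)

    def test_zero_channels_empty(self, rng):
        mesh = nested_sphere_mesh(1e-6, 0.4e-6, 1e-6 / 8, patch_ssys=["ssys"])
        model = build_model(
            species=["R"],
            surface_reactions=[
                SurfaceReaction("noop", (("R", "surface"),), (("R", "surface"),), 0.0)
            ],
            channel_state_sets=[ChannelStateSet("chan", ("R",), "R")],
            surface_systems=[SurfaceSystem("ssys", reactions=("noop",))],
        )
        state = build_solver(model, mesh, seed=0)
        comp = VisualComponent("ch", "patch_channel", target="interface",
                               species="chan")
        assert len(channel_positions(comp, state, rng)) == 0

    def test_hop_moves_exactly_one_position(self, channel_state, rng):
        comp = VisualComponent(
            "ch", "patch_channel", target="interface", species="chan"
        )
        first = channel_positions(comp, channel_state, rng)
        patch = channel_state.mesh.patches["interface"]
        src = int(patch.tri_indices[0])
        dst = int(patch.tri_indices[20])  # previously empty triangle
        channel_state.counts[channel_state.tri_slot(src, "R")] -= 1
        channel_state.counts[channel_state.tri_slot(dst, "R")] += 1
        second = channel_positions(comp, channel_state, rng)
        assert len(second) == len(first)
        assert (second.elements == dst).sum() == 1
        assert (second.elements == src).sum() == (first.elements == src).sum() - 1
        # exactly one position left (from src) and one appeared (in dst)
        old = {tuple(p) for p in first.positions}
        new = {tuple(p) for p in second.positions}
        assert len(old - new) == 1 and len(new - old) == 1

    def test_total_change_outside_transitions_rejected(self, channel_state, rng):
        comp = VisualComponent(
            "ch", "patch_channel", target="interface", species="chan"
        )
        channel_positions(comp, channel_state, rng)
        tri = int(channel_state.mesh.patches["interface"].tri_indices[0])
        channel_state.counts[channel_state.tri_slot(tri, "R")] += 5
        with pytest.raises(RenderError, match="outside"):
            channel_positions(comp, channel_state, rng)


class TestSceneAndDisplays:
    def test_shared_component_single_instance(self, simple_state, rng):
        set_count(simple_state, ("tet", 0), "A", 4)
        scene = Scene()
        scene.add_component(
            VisualComponent("sp", "compartment_species", target="c", species="A")
        )
        scene.assemble_display("global", ["sp"])
        scene.assemble_display("detail", ["sp"])
        snap = scene.snapshot(simple_state, rng)
        assert snap["global"]["sp"] is snap["detail"]["sp"]

    def test_static_only_display_has_no_point_clouds(self, simple_state, rng):
        scene = Scene()
        scene.add_component(
            VisualComponent("geom", "compartment_mesh", target="c")
        )
        scene.assemble_display("view", ["geom"])
        snap = scene.snapshot(simple_state, rng)
        assert not isinstance(snap["view"]["geom"], PointCloud)
        assert snap["view"]["geom"]["element_class"] == "tet"

    def test_split_views_conserve_species_counts(self, diffusion_model, rng):
        """Four single-ROI displays hold the same points as one global view."""
        mesh = box_mesh((4e-6, 1e-6, 1e-6), (4, 1, 1))
        make_compartment(mesh, "c", range(mesh.n_tets), ["vsys"])
        quarters = np.array_split(np.arange(mesh.n_tets), 4)
        state = build_solver(diffusion_model, mesh, seed=0)
        rng_counts = np.random.default_rng(1)
        for t in range(mesh.n_tets):
            state.counts[t * state.n_species] = rng_counts.integers(0, 6)
        scene = Scene()
        scene.add_component(
            VisualComponent("all", "compartment_species", target="c", species="A")
        )
        for k, ids in enumerate(quarters):
            add_roi(mesh, f"q{k}", "tetrahedron", ids)
            scene.add_component(
                VisualComponent(f"s{k}", "tet_species", target=f"q{k}", species="A")
            )
        scene.assemble_display("allinone", ["all"])
        scene.assemble_display("split", [f"s{k}" for k in range(4)])
        snap = scene.snapshot(state, rng)
        total_split = sum(len(snap["split"][f"s{k}"]) for k in range(4))
        assert total_split == len(snap["allinone"]["all"])

    def test_unknown_component_rejected(self):
        scene = Scene()
        with pytest.raises(RenderError, match="unknown component"):
            scene.assemble_display("d", ["ghost"])


def test_exporters_write_files(simple_state, rng, tmp_path):
    set_count(simple_state, ("tet", 0), "A", 5)
    comp = VisualComponent("c", "compartment_species", target="c", species="A")
    pc = generate_points(comp, simple_state, rng)
    csv_path = tmp_path / "pts.csv"
    ply_path = tmp_path / "pts.ply"
    write_csv(pc, csv_path)
    write_ply(pc, ply_path)
    assert len(csv_path.read_text().splitlines()) == 6  # header + 5 points
    assert ply_path.read_text().startswith("ply")
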