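"""Solver construction, propensity formulas, stepping and queries."""

import numpy as np
import pytest

from tetrasim.biomodel import (
    ModelError,
    Reaction,
    SurfaceReaction,
    SurfaceSystem,
    VolumeSystem,
    build_model,
)
from tetrasim.mesh_core import add_roi, build_tetmesh, make_compartment
from tetrasim.ssa_engine import (
    M3_PER_L,
    N_A,
    SimError,
    build_solver,
    conc,
    count,
    diffusion_propensity,
    inject_into_roi,
    reaction_propensity,
    run_until,
    run_with_checkpoints,
    set_count,
    step,
    sync_run,
)
from tetrasim.synthetic_geometry import box_mesh

from conftest import UNIT_TET_VERTS

FEMTOLITRE_TET = build_tetmesh(UNIT_TET_VERTS * (6e-18) ** (1 / 3), [(0, 1, 2, 3)])
# scaled so the single tet has volume 1e-18 m^3 (1 fL)


def make_single_tet_solver(model, seed=0):
    mesh = build_tetmesh(UNIT_TET_VERTS * (6e-18) ** (1 / 3), [(0, 1, 2, 3)])
    make_compartment(mesh, "cell", [0], ["vsys"])
    return build_solver(model, mesh, seed=seed)


class TestBuildSolver:
    def test_two_tet_diffusion_has_one_channel_per_direction(
        self, two_tet_mesh, diffusion_model
    ):
        make_compartment(two_tet_mesh, "c", [0, 1], ["vsys"])
        state = build_solver(diffusion_model, two_tet_mesh, seed=0)
        assert len(state.chan_rate) == 2
        assert (state.chan_kind == 2).all()

    def test_reaction_only_one_channel_per_tet(self, small_box, decay_model):
        make_compartment(small_box, "c", range(small_box.n_tets), ["vsys"])
        state = build_solver(decay_model, small_box, seed=0)
        assert len(state.chan_rate) == small_box.n_tets

    def test_surface_reaction_one_channel_per_triangle(self, nested_mesh):
        model = build_model(
            species=["Ca", "P"],
            surface_reactions=[
                SurfaceReaction(
                    "pump", (("Ca", "inner_volume"),), (("P", "surface"),), 1.0
                )
            ],
            surface_systems=[SurfaceSystem("ssys", reactions=("pump",))],
        )
        nested_mesh.patches["interface"].surface_system_ids.append("ssys")
        state = build_solver(model, nested_mesh, seed=0)
        assert len(state.chan_rate) == len(
            nested_mesh.patches["interface"].tri_indices
        )

    def test_dangling_system_id_rejected(self, two_tet_mesh, diffusion_model):
        make_compartment(two_tet_mesh, "c", [0, 1], ["vsys", "ghost"])
        with pytest.raises(ModelError, match="ghost"):
            build_solver(diffusion_model, two_tet_mesh, seed=0)

    def test_outer_volume_rule_needs_outer_compartment(self, small_box):
        make_compartment(small_box, "c", range(small_box.n_tets))
        from tetrasim.geom_select import skin_triangles
        from tetrasim.mesh_core import make_patch

        tris = skin_triangles(small_box)
        make_patch(small_box, "skin", tris, inner="c", surface_system_ids=["ssys"])
        model = build_model(
            species=["Ca", "P"],
            surface_reactions=[
                SurfaceReaction(
                    "leak",
                    (("P", "surface"),),
                    (("P", "surface"), ("Ca", "outer_volume")),
                    1.0,
                )
            ],
            surface_systems=[SurfaceSystem("ssys", reactions=("leak",))],
        )
        with pytest.raises(ModelError, match="outer"):
            build_solver(model, small_box, seed=0)


class TestPropensities:
    def test_zero_reactant_count_gives_zero(self):
        rule = Reaction("r", ("A", "B"), (), 1e6)
        assert reaction_propensity(rule, {"A": 0, "B": 50}, 1e-18) == 0.0

    def test_first_order(self):
        rule = Reaction("r", ("A",), (), 2.0)
        assert reaction_propensity(rule, {"A": 5}, 1e-18) == pytest.approx(10.0)

    def test_second_order_unit_conversion_oracle(self):
        """Cross-check M^-1 s^-1 -> per-pair conversion by dimensional analysis.

        k = 1e6 M^-1 s^-1, V = 1 fL: per-pair rate = k / (N_A * V_litres)
        with V_litres = 1e-18 m^3 / 1e-3 = 1e-15 L, so
        c = 1e6 / (6.022e23 * 1e-15) = 1.6605e-3 /s; a = c * 100 * 100.
        """
        rule = Reaction("r", ("A", "B"), (), 1e6)
        got = reaction_propensity(rule, {"A": 100, "B": 100}, 1e-18)
        v_litres = 1e-18 / M3_PER_L
        per_pair = 1e6 / (N_A * v_litres)
        assert got == pytest.approx(per_pair * 100 * 100, rel=1e-12)
        assert got == pytest.approx(16.605, rel=1e-3)

    def test_homo_dimerization_uses_n_times_n_minus_1(self):
        rule = Reaction("r", ("A", "A"), (), 1e6)
        one = reaction_propensity(rule, {"A": 1}, 1e-18)
        two = reaction_propensity(rule, {"A": 2}, 1e-18)
        assert one == 0.0 and two > 0.0

    def test_diffusion_zero_molecules(self, two_tet_mesh):
        assert diffusion_propensity(1e-11, two_tet_mesh, 0, 1, 0) == 0.0

    def test_diffusion_detailed_balance(self, two_tet_mesh):
        d01 = diffusion_propensity(1e-11, two_tet_mesh, 0, 1, 1)
        d10 = diffusion_propensity(1e-11, two_tet_mesh, 1, 0, 1)
        v0, v1 = two_tet_mesh.tet_volumes
        assert d01 * v0 == pytest.approx(d10 * v1, rel=1e-12)

    def test_non_adjacent_pair_rejected(self, small_box):
        far = int(small_box.n_tets - 1)
        with pytest.raises(SimError, match="adjacent"):
            diffusion_propensity(1e-11, small_box, 0, far, 1)


class TestStepping:
    def test_decay_mean_matches_analytic(self, decay_model):
        state = make_single_tet_solver(decay_model)
        finals = []
        for rep in range(200):
            state.reset(seed=rep)
            set_count(state, ("tet", 0), "A", 1000)
            run_until(state, 0.5)
            finals.append(count(state, ("tet", 0), "A"))
        finals = np.asarray(finals, dtype=float)
        expected = 1000 * np.exp(-0.5)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se

    def test_single_step_fires_one_event(self, decay_model):
        state = make_single_tet_solver(decay_model)
        set_count(state, ("tet", 0), "A", 10)
        step(state)
        assert count(state, ("tet", 0), "A") == 9
        assert count(state, ("tet", 0), "B") == 1
        assert state.n_events == 1

    def test_empty_state_runs_to_t_end_immediately(self, decay_model):
        state = make_single_tet_solver(decay_model)
        run_until(state, 1.0)
        assert state.t == 1.0 and state.n_events == 0

    def test_diffusion_conserves_total_at_checkpoints(
        self, bar_with_compartment, diffusion_model
    ):
        state = build_solver(diffusion_model, bar_with_compartment, seed=7)
        set_count(state, "bar", "A", 500)
        totals = []
        run_with_checkpoints(
            state, 5e-3, 1e-3,
            [lambda st, t: totals.append(count(st, "bar", "A"))],
        )
        assert totals == [500] * 6

    def test_checkpoint_count_includes_t_zero(self, decay_model):
        state = make_single_tet_solver(decay_model)
        times = []
        run_with_checkpoints(state, 0.01, 0.002, [lambda st, t: times.append(t)])
        assert times == pytest.approx([0.0, 0.002, 0.004, 0.006, 0.008, 0.01])

    def test_seeded_determinism(self, bar_with_compartment, diffusion_model):
        state = build_solver(diffusion_model, bar_with_compartment, seed=5)
        add_roi(bar_with_compartment, "first", "tetrahedron", [0])
        runs = []
        for _ in range(2):
            state.reset(seed=123)
            inject_into_roi(state, "first", "A", 200)
            run_until(state, 2e-3)
            runs.append((state.n_events, state.counts.copy()))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_incremental_propensities_match_rebuild(
        self, bar_with_compartment, diffusion_model
    ):
        state = build_solver(diffusion_model, bar_with_compartment, seed=11)
        add_roi(bar_with_compartment, "mid", "tetrahedron", [600])
        inject_into_roi(state, "mid", "A", 1000)
        run_until(state, 5e-3)
        exact = state.rebuilt_total_propensity()
        assert abs(state.a0 - exact) <= 1e-9 * exact

    def test_equilibrium_of_reversible_isomerization(self):
        """A <-> B with k+ = 2 k-: detailed balance gives <B>/<A> = 2."""
        model = build_model(
            species=["A", "B"],
            reactions=[
                Reaction("f", ("A",), ("B",), 2.0),
                Reaction("b", ("B",), ("A",), 1.0),
            ],
            volume_systems=[VolumeSystem("vsys", reactions=("f", "b"))],
        )
        state = make_single_tet_solver(model)
        ratios = []
        for rep in range(40):
            state.reset(seed=rep)
            set_count(state, ("tet", 0), "A", 300)
            run_until(state, 10.0)  # >> 1/(k+ + k-)
            ratios.append(count(state, ("tet", 0), "B"))
        mean_b = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean_b - 200.0) < 4 * se + 1


class TestInjectionAndQueries:
    def test_injection_total_and_exclusivity(
        self, bar_with_compartment, diffusion_model
    ):
        state = build_solver(diffusion_model, bar_with_compartment, seed=1)
        add_roi(bar_with_compartment, "zone", "tetrahedron", [10, 11, 12])
        inject_into_roi(state, "zone", "A", 2000)
        assert count(state, "zone", "A") == 2000
        assert count(state, "bar", "A") == 2000

    def test_single_tet_roi_gets_everything(
        self, bar_with_compartment, diffusion_model
    ):
        state = build_solver(diffusion_model, bar_with_compartment, seed=1)
        add_roi(bar_with_compartment, "one", "tetrahedron", [5])
        inject_into_roi(state, "one", "A", 77)
        assert count(state, ("tet", 5), "A") == 77

    def test_injection_proportional_to_volume(self, diffusion_model):
        """Multinomial expectation: mean per-tet count tracks tet volume."""
        mesh = box_mesh((2e-6, 1e-6, 1e-6), (2, 1, 1))
        make_compartment(mesh, "c", range(mesh.n_tets), ["vsys"])
        add_roi(mesh, "all", "tetrahedron", range(mesh.n_tets))
        state = build_solver(diffusion_model, mesh, seed=0)
        n, reps = 240, 500
        sums = np.zeros(mesh.n_tets)
        for rep in range(reps):
            state.reset(seed=rep)
            inject_into_roi(state, "all", "A", n)
            sums += state.counts[: mesh.n_tets]
        p = mesh.tet_volumes / mesh.tet_volumes.sum()
        expected = reps * n * p
        sigma = np.sqrt(reps * n * p * (1 - p))
        assert (np.abs(sums - expected) < 4 * sigma + 1).all()

    def test_empty_roi_rejected(self, bar_with_compartment, diffusion_model):
        state = build_solver(diffusion_model, bar_with_compartment, seed=1)
        add_roi(bar_with_compartment, "none", "tetrahedron", [])
        with pytest.raises(SimError, match="empty"):
            inject_into_roi(state, "none", "A", 5)

    def test_count_empty_state_is_zero(self, bar_with_compartment, diffusion_model):
        state = build_solver(diffusion_model, bar_with_compartment, seed=1)
        assert count(state, "bar", "A") == 0
        assert conc(state, "bar", "A") == 0.0

    def test_conc_unit_oracle(self, diffusion_model):
        """1 molecule in 1.660539e-21 m^3 is 1 uM (1/(N_A * V_litres))."""
        side = (6 * 1.660539e-21) ** (1 / 3)
        mesh = build_tetmesh(UNIT_TET_VERTS * side, [(0, 1, 2, 3)])
        make_compartment(mesh, "c", [0], ["vsys"])
        state = build_solver(diffusion_model, mesh, seed=0)
        set_count(state, ("tet", 0), "A", 1)
        assert conc(state, "c", "A") == pytest.approx(1e-6, rel=1e-5)

    def test_unknown_scope_rejected(self, bar_with_compartment, diffusion_model):
        state = build_solver(diffusion_model, bar_with_compartment, seed=1)
        with pytest.raises(SimError, match="unknown scope"):
            count(state, "nonexistent", "A")


class TestSyncRun:
    def test_aligned_records_across_four_sims(self, diffusion_model):
        sims = []
        for k in range(4):
            mesh = box_mesh((4e-6, 0.4e-6, 0.4e-6), (10, 1, 1))
            make_compartment(mesh, "c", range(mesh.n_tets), ["vsys"])
            add_roi(mesh, "start", "tetrahedron", [0])
            st = build_solver(diffusion_model, mesh, seed=k)
            inject_into_roi(st, "start", "A", 100)
            sims.append(st)
        times, records = sync_run(
            sims, 2e-3, 5e-4, [lambda st: count(st, "c", "A")]
        )
        assert len(records) == 4
        assert all(len(records[i][0]) == len(times) == 5 for i in range(4))
        assert all(records[i][0] == [100] * 5 for i in range(4))
        for st in sims:
            assert st.t == times[-1]

    def test_single_sim_matches_run_with_checkpoints(self, diffusion_model):
        def fresh():
            mesh = box_mesh((4e-6, 0.4e-6, 0.4e-6), (10, 1, 1))
            make_compartment(mesh, "c", range(mesh.n_tets), ["vsys"])
            add_roi(mesh, "start", "tetrahedron", [0])
            st = build_solver(diffusion_model, mesh, seed=9)
            inject_into_roi(st, "start", "A", 100)
            return st

        a, b = fresh(), fresh()
        seen = []
        run_with_checkpoints(
            a, 2e-3, 5e-4, [lambda st, t: seen.append(st.counts.copy())]
        )
        _, records = sync_run([b], 2e-3, 5e-4, [lambda st: st.counts.copy()])
        assert len(seen) == len(records[0][0])
        for x, y in zip(seen, records[0][0]):
            assert np.array_equal(x, y)

    def test_no_sims_rejected(self):
        with pytest.raises(SimError):
            sync_run([], 1.0, 0.1)


class TestIp3rDemo:
    """Receptor-state demo: channels conserved, Ca released store -> cytosol."""

    def test_open_receptors_release_calcium(self):
        from tetrasim.biomodel import IP3R_TRANSITIONS
        from tetrasim.examples import ip3r_demo_simulation

        rates = {t: 0.0 for t in IP3R_TRANSITIONS}
        rates.update(bind_ip3=1e9, open_ca=1e10, ca_release=1e9)
        mesh, state = ip3r_demo_simulation(rates, seed=4)
        patch = mesh.patches["ER_memb"]
        set_count(state, patch, "R", 50)
        set_count(state, mesh.compartments["ER"], "Ca", 2000)
        set_count(state, mesh.compartments["cyt"], "Ca", 200)
        set_count(state, mesh.compartments["cyt"], "IP3", 500)
        channel_states = ("R", "R_IP3", "R_open", "R_Ca1", "R_Ca2", "R_Ca3",
                          "R_Ca4")

        def channel_total():
            return sum(count(state, patch, s) for s in channel_states)

        def ca_total():
            """Free Ca plus Ca sequestered in receptor states (1 per open)."""
            bound = count(state, patch, "R_open") + sum(
                i * count(state, patch, f"R_Ca{i}") for i in range(1, 5)
            )
            return (count(state, mesh.compartments["ER"], "Ca")
                    + count(state, mesh.compartments["cyt"], "Ca") + bound)

        assert channel_total() == 50
        ca0_cyt = count(state, mesh.compartments["cyt"], "Ca")
        run_until(state, 0.005)
        assert channel_total() == 50  # transitions conserve channel copies
        assert ca_total() == 2200  # binding/release only relocates Ca
        assert count(state, patch, "R_open") > 0
        assert count(state, mesh.compartments["cyt"], "Ca") > ca0_cyt
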