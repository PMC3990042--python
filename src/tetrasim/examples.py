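"""The package's two worked examples, as reusable functions.

*Anomalous diffusion in spiny dendrites*: a single diffusible species is
injected into the center of a dendritic shaft (20 um x 0.7 um) and
diffuses along it; spines (spherical head on cylindrical neck) attached
at densities of 0-8 per um transiently trap molecules, slowing the
axial spread of the shaft population as spine density grows.  The
functions here build the meshes, run the synchronized simulations and
measure shaft-restricted axial spreads.

Parameter choices (package study conditions): diffusion coefficient
``D = 1e-11 m^2/s`` (10 um^2/s, a typical small cytosolic signalling
molecule), 2000 injected molecules, measurement horizon 0.4 s — roughly
two spine residence times, long enough for repeated trap-and-release
cycles to differentiate the densities — and the generator's default
voxel size (one eighth of the shaft diameter).

The IP3-receptor demonstration (state topology on an ER membrane patch
inside a nested-sphere geometry) is exposed through
:func:`ip3r_demo_simulation`; its kinetic constants must be supplied by
the caller, as they are model-specific.
"""

from __future__ import annotations

import numpy as np

from .biomodel import DiffusionRule, VolumeSystem, build_model, ip3r_demo_model
from .quantify import axial_distribution, axial_spread
from .ssa_engine import (
    build_solver,
    count,
    inject_into_roi,
    run_until,
    run_with_checkpoints,
)
from .synthetic_geometry import (
    SpinyDendriteSpec,
    injection_zone_roi,
    nested_sphere_mesh,
    spiny_dendrite_mesh,
)

__all__ = [
    "DEFAULT_D",
    "DENDRITE_DENSITIES",
    "N_INJECTED",
    "single_species_model",
    "dendrite_simulation",
    "injection_conservation_run",
    "anomalous_diffusion_spreads",
    "ip3r_demo_simulation",
]

#: diffusion coefficient of the single species, m^2/s
DEFAULT_D = 1e-11

#: spine densities of the four example meshes, spines per metre
DENDRITE_DENSITIES = (0.0, 2e6, 4e6, 8e6)

#: molecules injected into the central zone
N_INJECTED = 2000

X_AXIS = ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))


def single_species_model(D: float = DEFAULT_D):
    """One diffusible species ``X`` in volume system ``vsys``."""
    return build_model(
        species=["X"],
        diffusion_rules=[DiffusionRule("diff_X", "X", D)],
        volume_systems=[VolumeSystem("vsys", diffusion_rules=("diff_X",))],
    )


def dendrite_simulation(density: float, mesh_seed: int, *, D: float = DEFAULT_D,
                        voxel_size: float | None = None):
    """Dendrite mesh (with shaft and injection-zone ROIs) plus its solver."""
    gen = spiny_dendrite_mesh(
        SpinyDendriteSpec(spine_density=density, seed=mesh_seed,
                          voxel_size=voxel_size)
    )
    injection_zone_roi(gen)
    gen.mesh.compartments["dendrite"].volume_system_ids.append("vsys")
    state = build_solver(single_species_model(D), gen.mesh, seed=mesh_seed)
    return gen, state


def injection_conservation_run(seed: int, *, t_end: float = 0.01,
                               dt_update: float = 1e-3):
    """Central injection followed by a diffusion-only run.

    Returns the list of total molecule counts at every checkpoint
    (including t = 0); diffusion must conserve the total exactly.
    """
    gen, state = dendrite_simulation(0.0, mesh_seed=seed)
    state.reset(seed=seed)
    inject_into_roi(state, "injection_zone", "X", N_INJECTED)
    totals: list[int] = []
    run_with_checkpoints(
        state, t_end, dt_update,
        [lambda st, t: totals.append(count(st, "dendrite", "X"))],
    )
    return gen, totals


def anomalous_diffusion_spreads(
    seed: int,
    *,
    densities=DENDRITE_DENSITIES,
    n_replicates: int = 10,
    t_end: float = 0.4,
    bins: int = 50,
    voxel_size: float | None = None,
):
    """Shaft-restricted axial spread per density per replicate.

    One mesh is generated per density (mesh seed derived from ``seed``);
    each replicate reseeds the solver stream, injects 2000 molecules into
    the central zone and runs to ``t_end``.  Returns an array of shape
    (n_replicates, len(densities)) of axial standard deviations in
    metres, plus the per-run shaft molecule counts.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    sims = []
    for density in densities:
        mesh_seed = int(rng.integers(2**31 - 1))
        sims.append(dendrite_simulation(density, mesh_seed,
                                        voxel_size=voxel_size))
    spreads = np.zeros((n_replicates, len(densities)))
    shaft_counts = np.zeros_like(spreads, dtype=np.int64)
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        for j, (gen, state) in enumerate(sims):
            state.reset(seed=rep_seed + j)
            inject_into_roi(state, "injection_zone", "X", N_INJECTED)
            run_until(state, t_end)
            hist = axial_distribution(
                gen.mesh, state, "X", X_AXIS, bins, restriction="shaft",
                bin_range=(0.0, gen.shaft_length),
            )
            spreads[rep, j] = axial_spread(hist)
            shaft_counts[rep, j] = hist.counts.sum()
    return spreads, shaft_counts


def ip3r_demo_simulation(rate_table: dict[str, float], *, seed: int = 0,
                         outer_radius: float = 1e-6,
                         inner_radius: float = 0.4e-6,
                         voxel_size: float = 1e-6 / 8):
    """IP3-receptor demo on a nested-sphere (store-in-cytosol) geometry.

    Builds the two-compartment mesh with the membrane patch, associates
    the receptor model (kinetics from ``rate_table``) and returns the
    solver state; the caller sets initial channel, Ca and IP3 counts.
    """
    mesh = nested_sphere_mesh(
        outer_radius, inner_radius, voxel_size,
        inner_name="ER", outer_name="cyt", patch_name="ER_memb",
        inner_vsys=["er_vsys"], outer_vsys=["cyt_vsys"],
        patch_ssys=["memb_ssys"],
    )
    model = ip3r_demo_model(rate_table)
    return mesh, build_solver(model, mesh, seed=seed)
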