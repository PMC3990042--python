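# tetrasim

Stochastic reaction–diffusion simulation on tetrahedral meshes, with the
geometry-preparation and visualization-side machinery that such
simulations need: mesh import and archiving, element selection,
compartments/patches/ROIs, a spatial Gillespie solver, uniform
render-point generation, and quantitative spatial/temporal outputs.

## Who this is for

Computational neuroscientists and systems biologists who simulate
molecular signalling where the well-mixed assumption fails — e.g. Ca²⁺
release from intracellular stores in a dendritic spine, or diffusion
along spiny dendrites — and who want a self-contained, scriptable
pipeline from geometry to quantitative output.

## The model

Space is discretized into tetrahedral subvolumes, each assumed well
mixed. The state is the vector of molecule counts *n* per (element,
species). Reactions fire with mass-action propensities; for a
bimolecular reaction A+B with rate constant *k* (M⁻¹s⁻¹) in a tet of
volume *V*,

    a = k / (N_A · V_L) · n_A · n_B            (V_L in litres)

Diffusion of a species with coefficient *D* is a first-order hop from
tet *i* to face-neighbour *j*:

    d_ij = D · A_ij / (V_i · h_ij)

with `A_ij` the shared-face area and `h_ij` the distance between the two
barycenters projected onto the face normal (the finite-volume flux
consistent on non-orthogonal meshes; see `docs/methods.md`). Event times
and identities are sampled exactly with Gillespie's direct method;
surface reactions and channel-state transitions live on membrane patch
triangles and couple to the tet behind each side of the triangle.

Because a subvolume solver only tracks counts, visualization positions
are generated fresh at each update: exactly one uniform random point per
molecule inside its element (sorted-uniforms construction in a tet,
square-root construction in a triangle), reduced by per-component
`max_points` / `max_density` caps when populations are large.
Multi-state membrane channels keep permanent positions and change only
their state label.

## Worked example: anomalous diffusion in spiny dendrites

Molecules diffusing along a dendrite are transiently trapped by
dendritic spines, so the axial spread of a population released in the
shaft grows more slowly the denser the spines. The package reproduces
this end to end:

```python
import numpy as np
from tetrasim import examples
from tetrasim.quantify import axial_distribution, axial_spread
from tetrasim.ssa_engine import inject_into_roi, run_until

for density in (0.0, 2e6, 4e6, 8e6):          # spines per metre
    gen, state = examples.dendrite_simulation(density, mesh_seed=7)
    state.reset(seed=42)
    inject_into_roi(state, "injection_zone", "X", 2000)
    run_until(state, 0.4)                      # seconds
    hist = axial_distribution(gen.mesh, state, "X",
                              ((0, 0, 0), (1, 0, 0)), bins=50,
                              restriction="shaft",
                              bin_range=(0, gen.shaft_length))
    print(f"{density * 1e-6:.0f} spines/um: "
          f"shaft spread = {axial_spread(hist) * 1e6:.2f} um, "
          f"molecules in shaft = {hist.counts.sum()}")
```

Output (seed 42):

```
0 spines/um: shaft spread = 2.78 um, molecules in shaft = 1922
2 spines/um: shaft spread = 2.67 um, molecules in shaft = 1253
4 spines/um: shaft spread = 2.42 um, molecules in shaft = 958
8 spines/um: shaft spread = 1.99 um, molecules in shaft = 486
```

Each line is one 0.4 s simulation of 2000 molecules injected into a
0.7 µm × 0.7 µm cylindrical zone at the centre of a 20 µm × 0.7 µm
shaft. The spread is the standard deviation of the axial distribution of
the molecules still inside the shaft cylinder (the `"shaft"` ROI filters
out molecules sitting in spines); both the spread and the shaft
population fall monotonically with spine density — the anomalous
diffusion effect.

The IP₃-receptor demonstration (a 7-state channel on the membrane
between an intracellular Ca²⁺ store and the cytosol, opened by IP₃ then
Ca²⁺ binding, inactivated by direct Ca²⁺ binding) is available through
`tetrasim.examples.ip3r_demo_simulation`; its kinetic constants must be
supplied, see `tetrasim.biomodel.ip3r_demo_model`.

## Command line

```bash
tetrasim genmesh dendrite --density 8e6 --seed 1 --out mesh.xml
tetrasim select --mesh mesh.xml --cylinder 9.65e-6,0,0,10.35e-6,0,0,0.35e-6 \
    --roi-name injection --out mesh.xml
tetrasim run --mesh mesh.xml --model model.toml --seed 7 --t-end 0.1 \
    --dt-update 1e-3 --inject injection:X:2000 --record counts:shaft:X \
    --out run.csv
tetrasim analyze axial --mesh mesh.xml --state state.csv --species X \
    --roi shaft --bins 50 --out dist.csv
```

Meshes can also be imported from Abaqus `.inp`, TetGen `.node`/`.ele`
and Gmsh `.msh` (v2.2 ASCII) files with `tetrasim import`, and are
persisted — with compartments, patches, system associations, ROIs and
index maps — in a byte-stable XML archive.

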