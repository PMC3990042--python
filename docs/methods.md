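# Methods

## Spatial stochastic model

The solver implements Gillespie's direct method on a tetrahedral
discretization of space. Each tetrahedron is a well-mixed subvolume
holding integer molecule counts per species; each triangle of a membrane
patch holds counts of surface-bound species. Event channels are:

* **volume reactions** — one channel per (tet, reaction rule) for every
  rule of every volume system attached to the tet's compartment.
  Molar rate constants are converted to stochastic rates with the
  element volume in litres: order 0, `k·N_A·V_L` events/s; order 1, `k`
  per molecule; order 2, `k/(N_A·V_L)` per reactant pair (`n·(n−1)`
  pairs for identical reactants).
* **diffusion hops** — one channel per ordered face-adjacent tet pair
  within a compartment, rate `d_ij·n_i` with
  `d_ij = D·A_ij/(V_i·h_ij)`.
* **surface reactions** — one channel per (patch triangle, rule).
  Volumetric participants resolve to the tet directly behind the
  triangle on the inner or outer side. For bimolecular rules the volume
  scale is the tet of the first volumetric reactant; a pure
  surface–surface pair uses the inner tet's volume.
* **surface diffusion** — hops between edge-adjacent patch triangles,
  rate `D·l_ij/(A_i·h_ij)` with `l_ij` the shared edge length.

### The diffusion length scale `h_ij`

`h_ij` is the distance between the two barycenters **projected onto the
shared-face normal**, not the plain barycenter distance. On orthogonal
meshes the two coincide; on the Kuhn-subdivision meshes the generator
produces, the connecting line is far from the face normal and the plain
distance underestimates the flux systematically: a deterministic
master-equation solution of the same rate matrix on a long thin bar
gives an effective diffusivity of 0.90·D with the plain distance and
1.000·D with the projected distance. The projected distance is the
standard two-point-flux correction for non-orthogonal meshes, preserves
detailed balance (`d_ij·V_i = d_ji·V_j`, since the projection is
symmetric in i and j), and is isolated in `ssa_engine._hop_rate` so an
alternative discretization can be substituted in one place. Its known
failure mode — near-zero projection for badly sheared element pairs —
does not arise on voxel-derived meshes.

### Event loop

The loop is compiled with numba and operates on flat channel tables.
Channel selection uses a three-level block-sum search (blocks of 64
channels, superblocks of 64 blocks): three short contiguous scans per
event, three adds per refreshed channel. For the common special case of
a single diffusing species with no reactions, channels are aggregated
per tet (propensity `n_tet · R_tet` with `R_tet` the constant sum of
outgoing hop rates) and the face is drawn in a second stage; the
factorized draw is distributionally identical to per-channel selection,
and the per-tet bookkeeping is cross-checked in the tests against a
from-scratch channel-level rebuild.

The running total propensity and the block sums are maintained
incrementally and rebuilt exactly every 2²⁰ events; tests assert the
incremental total stays within 1e-9 (relative) of a full rebuild. If
floating-point drift ever lets a selection scan run past the last
channel, the tables are rebuilt and the draw repeated — valid because
the exponential waiting time is memoryless.

**Checkpoint semantics.** `run_with_checkpoints` fires callbacks at
exact multiples of the update interval, observing the state strictly
before the first event whose time exceeds the checkpoint. On reaching a
checkpoint the pending waiting-time draw is discarded and redrawn
afterwards; by memorylessness this leaves the trajectory distribution
unchanged while keeping multi-simulation records aligned bit-exactly in
time. `sync_run` advances several simulations against one shared
checkpoint schedule.

**Determinism.** Every stochastic component (spine placement, molecule
injection, the event loop, render-point sampling) draws from an
explicitly seeded PCG64 stream; identical seeds give bit-identical
meshes and trajectories.

## Geometry

`build_tetmesh` validates connectivity, normalizes tet orientation to
positive signed volume (simplifying barycentric point tests), rejects
degenerate tets below `1e-18·(bounding-box diagonal)³` — a scale-free
guard — and computes volumes, areas, barycenters and the face-adjacency
relation with vectorized sorting (every interior face must be shared by
exactly 2 tets, every skin face by 1). Compartments own disjoint tet
sets; patches record, per triangle, the tet behind each side, and a
triangle whose two incident tets lie in the same compartment is rejected
— a membrane must separate distinct regions. Triangles referenced by a
patch or skin query but absent from the input file are labeled on
demand, since TetGen/Gmsh exports often omit surface elements.

Element selection tests barycenters (default), all vertices, or any
vertex of each element against a convex primitive (axis-aligned box,
sphere, cylinder) with inclusive containment and a slack of `1e-12`
times the primitive scale, so points exactly on analytic surfaces select
deterministically. The three modes make the otherwise ambiguous notion
of an element "overlapping" a bounding object explicit; for convex
primitives `all_vertices ⊆ barycenter` and `all_vertices ⊆ any_vertex`
(the barycenter mode is not comparable with `any_vertex`: a primitive
smaller than an element can contain the barycenter and no vertex).
`inner_tets` removes every selected tet that touches a skin face through
any vertex, leaving only elements completely covered by others.

## Synthetic geometry

Meshes are produced by voxelizing implicit solids: the solid's inside
test is evaluated at voxel centers and each inside voxel is split into
six tetrahedra along permutations of the axes (Kuhn subdivision), which
is conforming by construction. This replaces an interactive external
mesh generator with reproducible, seedable code; the price is stair-step
boundaries, so generated volumes converge to the analytic solid volume
only as the voxel size shrinks (the smooth-dendrite mesh is within ~4%
of the analytic cylinder volume at the default resolution; tests assert
10%).

The spiny dendrite is a shaft cylinder (20 µm long, 0.7 µm diameter,
along x) with `round(density · length)` spines — a deliberate design
choice over Poisson sampling so the advertised density is exactly
testable. Each spine is a spherical head (radius 0.3 µm) on a
cylindrical neck (radius 0.1 µm, length 0.5 µm) mounted radially;
head/neck dimensions are package defaults typical of hippocampal
pyramidal-cell spines, configurable in `SpinyDendriteSpec`. Axial
positions (one head radius of end clearance) and azimuths are uniform;
a candidate is rejected when its head center comes within two head radii
of an accepted one, so heads never overlap — note the rejection is on
3D head-center distance, not axial distance, since at 8 spines/µm the
mean axial spacing (0.125 µm) is far below the head diameter and an
axial-distance rule could not place the required 160 spines. Necks of
nearby spines may intersect; the union solid voxelizes correctly and
the merged geometry is physically unobjectionable. The default voxel
size is one eighth of the shaft diameter (87.5 nm), the coarsest
resolution that spans the default neck diameter with two voxels.

The `"shaft"` ROI (tets whose barycenter lies inside the analytic shaft
cylinder) and the `"injection_zone"` ROI (0.7 µm × 0.7 µm cylinder at
the shaft midpoint, barycenter selection) are registered on the mesh at
generation time, mirroring the selection-and-store workflow the package
supports for arbitrary geometries.

The nested-sphere geometry (inner ball compartment inside an outer
ball, interface patch between them) classifies tets by barycenter
radius; every interface triangle has exactly one incident tet per
compartment.

## Study conditions of the worked example

The anomalous-diffusion experiment
(`tetrasim.examples.anomalous_diffusion_spreads`) uses: spine densities
0, 2, 4, 8 per µm; 2000 molecules injected into the central zone;
diffusion coefficient `D = 1e-11 m²/s` (10 µm²/s, typical of a small
cytosolic signalling molecule — the choice sets only the time scale of
the dimensionless dynamics); measurement horizon 0.4 s; 50 axial bins
over the shaft; 10 replicates with seeds derived from one base seed;
generator-default voxel size. The horizon is roughly twice the mean
spine residence time (head volume × neck length / (D × neck
cross-section) ≈ 0.2 s), long enough for repeated trap-and-release
cycles — the mechanism of the anomaly — to differentiate the densities;
at much shorter horizons the molecules still in the shaft are mostly
those that were never trapped, and the densities are statistically
indistinguishable.

## Render-point generation

Uniform sampling in a tetrahedron sorts three U(0,1) draws and uses the
gaps as barycentric weights; in a triangle, the square-root construction
is used. Both are exact and constant-cost (no rejection); tests verify
the Beta marginals of the barycentric coordinates (KS, α=0.001) and
equal-volume occupancy of the corner cells of the midpoint subdivision
(χ², α=0.001) at n=10⁵.

The reduction policy: below the caps, exactly one point per molecule.
When the component total exceeds `max_points`, each element is capped at
`floor(density · measure)`; with auto-adjust the density is rescaled
once (single pass, not a fixed point iteration) by
`max_points / uncapped total` before the caps are applied — relative
densities across elements are preserved up to the floor. Per-element
reduction keeps `min(count, cap)` rather than thinning proportionally;
the arithmetic is asserted against an independent cap computation in the
tests.

Channel components are stateful: copies get permanent triangle-uniform
positions at first generation; subsequent updates reconcile only
per-triangle totals (a surface-diffusion hop removes one copy from the
source triangle and samples one in the destination) and reassign state
labels within each triangle to match the current counts. A change in
the global channel total outside transitions raises a consistency
error. Within-triangle label assignment is arbitrary — individual
channel identity is not tracked by a subvolume solver, so any labelling
consistent with the counts is equally valid.

Displays associate many-to-many with components through a `Scene`; a
snapshot generates each dynamic component once per update and lets every
display reference the same point-cloud instance.

## Quantitative outputs

Axial distributions bin molecules by the projection of their element's
barycenter onto an axis — deterministic and independent of the
render-point RNG, at the cost of sub-element position resolution (the
difference from position-based binning is below one voxel size). Bins
are half-open with the last bin closed, so bin counts sum exactly to the
restricted molecule count; merging adjacent bins of a 2k-bin histogram
reproduces the k-bin histogram. Time series are recorded on the shared
checkpoint schedule of `sync_run`. Plotting renders stacked panels to
static files and is never load-bearing in tests.

## Problem sizes and tolerances in the tests

Statistical assertions use α=0.001 (KS, χ²) or 3–4 standard-error
bounds; exact assertions (conservation, round trips, determinism) use
equality. The thin-bar diffusion check uses a 20 µm bar at 0.2 µm
resolution, 10⁴ molecules, t = 0.05 s (σ = 1 µm: five cells wide, ten σ
from the ends, so neither discreteness nor boundaries distort the
comparison against N(x₀, 2Dt)). The ordering experiment runs the four
full-size dendrite meshes for 10 replicates; it is the long pole of the
test suite (~6 minutes) and of the acceptance script.

## Known limitations

* Voxelized boundaries: generated solids carry stair-step surfaces, so
  surface areas do not converge to analytic values (volumes do); none of
  the shipped analyses depend on boundary areas.
* The well-mixed-subvolume assumption degrades if voxels are large
  compared with reaction correlation lengths; the package does not warn
  about this.
* Synthetic geometry only emulates idealized shapes (cylinders, spheres,
  boxes and unions thereof); reconstructed morphologies must be imported
  through the mesh readers, and passing tests on generated meshes says
  nothing about mesh quality of external meshes.
* No membrane-potential coupling; channel kinetics cannot depend on
  voltage.
* Single-threaded by design; the solver targets desk-scale meshes
  (≲ 3·10⁵ tets).
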