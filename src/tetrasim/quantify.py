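"""Quantitative simulation outputs.

Time series of molecule counts or concentrations per scope, and spatial
distributions of molecules projected onto an axis (e.g. along a
dendritic shaft), both synchronized with the solver's checkpoint
schedule.  Molecules are binned by the barycenter of the element that
holds them — deterministic and independent of the render-point RNG — and
an optional restriction (ROI or compartment) filters elements first,
e.g. the "shaft" ROI to exclude molecules trapped in spines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import MeshError
from .ssa_engine import SimState, _scope_elements, sync_run

__all__ = [
    "AxialHistogram",
    "TimeSeries",
    "axial_distribution",
    "axial_spread",
    "record_time_series",
    "plot_outputs",
]


@dataclass
class AxialHistogram:
    """Molecule counts in bins along an axis at one instant.

    Bins are half-open ``[edge_i, edge_i+1)`` except the last, which
    includes its right edge, so the bins partition the full range and the
    bin counts sum to the molecule count of the restriction.
    """

    origin: np.ndarray
    direction: np.ndarray  # unit vector
    bin_edges: np.ndarray  # m, along the axis from origin
    counts: np.ndarray  # per bin
    species: str
    restriction: str | None
    t: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        n = self.counts.sum()
        if n == 0:
            return float("nan")
        return float((self.centers * self.counts).sum() / n)

    def variance(self) -> float:
        n = self.counts.sum()
        if n == 0:
            return float("nan")
        m = self.mean()
        return float(((self.centers - m) ** 2 * self.counts).sum() / n)


@dataclass
class TimeSeries:
    """Aligned checkpoint times and per-(scope, species) value arrays."""

    times: np.ndarray
    values: dict[tuple[str, str], np.ndarray]  # (scope name, species) -> series


def axial_distribution(
    mesh,
    state: SimState,
    species: str,
    axis,
    bins,
    restriction=None,
    bin_range=None,
) -> AxialHistogram:
    """Histogram of molecule positions projected onto an axis.

    ``axis`` is ``(origin, direction)``; every molecule is assigned the
    projection of its element's barycenter.  ``bins`` is a bin count or
    an explicit edge array; the default range spans the projections of
    the restricted elements, so no molecule falls outside.
    """
    origin, direction = (np.asarray(a, dtype=float) for a in axis)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise MeshError("axis direction has zero length")
    direction = direction / norm

    kind, elems = _scope_elements(state, restriction) if restriction is not None \
        else ("tet", np.arange(mesh.n_tets))
    if kind != "tet":
        raise MeshError("axial distributions are over tetrahedral scopes")
    elems = np.asarray(elems)
    s = state._sidx(species)
    weights = state.counts[elems * state.n_species + s]
    proj = (mesh.tet_barycenters[elems] - origin) @ direction

    if np.ndim(bins) == 0:
        nbins = int(bins)
        if nbins < 1:
            raise MeshError("bins must be >= 1")
        if bin_range is None:
            lo, hi = float(proj.min()), float(proj.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
        else:
            lo, hi = bin_range
        edges = np.linspace(lo, hi, nbins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(proj, bins=edges, weights=weights)
    name = restriction if isinstance(restriction, str) else getattr(
        restriction, "name", None
    )
    return AxialHistogram(origin, direction, edges, counts.astype(np.int64),
                          species, name, state.t)


def axial_spread(hist: AxialHistogram) -> float:
    """Standard deviation of the axial distribution (m)."""
    return float(np.sqrt(hist.variance()))


def record_time_series(
    sims, scopes, species, t_end: float, dt_update: float
) -> list[TimeSeries]:
    """Count time series per (scope, species) for each simulation.

    All simulations share one checkpoint schedule (see
    :func:`~tetrasim.ssa_engine.sync_run`), so the returned series are
    aligned by checkpoint index; timestamps are bit-identical across
    simulations.
    """
    from .ssa_engine import count  # local import to avoid cycle at module load

    scopes = list(scopes)
    species = list(species)
    recorders = [
        (lambda st, sc=sc, sp=sp: count(st, sc, sp))
        for sc in scopes
        for sp in species
    ]
    times, records = sync_run(sims, t_end, dt_update, recorders)
    out = []
    for i in range(len(records)):
        values = {}
        j = 0
        for sc in scopes:
            name = sc if isinstance(sc, str) else getattr(sc, "name", str(sc))
            for sp in species:
                values[(name, sp)] = np.asarray(records[i][j])
                j += 1
        out.append(TimeSeries(times=np.asarray(times), values=values))
    return out


def plot_outputs(items, path) -> None:
    """Render histograms and/or time series into one stacked-panel figure.

    One row per item; histograms as bar plots over axial position,
    time series as one line per (scope, species).  Accepts a single item
    or a sequence; raises on an empty record set.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(items, (AxialHistogram, TimeSeries)):
        items = [items]
    items = list(items)
    if not items:
        raise MeshError("nothing to plot")
    fig, axes = plt.subplots(
        len(items), 1, figsize=(7, 2.2 * len(items)), squeeze=False
    )
    for ax, item in zip(axes[:, 0], items):
        if isinstance(item, AxialHistogram):
            ax.bar(item.centers * 1e6, item.counts,
                   width=np.diff(item.bin_edges) * 1e6, align="center")
            ax.set_xlabel("axial position (um)")
            ax.set_ylabel(f"{item.species} count")
            label = item.restriction or "all"
            ax.set_title(f"t = {item.t:.4g} s ({label})", fontsize=9)
        elif isinstance(item, TimeSeries):
            for (scope, sp), vals in item.values.items():
                ax.plot(item.times, vals, label=f"{sp} in {scope}")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("count")
            ax.legend(fontsize=7)
        else:
            raise MeshError(f"cannot plot object of type {type(item).__name__}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
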