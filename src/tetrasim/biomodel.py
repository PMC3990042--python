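"""Biochemical model description.

A :class:`BioModel` declares the chemistry of a simulation separately
from any geometry: molecular species, volume systems (mass-action
reactions and diffusion rules that apply inside a compartment) and
surface systems (reactions and diffusion on a membrane patch, including
the state sets of multi-state channels).  Geometry and chemistry are
joined only by the system *ids* stored on compartments and patches, so
one model can be reused with many meshes and vice versa.

Rate-constant convention (converted to stochastic per-element rates by
the solver): ``kcst`` is molar-based — ``M s^-1`` for order 0, ``s^-1``
for order 1 and ``M^-1 s^-1`` for order 2, where the order is the total
reactant stoichiometry.  Diffusion coefficients are ``m^2 s^-1``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = [
    "ModelError",
    "load_model_config",
    "Species",
    "Reaction",
    "DiffusionRule",
    "SurfaceReaction",
    "SurfaceDiffusionRule",
    "ChannelStateSet",
    "VolumeSystem",
    "SurfaceSystem",
    "BioModel",
    "build_model",
    "ip3r_demo_model",
    "IP3R_TRANSITIONS",
]

LOCATIONS = ("surface", "inner_volume", "outer_volume")


class ModelError(ValueError):
    """Inconsistent biochemical model declaration."""


@dataclass(frozen=True)
class Species:
    id: str


@dataclass(frozen=True)
class Reaction:
    """Mass-action volume reaction, order (total reactant stoichiometry) <= 2."""

    id: str
    reactants: tuple[str, ...]  # species ids, repeated per stoichiometry
    products: tuple[str, ...]
    kcst: float  # M^(1-order) s^-1

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass(frozen=True)
class DiffusionRule:
    id: str
    species: str
    D: float  # m^2 / s


@dataclass(frozen=True)
class SurfaceReaction:
    """Reaction with at least one membrane-bound participant.

    Each participant is a ``(species_id, location)`` pair with location
    one of ``surface``, ``inner_volume`` or ``outer_volume``.
    """

    id: str
    reactants: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    kcst: float

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass(frozen=True)
class SurfaceDiffusionRule:
    id: str
    species: str  # surface species
    D: float  # m^2 / s


@dataclass(frozen=True)
class ChannelStateSet:
    """Species interpreted as the states of one membrane channel.

    Transitions between states are ordinary surface reactions among the
    member species; any such transition conserves the channel count.
    """

    id: str
    states: tuple[str, ...]
    initial_state: str


@dataclass(frozen=True)
class VolumeSystem:
    id: str
    reactions: tuple[str, ...] = ()
    diffusion_rules: tuple[str, ...] = ()


@dataclass(frozen=True)
class SurfaceSystem:
    id: str
    reactions: tuple[str, ...] = ()
    diffusion_rules: tuple[str, ...] = ()


@dataclass(frozen=True)
class BioModel:
    """Validated, immutable biochemical model."""

    species: dict[str, Species]
    reactions: dict[str, Reaction]
    diffusion_rules: dict[str, DiffusionRule]
    surface_reactions: dict[str, SurfaceReaction]
    surface_diffusion_rules: dict[str, SurfaceDiffusionRule]
    channel_state_sets: dict[str, ChannelStateSet]
    volume_systems: dict[str, VolumeSystem]
    surface_systems: dict[str, SurfaceSystem]


def _check_unique(ids, what):
    dup = [k for k, c in Counter(ids).items() if c > 1]
    if dup:
        raise ModelError(f"duplicate {what} id {dup[0]!r}")


def build_model(
    species=(),
    reactions=(),
    diffusion_rules=(),
    surface_reactions=(),
    surface_diffusion_rules=(),
    channel_state_sets=(),
    volume_systems=(),
    surface_systems=(),
) -> BioModel:
    """Validate declarations and return an immutable :class:`BioModel`.

    Checks: unique ids within each category; every rule references
    declared species; reaction order <= 2 with non-negative rate; every
    system member references a declared rule; surface reactions have at
    least one surface participant; channel states are distinct declared
    species including the initial state.
    """
    species = tuple(Species(s) if isinstance(s, str) else s for s in species)
    _check_unique([s.id for s in species], "species")
    known = {s.id for s in species}

    def check_species(sid, where):
        if sid not in known:
            raise ModelError(f"{where} references undeclared species {sid!r}")

    for r in reactions:
        if r.order > 2:
            raise ModelError(f"reaction {r.id!r} has order {r.order} > 2")
        if r.kcst < 0:
            raise ModelError(f"reaction {r.id!r} has negative rate")
        for sid in (*r.reactants, *r.products):
            check_species(sid, f"reaction {r.id!r}")
    _check_unique([r.id for r in reactions], "reaction")

    for d in diffusion_rules:
        if d.D < 0:
            raise ModelError(f"diffusion rule {d.id!r} has negative D")
        check_species(d.species, f"diffusion rule {d.id!r}")
    _check_unique([d.id for d in diffusion_rules], "diffusion rule")

    for sr in surface_reactions:
        if sr.order > 2:
            raise ModelError(f"surface reaction {sr.id!r} has order {sr.order} > 2")
        if sr.kcst < 0:
            raise ModelError(f"surface reaction {sr.id!r} has negative rate")
        participants = (*sr.reactants, *sr.products)
        for sid, loc in participants:
            check_species(sid, f"surface reaction {sr.id!r}")
            if loc not in LOCATIONS:
                raise ModelError(
                    f"surface reaction {sr.id!r}: unknown location {loc!r}"
                )
        if not any(loc == "surface" for _, loc in participants):
            raise ModelError(
                f"surface reaction {sr.id!r} has no surface participant"
            )
    _check_unique([sr.id for sr in surface_reactions], "surface reaction")

    for sd in surface_diffusion_rules:
        if sd.D < 0:
            raise ModelError(f"surface diffusion rule {sd.id!r} has negative D")
        check_species(sd.species, f"surface diffusion rule {sd.id!r}")
    _check_unique(
        [sd.id for sd in surface_diffusion_rules], "surface diffusion rule"
    )

    for cs in channel_state_sets:
        if len(set(cs.states)) != len(cs.states):
            raise ModelError(f"channel set {cs.id!r} repeats a state")
        for sid in cs.states:
            check_species(sid, f"channel set {cs.id!r}")
        if cs.initial_state not in cs.states:
            raise ModelError(
                f"channel set {cs.id!r}: initial state {cs.initial_state!r} "
                "is not a member state"
            )
    _check_unique([cs.id for cs in channel_state_sets], "channel state set")

    rxn_ids = {r.id for r in reactions}
    diff_ids = {d.id for d in diffusion_rules}
    for vs in volume_systems:
        for rid in vs.reactions:
            if rid not in rxn_ids:
                raise ModelError(
                    f"volume system {vs.id!r} references unknown reaction {rid!r}"
                )
        for did in vs.diffusion_rules:
            if did not in diff_ids:
                raise ModelError(
                    f"volume system {vs.id!r} references unknown diffusion "
                    f"rule {did!r}"
                )
    _check_unique([vs.id for vs in volume_systems], "volume system")

    srxn_ids = {sr.id for sr in surface_reactions}
    sdiff_ids = {sd.id for sd in surface_diffusion_rules}
    for ss in surface_systems:
        for rid in ss.reactions:
            if rid not in srxn_ids:
                raise ModelError(
                    f"surface system {ss.id!r} references unknown surface "
                    f"reaction {rid!r}"
                )
        for did in ss.diffusion_rules:
            if did not in sdiff_ids:
                raise ModelError(
                    f"surface system {ss.id!r} references unknown surface "
                    f"diffusion rule {did!r}"
                )
    _check_unique([ss.id for ss in surface_systems], "surface system")

    return BioModel(
        species={s.id: s for s in species},
        reactions={r.id: r for r in reactions},
        diffusion_rules={d.id: d for d in diffusion_rules},
        surface_reactions={sr.id: sr for sr in surface_reactions},
        surface_diffusion_rules={sd.id: sd for sd in surface_diffusion_rules},
        channel_state_sets={cs.id: cs for cs in channel_state_sets},
        volume_systems={vs.id: vs for vs in volume_systems},
        surface_systems={ss.id: ss for ss in surface_systems},
    )


def load_model_config(path) -> BioModel:
    """Build a model from a TOML description.

    Schema (all blocks optional except ``species``)::

        species = ["A", "B"]

        [[reactions]]            # kcst: M^(1-order) s^-1
        id = "r1"
        reactants = ["A"]
        products = ["B"]
        kcst = 1.0

        [[diffusion]]            # D: m^2/s
        id = "d1"
        species = "A"
        D = 1e-11

        [[surface_reactions]]    # participants: [species, location]
        id = "sr1"
        reactants = [["R", "surface"], ["Ca", "outer_volume"]]
        products = [["R_Ca1", "surface"]]
        kcst = 1e6

        [[surface_diffusion]]
        id = "sd1"
        species = "R"
        D = 1e-14

        [[channel_state_sets]]
        id = "IP3R"
        states = ["R", "R_open"]
        initial_state = "R"

        [[volume_systems]]
        id = "vsys"
        reactions = ["r1"]
        diffusion = ["d1"]

        [[surface_systems]]
        id = "ssys"
        reactions = ["sr1"]
        diffusion = ["sd1"]
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        return build_model(
            species=cfg.get("species", ()),
            reactions=[
                Reaction(r["id"], tuple(r.get("reactants", ())),
                         tuple(r.get("products", ())), float(r["kcst"]))
                for r in cfg.get("reactions", ())
            ],
            diffusion_rules=[
                DiffusionRule(d["id"], d["species"], float(d["D"]))
                for d in cfg.get("diffusion", ())
            ],
            surface_reactions=[
                SurfaceReaction(
                    r["id"],
                    tuple((s, loc) for s, loc in r.get("reactants", ())),
                    tuple((s, loc) for s, loc in r.get("products", ())),
                    float(r["kcst"]),
                )
                for r in cfg.get("surface_reactions", ())
            ],
            surface_diffusion_rules=[
                SurfaceDiffusionRule(d["id"], d["species"], float(d["D"]))
                for d in cfg.get("surface_diffusion", ())
            ],
            channel_state_sets=[
                ChannelStateSet(c["id"], tuple(c["states"]), c["initial_state"])
                for c in cfg.get("channel_state_sets", ())
            ],
            volume_systems=[
                VolumeSystem(v["id"], tuple(v.get("reactions", ())),
                             tuple(v.get("diffusion", ())))
                for v in cfg.get("volume_systems", ())
            ],
            surface_systems=[
                SurfaceSystem(s["id"], tuple(s.get("reactions", ())),
                              tuple(s.get("diffusion", ())))
                for s in cfg.get("surface_systems", ())
            ],
        )
    except KeyError as exc:
        raise ModelError(f"model config is missing required key {exc}") from None


#: transition ids that a rate table for :func:`ip3r_demo_model` must supply
IP3R_TRANSITIONS = (
    "bind_ip3", "unbind_ip3",
    "open_ca", "close_ca",
    "inact_ca1", "uninact_ca1",
    "inact_ca2", "uninact_ca2",
    "inact_ca3", "uninact_ca3",
    "inact_ca4", "uninact_ca4",
    "ca_release",
)


def ip3r_demo_model(rate_table: dict[str, float]) -> BioModel:
    """IP3-receptor state-topology model on an ER membrane patch.

    The receptor sits on the membrane between an inner store compartment
    (the ER) and the outer cytosol.  From the native state ``R`` it opens
    by binding cytosolic IP3 first (``R -> R_IP3``) and then Ca
    (``R_IP3 -> R_open``), or is inactivated by binding Ca directly;
    four inactivated states ``R_Ca1..R_Ca4`` track the number of bound
    Ca ions.  Inactivated states do not bind IP3.  Open receptors move Ca
    from the store to the cytosol (``ca_release``, first order in store
    Ca per open channel).

    ``rate_table`` must supply a constant for every id in
    :data:`IP3R_TRANSITIONS`; none default, since the underlying kinetics
    are model-specific.  Binding steps are ``M^-1 s^-1``, unbinding
    ``s^-1``.
    """
    missing = [t for t in IP3R_TRANSITIONS if t not in rate_table]
    if missing:
        raise ModelError(
            f"rate table is missing transition constants: {missing}"
        )
    k = rate_table
    states = ("R", "R_IP3", "R_open", "R_Ca1", "R_Ca2", "R_Ca3", "R_Ca4")
    surf = "surface"
    cyt, er = "outer_volume", "inner_volume"

    def sr(rid, reactants, products):
        return SurfaceReaction(rid, tuple(reactants), tuple(products), k[rid])

    ip3_chain = [
        sr("bind_ip3", [("R", surf), ("IP3", cyt)], [("R_IP3", surf)]),
        sr("unbind_ip3", [("R_IP3", surf)], [("R", surf), ("IP3", cyt)]),
        sr("open_ca", [("R_IP3", surf), ("Ca", cyt)], [("R_open", surf)]),
        sr("close_ca", [("R_open", surf)], [("R_IP3", surf), ("Ca", cyt)]),
    ]
    ca_chain = []
    prev = "R"
    for i in range(1, 5):
        cur = f"R_Ca{i}"
        ca_chain.append(
            sr(f"inact_ca{i}", [(prev, surf), ("Ca", cyt)], [(cur, surf)])
        )
        ca_chain.append(
            sr(f"uninact_ca{i}", [(cur, surf)], [(prev, surf), ("Ca", cyt)])
        )
        prev = cur
    release = sr(
        "ca_release",
        [("R_open", surf), ("Ca", er)],
        [("R_open", surf), ("Ca", cyt)],
    )
    transitions = [*ip3_chain, *ca_chain, release]

    return build_model(
        species=["Ca", "IP3", *states],
        diffusion_rules=[
            DiffusionRule("diff_ca_cyt", "Ca", 2.2e-10),
            DiffusionRule("diff_ip3_cyt", "IP3", 2.8e-10),
            DiffusionRule("diff_ca_er", "Ca", 2.2e-10),
        ],
        surface_reactions=transitions,
        channel_state_sets=[ChannelStateSet("IP3R", states, "R")],
        volume_systems=[
            VolumeSystem("cyt_vsys", diffusion_rules=("diff_ca_cyt", "diff_ip3_cyt")),
            VolumeSystem("er_vsys", diffusion_rules=("diff_ca_er",)),
        ],
        surface_systems=[
            SurfaceSystem("memb_ssys", reactions=tuple(t.id for t in transitions)),
        ],
    )
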