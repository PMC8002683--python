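"""Detailed inference model (DM): reduced reaction schemes with explicit
promoter states.

The DM deliberately ignores mRNA and dimer dynamics present in the
fine-grained generating schemes: for the auto-activation circuit the
protein monomer itself binds the promoter, and production is a single
promoter-state-dependent birth step.  Binding removes one protein from
the free pool (and unbinding returns it), following the mass-action
reading of the binding reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuits import Reaction, ReactionNetwork
from .fsp import Channel, FSPStateSpace, GeneratorMatrix, assemble_generator


def _require_nonneg(**rates) -> None:
    bad = {k: v for k, v in rates.items() if v < 0}
    if bad:
        raise ValueError(f"DM rates must be >= 0, got {bad}")


@dataclass(frozen=True)
class DMParamsSGAA:
    """Rates of the reduced auto-activation scheme: basal/activated
    production g1/g1*, degradation r1, promoter binding f1 (per protein)
    and unbinding b1 (all s^-1)."""

    g1: float
    g1_star: float
    r1: float
    f1: float
    b1: float

    def __post_init__(self) -> None:
        _require_nonneg(g1=self.g1, g1_star=self.g1_star, r1=self.r1,
                        f1=self.f1, b1=self.b1)


@dataclass(frozen=True)
class DMParamsTS:
    """Rates of the reduced toggle scheme (A<->B symmetric): basal
    production g4, repressed production g4*, degradation r4, operator
    binding f4 (per protein) and unbinding b4."""

    g4: float
    g4_star: float
    r4: float
    f4: float
    b4: float

    def __post_init__(self) -> None:
        _require_nonneg(g4=self.g4, g4_star=self.g4_star, r4=self.r4,
                        f4=self.f4, b4=self.b4)


def sgaa_dm_channels(params: DMParamsSGAA) -> list[Channel]:
    """Channels on a (protein count, promoter flag) space; flag 0 is the
    basal state, 1 the activated (protein-bound) state."""
    p = params
    return [
        Channel((+1, 0), lambda N, s: p.g1 * (s == 0) + p.g1_star * (s == 1),
                "production"),
        Channel((-1, 0), lambda N, s: p.r1 * N, "degradation"),
        Channel((-1, +1), lambda N, s: p.f1 * N * (s == 0), "binding"),
        Channel((+1, -1), lambda N, s: p.b1 * (s == 1), "unbinding"),
    ]


def sgaa_dm_generator(params: DMParamsSGAA, space: FSPStateSpace,
                      **kw) -> GeneratorMatrix:
    if len(space.axes) != 2 or space.axes[1][1] != 2:
        raise ValueError(
            "SGAA DM needs one protein axis plus a binary promoter axis"
        )
    return assemble_generator(sgaa_dm_channels(params), space, **kw)


def ts_dm_channels(params: DMParamsTS) -> list[Channel]:
    """Channels on (N_A, N_B, s_A, s_B): s_A=1 means an A protein is
    bound to its operator (repressing B) and symmetrically for s_B.
    A is produced at g4 while s_B=0 and at g4* while s_B=1."""
    p = params
    return [
        Channel((+1, 0, 0, 0),
                lambda NA, NB, sA, sB: p.g4 * (sB == 0) + p.g4_star * (sB == 1),
                "production_A"),
        Channel((0, +1, 0, 0),
                lambda NA, NB, sA, sB: p.g4 * (sA == 0) + p.g4_star * (sA == 1),
                "production_B"),
        Channel((-1, 0, 0, 0), lambda NA, NB, sA, sB: p.r4 * NA, "degradation_A"),
        Channel((0, -1, 0, 0), lambda NA, NB, sA, sB: p.r4 * NB, "degradation_B"),
        Channel((-1, 0, +1, 0), lambda NA, NB, sA, sB: p.f4 * NA * (sA == 0),
                "binding_A"),
        Channel((+1, 0, -1, 0), lambda NA, NB, sA, sB: p.b4 * (sA == 1),
                "unbinding_A"),
        Channel((0, -1, 0, +1), lambda NA, NB, sA, sB: p.f4 * NB * (sB == 0),
                "binding_B"),
        Channel((0, +1, 0, -1), lambda NA, NB, sA, sB: p.b4 * (sB == 1),
                "unbinding_B"),
    ]


def ts_dm_generator(params: DMParamsTS, space: FSPStateSpace,
                    **kw) -> GeneratorMatrix:
    if len(space.axes) != 4 or space.axes[2][1] != 2 or space.axes[3][1] != 2:
        raise ValueError(
            "TS DM needs two protein axes plus two binary occupancy axes"
        )
    return assemble_generator(ts_dm_channels(params), space, **kw)


def dm_effective_rates(params: DMParamsSGAA | DMParamsTS) -> dict[str, float]:
    """Effective rates are the DM's own production/degradation rates."""
    if isinstance(params, DMParamsSGAA):
        return {"peff": params.g1, "peff_star": params.g1_star,
                "reff": params.r1}
    return {"peff": params.g4, "peff_star": params.g4_star, "reff": params.r4}


def sgaa_dm_network(params: DMParamsSGAA) -> ReactionNetwork:
    """The reduced SGAA scheme as a simulatable reaction network (used to
    generate data from the DM's own model, e.g. for recovery checks)."""
    p = params
    species = ["A", "P_basal", "P_active"]
    rxns = [
        Reaction("production_basal", {"P_basal": 1}, {"P_basal": 1, "A": 1}, p.g1),
        Reaction("production_active", {"P_active": 1}, {"P_active": 1, "A": 1}, p.g1_star),
        Reaction("degradation", {"A": 1}, {}, p.r1),
        Reaction("binding", {"P_basal": 1, "A": 1}, {"P_active": 1}, p.f1),
        Reaction("unbinding", {"P_active": 1}, {"P_basal": 1, "A": 1}, p.b1),
    ]
    return ReactionNetwork(
        species=species, reactions=rxns,
        initial_state={"A": 0, "P_basal": 1, "P_active": 0},
        promoter_groups=[("P_basal", "P_active")],
        observed=["A"],
    )
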