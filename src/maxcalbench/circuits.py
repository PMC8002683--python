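"""Reaction networks for the two benchmark gene circuits.

Two fine-grained generating schemes are defined here:

* SGAA — a single gene whose protein product dimerizes and, as a dimer,
  binds the promoter and switches it to a state with a much higher
  transcription rate (positive auto-activation).  The circuit produces
  noisy, switch-like trajectories that dwell for hours in a low- and a
  high-expression state.
* TS — a two-gene toggle switch: either protein monomer can bind the
  shared promoter region and throttle transcription of the *other* gene
  (mutual repression), yielding bistable anticorrelated expression.

Both schemes include mRNA and (for SGAA) dimer species; only the tagged
proteins are ever recorded in trajectories, mimicking a fluorescence
readout.  Reduced schemes used for inference live in :mod:`.dm` and
:mod:`.cgm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum


class PropensityRule(str, Enum):
    MASS_ACTION = "mass_action"
    HILL_ACTIVATION = "hill_activation"
    HILL_REPRESSION = "hill_repression"
    CUSTOM = "custom"


# Default rate constants of the SGAA generating scheme (all s^-1 or
# s^-1 per pair for the bimolecular steps).
SGAA_RATES = {
    "g": 0.05,       # basal transcription
    "g_star": 0.5,   # activated transcription
    "d": 0.2,        # mRNA degradation
    "p": 0.02,       # translation (per mRNA)
    "r": 1.0e-3,     # protein degradation (per monomer)
    "fd": 5.0e-3,    # dimerization (per monomer pair)
    "bd": 50.0,      # dimer dissociation
    "fp": 6.0e-3,    # dimer-promoter binding
    "bp": 3.0e-5,    # dimer-promoter unbinding
}

# Default rate constants of the TS generating scheme.
TS_RATES = {
    "g3": 0.5,         # basal transcription (either gene)
    "g3_star": 2.5e-3, # repressed transcription
    "d3": 0.5,         # mRNA degradation
    "p3": 0.02,        # translation
    "r3": 1.0e-3,      # protein degradation
    "f3": 3.5e-6,      # monomer-promoter binding (per monomer)
    "b3": 2.0e-5,      # monomer-promoter unbinding
}


class ParameterDomainError(ValueError):
    """A rate constant lies outside its admissible domain."""


@dataclass
class Reaction:
    """A single reaction channel.

    ``rate_constant`` carries units depending on the reaction order
    (s^-1 for zeroth/first order, s^-1 per pair for second order).  For
    ``mass_action`` the propensity is the standard SSA combinatorial form
    k * prod_s C(x_s, nu_s); a reaction with two identical reactants may
    opt out of the 1/2 symmetry factor via ``combinatorial=False``.
    Hill rules read a single species ``hill_species`` and evaluate
    k * x^n/(x^n + K) (activation) or k / (x^n + K) (repression).
    """

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float
    rule: PropensityRule = PropensityRule.MASS_ACTION
    combinatorial: bool = True
    hill_species: str | None = None
    hill_n: int = 2
    hill_K: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ParameterDomainError(
                f"reaction {self.name!r}: rate constant must be >= 0, "
                f"got {self.rate_constant}"
            )
        for stoich in (self.reactants, self.products):
            for sp, cnt in stoich.items():
                if not (isinstance(cnt, int) and cnt >= 0):
                    raise ParameterDomainError(
                        f"reaction {self.name!r}: stoichiometry of {sp!r} "
                        f"must be a non-negative integer, got {cnt!r}"
                    )

    def propensity(self, state: dict[str, int]) -> float:
        """Evaluate the propensity at a species-count state (for checks;
        the simulator uses a compiled equivalent)."""
        if self.rule is PropensityRule.MASS_ACTION:
            a = self.rate_constant
            for sp, nu in self.reactants.items():
                x = state[sp]
                if x < nu:
                    return 0.0
                for c in range(nu):
                    a *= x - c
                if self.combinatorial:
                    for c in range(2, nu + 1):
                        a /= c
            return a
        x = float(state[self.hill_species])
        xn = x ** self.hill_n
        if self.rule is PropensityRule.HILL_ACTIVATION:
            a = self.rate_constant * xn / (xn + self.hill_K)
        elif self.rule is PropensityRule.HILL_REPRESSION:
            a = self.rate_constant / (xn + self.hill_K)
        else:
            raise NotImplementedError(self.rule)
        # gate on reactant availability (promoter indicator etc.)
        for sp, nu in self.reactants.items():
            if state[sp] < nu:
                return 0.0
        return a


@dataclass
class ReactionNetwork:
    """Species list, reaction channels and initial state.

    ``promoter_groups`` lists tuples of indicator species that are
    mutually exclusive (exactly one is 1 at any time per gene copy).
    ``observed`` names the tagged proteins recorded in trajectories.
    """

    species: list[str]
    reactions: list[Reaction]
    initial_state: dict[str, int] = field(default_factory=dict)
    promoter_groups: list[tuple[str, ...]] = field(default_factory=list)
    observed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.species)
        for rxn in self.reactions:
            for sp in (*rxn.reactants, *rxn.products):
                if sp not in known:
                    raise ValueError(
                        f"reaction {rxn.name!r} references unknown species {sp!r}"
                    )
            if rxn.hill_species is not None and rxn.hill_species not in known:
                raise ValueError(
                    f"reaction {rxn.name!r} reads unknown species "
                    f"{rxn.hill_species!r}"
                )
        for group in self.promoter_groups:
            total = sum(self.initial_state.get(sp, 0) for sp in group)
            if total != 1:
                raise ValueError(
                    f"promoter group {group} must have exactly one active "
                    f"indicator in the initial state (found {total})"
                )

    def index(self, name: str) -> int:
        return self.species.index(name)


def _check_rates(params: dict[str, float], required: tuple[str, ...]) -> None:
    missing = [k for k in required if k not in params]
    if missing:
        raise ParameterDomainError(f"missing rate constants: {missing}")
    bad = {k: params[k] for k in required if params[k] < 0}
    if bad:
        raise ParameterDomainError(f"negative rate constants: {bad}")


def build_sgaa_generator(
    params: dict[str, float] | None = None,
    *,
    dimer_half_factor: bool = True,
) -> ReactionNetwork:
    """Build the fine-grained SGAA generating scheme.

    Species: mRNA ``a``, monomer ``A``, free dimer ``A2`` and the two
    promoter indicators ``P_basal``/``P_active``.  The promoter-bound
    dimer is sequestered: binding consumes one free A2 and unbinding
    restores it; bound dimers never dissociate to monomers.

    ``dimer_half_factor`` selects the dimerization propensity
    convention: the default SSA combinatorial form fd*N*(N-1)/2, or
    fd*N*(N-1) when False.
    """
    p = dict(SGAA_RATES)
    if params:
        p.update(params)
    _check_rates(p, tuple(SGAA_RATES))
    if p["g_star"] < p["g"]:
        warnings.warn(
            "activated transcription rate g* is below the basal rate g; "
            "the circuit will not auto-activate",
            stacklevel=2,
        )
    species = ["a", "A", "A2", "P_basal", "P_active"]
    rxns = [
        Reaction("transcription_basal", {"P_basal": 1}, {"P_basal": 1, "a": 1}, p["g"]),
        Reaction("mrna_decay", {"a": 1}, {}, p["d"]),
        Reaction("translation", {"a": 1}, {"a": 1, "A": 1}, p["p"]),
        Reaction("protein_decay", {"A": 1}, {}, p["r"]),
        Reaction("dimerization", {"A": 2}, {"A2": 1}, p["fd"],
                 combinatorial=dimer_half_factor),
        Reaction("dimer_dissociation", {"A2": 1}, {"A": 2}, p["bd"]),
        Reaction("promoter_binding", {"P_basal": 1, "A2": 1}, {"P_active": 1}, p["fp"]),
        Reaction("promoter_unbinding", {"P_active": 1}, {"P_basal": 1, "A2": 1}, p["bp"]),
        Reaction("transcription_active", {"P_active": 1}, {"P_active": 1, "a": 1}, p["g_star"]),
    ]
    return ReactionNetwork(
        species=species,
        reactions=rxns,
        initial_state={"a": 0, "A": 0, "A2": 0, "P_basal": 1, "P_active": 0},
        promoter_groups=[("P_basal", "P_active")],
        observed=["A"],
    )


def build_ts_generator(params: dict[str, float] | None = None) -> ReactionNetwork:
    """Build the fine-grained toggle-switch generating scheme.

    A single promoter region with three mutually exclusive states:
    basal ``P_basal``, ``P_A`` (an A monomer bound, repressing b/B) and
    ``P_B`` (a B monomer bound, repressing a/A).  The scheme is symmetric
    under A<->B exchange; the bound monomer is sequestered from the free
    pool while bound.
    """
    p = dict(TS_RATES)
    if params:
        p.update(params)
    _check_rates(p, tuple(TS_RATES))
    if p["g3_star"] > p["g3"]:
        warnings.warn(
            "repressed transcription rate g3* exceeds the basal rate g3; "
            "the circuit will not toggle",
            stacklevel=2,
        )
    species = ["a", "b", "A", "B", "P_basal", "P_A", "P_B"]
    rxns = [
        # basal promoter: both genes at full rate
        Reaction("transcription_a_basal", {"P_basal": 1}, {"P_basal": 1, "a": 1}, p["g3"]),
        Reaction("transcription_b_basal", {"P_basal": 1}, {"P_basal": 1, "b": 1}, p["g3"]),
        # A bound: gene a at full rate, gene b repressed
        Reaction("transcription_a_Abound", {"P_A": 1}, {"P_A": 1, "a": 1}, p["g3"]),
        Reaction("transcription_b_Abound", {"P_A": 1}, {"P_A": 1, "b": 1}, p["g3_star"]),
        # B bound: gene a repressed, gene b at full rate
        Reaction("transcription_a_Bbound", {"P_B": 1}, {"P_B": 1, "a": 1}, p["g3_star"]),
        Reaction("transcription_b_Bbound", {"P_B": 1}, {"P_B": 1, "b": 1}, p["g3"]),
        Reaction("mrna_a_decay", {"a": 1}, {}, p["d3"]),
        Reaction("mrna_b_decay", {"b": 1}, {}, p["d3"]),
        Reaction("translation_A", {"a": 1}, {"a": 1, "A": 1}, p["p3"]),
        Reaction("translation_B", {"b": 1}, {"b": 1, "B": 1}, p["p3"]),
        Reaction("protein_A_decay", {"A": 1}, {}, p["r3"]),
        Reaction("protein_B_decay", {"B": 1}, {}, p["r3"]),
        Reaction("A_binding", {"P_basal": 1, "A": 1}, {"P_A": 1}, p["f3"]),
        Reaction("A_unbinding", {"P_A": 1}, {"P_basal": 1, "A": 1}, p["b3"]),
        Reaction("B_binding", {"P_basal": 1, "B": 1}, {"P_B": 1}, p["f3"]),
        Reaction("B_unbinding", {"P_B": 1}, {"P_basal": 1, "B": 1}, p["b3"]),
    ]
    return ReactionNetwork(
        species=species,
        reactions=rxns,
        initial_state={sp: 0 for sp in species} | {"P_basal": 1},
        promoter_groups=[("P_basal", "P_A", "P_B")],
        observed=["A", "B"],
    )


def true_effective_rates(circuit: str, params: dict[str, float] | None = None) -> dict[str, float]:
    """Effective rates implied by a generating scheme's rate constants.

    The basal/activated (or repressed) production rates are the
    translation rate times the steady-state mRNA level in the
    corresponding promoter state, peff = p*(g/d); the effective
    degradation rate is the protein degradation rate itself.
    """
    if circuit == "sgaa":
        p = dict(SGAA_RATES)
        if params:
            p.update(params)
        return {
            "peff": p["p"] * p["g"] / p["d"],
            "peff_star": p["p"] * p["g_star"] / p["d"],
            "reff": p["r"],
        }
    if circuit == "ts":
        p = dict(TS_RATES)
        if params:
            p.update(params)
        return {
            "peff": p["p3"] * p["g3"] / p["d3"],
            "peff_star": p["p3"] * p["g3_star"] / p["d3"],
            "reff": p["r3"],
        }
    raise ValueError(f"unknown circuit {circuit!r}")
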