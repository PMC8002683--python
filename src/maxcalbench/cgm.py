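"""Coarse-grain inference model (CGM): Hill-feedback birth-death CMEs.

Feedback is folded into an effective production propensity: a Hill
activation term for the auto-activation circuit and a Hill repression
term (reading the other gene's count) for the toggle switch.  The
cooperativity is fixed at n = 2, the standard choice for dimer-mediated
regulation; it can be overridden for exploration but is excluded from
optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import PropensityRule, Reaction, ReactionNetwork
from .fsp import Channel, FSPStateSpace, GeneratorMatrix, assemble_generator


@dataclass(frozen=True)
class CGMParamsSGAA:
    """Auto-activation CGM: production g2 + g2* N^n/(N^n + K), per-capita
    degradation r2.  K is in counts^n."""

    g2: float
    g2_star: float
    K: float
    r2: float
    n: int = 2

    def __post_init__(self) -> None:
        if min(self.g2, self.g2_star, self.K, self.r2) < 0:
            raise ValueError("CGM parameters must be >= 0")


@dataclass(frozen=True)
class CGMParamsTS:
    """Toggle CGM: production of each gene is g5 + g5*/(N_other^n + K);
    g5* carries units of s^-1 * counts^n."""

    g5: float
    g5_star: float
    K: float
    r5: float
    n: int = 2

    def __post_init__(self) -> None:
        if min(self.g5, self.g5_star, self.K, self.r5) < 0:
            raise ValueError("CGM parameters must be >= 0")


def hill_production_sgaa(N, params: CGMParamsSGAA):
    """Monotone non-decreasing in N, bounded by g2 + g2*."""
    N = np.asarray(N, dtype=float)
    Nn = N ** params.n
    return params.g2 + params.g2_star * np.divide(
        Nn, Nn + params.K,
        out=np.zeros_like(Nn), where=(Nn + params.K) > 0,
    )


def hill_production_ts(N_other, params: CGMParamsTS):
    """Monotone non-increasing in the other gene's count; equals
    g5 + g5*/K at zero and approaches g5 asymptotically."""
    N = np.asarray(N_other, dtype=float)
    Nn = N ** params.n
    if params.K == 0 and np.any(Nn == 0):
        raise ZeroDivisionError(
            "TS Hill propensity with K=0 is undefined at zero repressor count"
        )
    return params.g5 + params.g5_star / (Nn + params.K)


def cgm_generator(params: CGMParamsSGAA | CGMParamsTS,
                  space: FSPStateSpace, **kw) -> GeneratorMatrix:
    """Hill-birth / per-capita-death generator on a promoter-free space
    (one axis for the auto-activation circuit, two for the toggle)."""
    if isinstance(params, CGMParamsSGAA):
        if len(space.axes) != 1:
            raise ValueError("SGAA CGM needs a single protein axis")
        p = params
        channels = [
            Channel((+1,), lambda N: hill_production_sgaa(N, p), "production"),
            Channel((-1,), lambda N: p.r2 * N, "degradation"),
        ]
    else:
        if len(space.axes) != 2:
            raise ValueError("TS CGM needs two protein axes")
        p = params
        channels = [
            Channel((+1, 0), lambda NA, NB: hill_production_ts(NB, p) * np.ones_like(NA, dtype=float),
                    "production_A"),
            Channel((0, +1), lambda NA, NB: hill_production_ts(NA, p) * np.ones_like(NB, dtype=float),
                    "production_B"),
            Channel((-1, 0), lambda NA, NB: p.r5 * NA, "degradation_A"),
            Channel((0, -1), lambda NA, NB: p.r5 * NB, "degradation_B"),
        ]
    return assemble_generator(channels, space, **kw)


def cgm_effective_rates(params: CGMParamsSGAA | CGMParamsTS) -> dict[str, float]:
    """Effective rates implied by the Hill propensity: its value in the
    basal and the saturated regime, plus the degradation rate."""
    if isinstance(params, CGMParamsSGAA):
        return {"peff": params.g2, "peff_star": params.g2 + params.g2_star,
                "reff": params.r2}
    return {"peff": params.g5 + params.g5_star / params.K,
            "peff_star": params.g5, "reff": params.r5}


def sgaa_cgm_network(params: CGMParamsSGAA) -> ReactionNetwork:
    """The SGAA CGM as a simulatable reaction network (data generated
    from the CGM's own scheme, e.g. for recovery checks)."""
    p = params
    rxns = [
        Reaction("production_basal", {}, {"A": 1}, p.g2),
        Reaction("production_hill", {}, {"A": 1}, p.g2_star,
                 rule=PropensityRule.HILL_ACTIVATION,
                 hill_species="A", hill_n=p.n, hill_K=p.K),
        Reaction("degradation", {"A": 1}, {}, p.r2),
    ]
    return ReactionNetwork(species=["A"], reactions=rxns,
                           initial_state={"A": 0}, observed=["A"])
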