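"""Exact stochastic simulation (Gillespie direct method) of reaction networks.

Trajectories are recorded as frame-sampled counts of the tagged proteins
only: the state immediately before/at each multiple of the frame
interval, after an initial burn-in that is discarded.  The inner loop is
compiled with numba; the per-trajectory RNG stream is derived from the
configured seed, so identical configurations reproduce identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .circuits import PropensityRule, ReactionNetwork

DEFAULT_DELTA_T = 300.0     # s; frame interval
DEFAULT_BURN_IN = 43200.0   # s; 12 h discarded before recording


@dataclass
class SimulationConfig:
    """Simulation run description.

    ``t_end`` is the total simulated time in seconds including the
    burn-in; frames are recorded at ``burn_in + k*delta_t`` for
    k = 0..floor((t_end-burn_in)/delta_t), i.e. the recorded span is
    ``t_end - burn_in`` seconds.
    """

    t_end: float
    delta_t: float = DEFAULT_DELTA_T
    n_trajectories: int = 1
    n_replicates: int = 1
    burn_in: float = DEFAULT_BURN_IN
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_end > self.delta_t > 0):
            raise ValueError("require t_end > delta_t > 0")
        if self.burn_in < 0 or self.burn_in >= self.t_end:
            raise ValueError("require 0 <= burn_in < t_end")
        if self.n_trajectories < 1 or self.n_replicates < 1:
            raise ValueError("trajectory and replicate counts must be >= 1")

    @property
    def n_frames(self) -> int:
        return math.floor((self.t_end - self.burn_in) / self.delta_t) + 1


@dataclass
class FrameSeries:
    """A uniformly sampled protein-count trajectory."""

    delta_t: float
    counts: np.ndarray                      # [n_frames, n_tagged]
    species_labels: list[str] = field(default_factory=lambda: ["A"])

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("frame counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("frame counts must be non-negative")
        if self.counts.shape[1] != len(self.species_labels):
            raise ValueError("one label per tagged-protein column is required")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.delta_t


@njit(cache=True)
def _ssa_kernel(x0, nu_react, nu_delta, rates, divisors, ptype, hill_sp,
                hill_n, hill_K, obs_idx, burn_in, dt, n_frames, seed):
    np.random.seed(seed)
    n_rxn = rates.shape[0]
    n_sp = x0.shape[0]
    x = x0.copy()
    frames = np.zeros((n_frames, obs_idx.shape[0]), dtype=np.int64)
    a = np.zeros(n_rxn)
    t = 0.0
    k = 0  # next frame index
    while k < n_frames:
        a0 = 0.0
        for j in range(n_rxn):
            if ptype[j] == 0:
                aj = rates[j]
                for s in range(n_sp):
                    nu = nu_react[j, s]
                    for c in range(nu):
                        aj *= x[s] - c
                if aj < 0.0:
                    aj = 0.0
                aj /= divisors[j]
            else:
                xn = float(x[hill_sp[j]]) ** hill_n[j]
                if ptype[j] == 1:
                    aj = rates[j] * xn / (xn + hill_K[j])
                else:
                    aj = rates[j] / (xn + hill_K[j])
                for s in range(n_sp):
                    if x[s] < nu_react[j, s]:
                        aj = 0.0
            a[j] = aj
            a0 += aj
        if not np.isfinite(a0):
            return frames, -1  # numeric error flag
        if a0 <= 0.0:
            # absorbing state: trajectory continues as a constant
            while k < n_frames:
                for o in range(obs_idx.shape[0]):
                    frames[k, o] = x[obs_idx[o]]
                k += 1
            break
        tau = -math.log(np.random.random()) / a0
        t_next = t + tau
        while k < n_frames and burn_in + k * dt <= t_next:
            for o in range(obs_idx.shape[0]):
                frames[k, o] = x[obs_idx[o]]
            k += 1
        u = np.random.random() * a0
        acc = 0.0
        jsel = n_rxn - 1
        for j in range(n_rxn):
            acc += a[j]
            if u < acc:
                jsel = j
                break
        for s in range(n_sp):
            x[s] += nu_delta[jsel, s]
        t = t_next
    return frames, 0


def _compile_network(network: ReactionNetwork):
    n_sp = len(network.species)
    n_rxn = len(network.reactions)
    nu_react = np.zeros((n_rxn, n_sp), dtype=np.int64)
    nu_delta = np.zeros((n_rxn, n_sp), dtype=np.int64)
    rates = np.zeros(n_rxn)
    divisors = np.ones(n_rxn)
    ptype = np.zeros(n_rxn, dtype=np.int64)
    hill_sp = np.zeros(n_rxn, dtype=np.int64)
    hill_n = np.full(n_rxn, 2.0)
    hill_K = np.ones(n_rxn)
    for j, rxn in enumerate(network.reactions):
        for sp, nu in rxn.reactants.items():
            s = network.index(sp)
            nu_react[j, s] = nu
            nu_delta[j, s] -= nu
        for sp, nu in rxn.products.items():
            nu_delta[j, network.index(sp)] += nu
        rates[j] = rxn.rate_constant
        if rxn.rule is PropensityRule.MASS_ACTION:
            if rxn.combinatorial:
                for nu in rxn.reactants.values():
                    divisors[j] *= math.factorial(nu)
        elif rxn.rule is PropensityRule.HILL_ACTIVATION:
            ptype[j] = 1
        elif rxn.rule is PropensityRule.HILL_REPRESSION:
            ptype[j] = 2
        else:
            raise NotImplementedError(f"propensity rule {rxn.rule}")
        if ptype[j] != 0:
            hill_sp[j] = network.index(rxn.hill_species)
            hill_n[j] = float(rxn.hill_n)
            hill_K[j] = float(rxn.hill_K)
    x0 = np.zeros(n_sp, dtype=np.int64)
    for sp, cnt in network.initial_state.items():
        x0[network.index(sp)] = cnt
    obs_idx = np.array([network.index(sp) for sp in network.observed],
                       dtype=np.int64)
    return x0, nu_react, nu_delta, rates, divisors, ptype, hill_sp, hill_n, \
        hill_K, obs_idx


def trajectory_seeds(rng_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit kernel seeds from a master seed."""
    ss = np.random.SeedSequence(rng_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def simulate_ssa(network: ReactionNetwork, config: SimulationConfig) -> list[FrameSeries]:
    """Simulate ``config.n_trajectories`` exact SSA trajectories.

    Returns one :class:`FrameSeries` per trajectory holding the tagged
    protein counts at every frame.
    """
    parts = _compile_network(network)
    seeds = trajectory_seeds(config.rng_seed, config.n_trajectories)
    out = []
    labels = list(network.observed)
    for i in range(config.n_trajectories):
        frames, status = _ssa_kernel(
            *parts, config.burn_in, config.delta_t, config.n_frames,
            int(seeds[i]),
        )
        if status != 0:
            raise FloatingPointError("non-finite total propensity during SSA")
        out.append(FrameSeries(config.delta_t, frames, labels))
    return out


def simulate_ensemble(
    circuit: str,
    config: SimulationConfig,
    params: dict[str, float] | None = None,
) -> list[list[FrameSeries]]:
    """Simulate ``n_replicates`` independent sets of trajectories for a
    named benchmark circuit (``sgaa`` or ``ts``) at its default rates
    unless overridden."""
    from .circuits import build_sgaa_generator, build_ts_generator

    if circuit == "sgaa":
        network = build_sgaa_generator(params)
    elif circuit == "ts":
        network = build_ts_generator(params)
    else:
        raise ValueError(f"unknown circuit {circuit!r}")
    rep_seeds = trajectory_seeds(config.rng_seed, config.n_replicates)
    replicates = []
    for rep in range(config.n_replicates):
        rep_cfg = SimulationConfig(
            t_end=config.t_end, delta_t=config.delta_t,
            n_trajectories=config.n_trajectories, n_replicates=1,
            burn_in=config.burn_in, rng_seed=int(rep_seeds[rep]),
        )
        replicates.append(simulate_ssa(network, rep_cfg))
    return replicates


def generate_benchmark_ensemble(
    circuit: str,
    config: SimulationConfig,
    out_dir,
    params: dict[str, float] | None = None,
):
    """Simulate a benchmark ensemble and write it to disk as TSV
    trajectory files plus a JSON manifest; returns the manifest."""
    from . import io as _io

    replicates = simulate_ensemble(circuit, config, params)
    return _io.write_ensemble(out_dir, circuit, config, replicates, params)
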