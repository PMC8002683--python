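"""Maximum Caliber model: path probabilities per frame from constrained
path-entropy maximization.

Between consecutive frames the model tracks, for each tagged protein,
the number of new productions l_alpha (capped at M) and the number of
survivors l_A among the N proteins present.  Maximizing the path entropy
subject to constraints on mean production, mean survival and the
production-abundance coupling gives a Gibbs form over (l_alpha, l_A)
with Lagrange multipliers (h_alpha, h_A, K_A) and a binomial degeneracy
C(N, l_A).  Degradation is implicit in survival: there is no separate
death multiplier.  The toggle-switch variant shares one production and
one survival multiplier between the two genes and adds a same-gene
coupling K_A_alpha and a cross-gene coupling K_A_beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .fsp import FSPStateSpace, PropagatorMatrix, stationary_distribution


@dataclass(frozen=True)
class MaxCalParamsSGAA:
    h_alpha: float
    h_A: float
    K_A: float
    M: int

    def __post_init__(self) -> None:
        if self.M < 1 or int(self.M) != self.M:
            raise ValueError("M must be a positive integer")
        if not all(np.isfinite([self.h_alpha, self.h_A, self.K_A])):
            raise ValueError("multipliers must be finite")


@dataclass(frozen=True)
class MaxCalParamsTS:
    h_alpha: float
    h_A: float
    K_A_alpha: float
    K_A_beta: float
    M: int

    def __post_init__(self) -> None:
        if self.M < 1 or int(self.M) != self.M:
            raise ValueError("M must be a positive integer")
        if not all(np.isfinite([self.h_alpha, self.h_A,
                                self.K_A_alpha, self.K_A_beta])):
            raise ValueError("multipliers must be finite")


@dataclass
class PathDistribution:
    """Normalized probabilities over per-frame path variables for a
    fixed conditioning state, plus the log partition function."""

    state: tuple[int, ...]
    probs: np.ndarray          # (M+1, NA+1) or (M+1, NA+1, M+1, NB+1)
    log_Q: float
    labels: tuple[str, ...] = field(default=("l_alpha", "l_A"))

    @property
    def Q(self) -> float:
        return float(np.exp(self.log_Q))

    def mean(self, axis_label: str) -> float:
        """Conditional mean of one path variable."""
        ax = self.labels.index(axis_label)
        grid = np.arange(self.probs.shape[ax])
        marg = self.probs.sum(axis=tuple(i for i in range(self.probs.ndim)
                                         if i != ax))
        return float(grid @ marg)


def _log_weights_sgaa(NA: int, params: MaxCalParamsSGAA) -> np.ndarray:
    la = np.arange(params.M + 1)[:, None]      # productions
    lA = np.arange(NA + 1)[None, :]            # survivors
    log_binom = gammaln(NA + 1) - gammaln(lA + 1.0) - gammaln(NA - lA + 1.0)
    return (log_binom + params.h_alpha * la + params.h_A * lA
            + params.K_A * la * lA)


def path_distribution_sgaa(NA: int, params: MaxCalParamsSGAA) -> PathDistribution:
    """Joint distribution of (l_alpha, l_A) given NA proteins present."""
    if NA < 0:
        raise ValueError("NA must be >= 0")
    logw = _log_weights_sgaa(NA, params)
    log_Q = float(logsumexp(logw))
    if not np.isfinite(log_Q):
        raise FloatingPointError("partition function overflow/underflow")
    return PathDistribution((NA,), np.exp(logw - log_Q), log_Q)


def _log_weights_ts(NA: int, NB: int, params: MaxCalParamsTS) -> np.ndarray:
    M = params.M
    la = np.arange(M + 1)[:, None, None, None]
    lA = np.arange(NA + 1)[None, :, None, None]
    lb = np.arange(M + 1)[None, None, :, None]
    lB = np.arange(NB + 1)[None, None, None, :]
    log_binom = (
        gammaln(NA + 1) - gammaln(lA + 1.0) - gammaln(NA - lA + 1.0)
        + gammaln(NB + 1) - gammaln(lB + 1.0) - gammaln(NB - lB + 1.0)
    )
    return (log_binom
            + params.h_alpha * (la + lb)
            + params.h_A * (lA + lB)
            + params.K_A_alpha * (la * lA + lb * lB)
            + params.K_A_beta * (lb * lA + la * lB))


def path_distribution_ts(NA: int, NB: int,
                         params: MaxCalParamsTS) -> PathDistribution:
    """Joint distribution of (l_alpha, l_A, l_beta, l_B) given (NA, NB)."""
    if NA < 0 or NB < 0:
        raise ValueError("counts must be >= 0")
    logw = _log_weights_ts(NA, NB, params)
    log_Q = float(logsumexp(logw))
    if not np.isfinite(log_Q):
        raise FloatingPointError("partition function overflow/underflow")
    return PathDistribution((NA, NB), np.exp(logw - log_Q), log_Q,
                            labels=("l_alpha", "l_A", "l_beta", "l_B"))


def transition_matrix_sgaa(params: MaxCalParamsSGAA,
                           space: FSPStateSpace) -> PropagatorMatrix:
    """One-frame transition matrix P[j, i] = P(i -> j): the next count is
    j = l_alpha + l_A; mass beyond the tracked range goes to the sink,
    which is absorbing.

    Vectorized over all source states: the unnormalized path weight
    factorizes as A[l_alpha, l_A] * B[i, l_A], and the per-state
    normalization cancels any uniform rescaling, so each factor is
    shifted by its own maximum exponent before exponentiation.
    """
    if len(space.axes) != 1:
        raise ValueError("the SGAA MaxCal space has a single protein axis")
    nmax = space.shape[0]
    n = space.dimension
    M = params.M
    la = np.arange(M + 1)[:, None]
    lA = np.arange(nmax)[None, :]
    i = np.arange(nmax)[:, None]
    ea = params.h_alpha * la + params.K_A * la * lA          # (M+1, lA)
    mask = lA <= i
    with np.errstate(invalid="ignore"):
        logb = np.where(
            mask,
            gammaln(i + 1.0) - gammaln(lA + 1.0) - gammaln(np.maximum(i - lA, 0) + 1.0),
            -np.inf,
        )
    eb = logb + params.h_A * lA                              # (i, lA)
    A = np.exp(ea - ea.max())
    B = np.exp(eb - eb.max(initial=-np.inf, where=mask, axis=None))
    Tpad = np.zeros((nmax + M, nmax))
    for a in range(M + 1):
        Tpad[a:a + nmax, :] += (B * A[a][None, :]).T
    Q = Tpad.sum(axis=0)
    if not np.all(np.isfinite(Q)) or np.any(Q <= 0):
        raise FloatingPointError("path-weight overflow/underflow in "
                                 "transition-matrix assembly")
    P = np.zeros((n, n))
    P[:nmax, :nmax] = Tpad[:nmax, :] / Q
    P[space.sink_index, :nmax] = Tpad[nmax:, :].sum(axis=0) / Q
    P[space.sink_index, space.sink_index] = 1.0
    return PropagatorMatrix(space, P, 1)


def transition_matrix_ts(params: MaxCalParamsTS,
                         space: FSPStateSpace) -> PropagatorMatrix:
    """One-frame transition matrix on the joint (N_A, N_B) space."""
    if len(space.axes) != 2:
        raise ValueError("the TS MaxCal space has two protein axes")
    nA, nB = space.shape
    n = space.dimension
    M = params.M
    P = np.zeros((n, n))
    la = np.arange(M + 1)[:, None, None, None]
    lb = np.arange(M + 1)[None, None, :, None]
    for i in range(nA):
        for k in range(nB):
            probs = path_distribution_ts(i, k, params).probs
            j = la + np.arange(i + 1)[None, :, None, None]
            l = lb + np.arange(k + 1)[None, None, None, :]
            jf = np.broadcast_to(j, probs.shape).ravel()
            lf = np.broadcast_to(l, probs.shape).ravel()
            src = space.index((i, k))
            in_range = (jf < nA) & (lf < nB)
            dest = jf[in_range] * nB + lf[in_range]
            col = np.bincount(dest, weights=probs.ravel()[in_range],
                              minlength=space.n_tracked)
            P[:space.n_tracked, src] = col
            P[space.sink_index, src] = probs.ravel()[~in_range].sum()
    P[space.sink_index, space.sink_index] = 1.0
    return PropagatorMatrix(space, P, 1)


class ModeError(RuntimeError):
    """The stationary law does not exhibit the two modes required for
    effective-rate extraction."""

    def __init__(self, message: str, candidates=None, distribution=None):
        super().__init__(message)
        self.candidates = candidates
        self.distribution = distribution


def find_two_modes(pi: np.ndarray) -> tuple[int, int]:
    """Strict local maxima of a 1-D distribution; returns the low and
    high mode locations, keeping the two with largest mass if more than
    two candidates exist."""
    pi = np.asarray(pi, dtype=float)
    cand = []
    for i in range(pi.size):
        left = pi[i - 1] if i > 0 else -np.inf
        right = pi[i + 1] if i < pi.size - 1 else -np.inf
        if pi[i] > left and pi[i] > right:
            cand.append(i)
    if len(cand) < 2:
        raise ModeError(
            f"stationary law has {len(cand)} strict mode(s); two are "
            "required for low/high-state rate extraction",
            candidates=cand, distribution=pi,
        )
    cand = sorted(sorted(cand, key=lambda i: pi[i], reverse=True)[:2])
    return cand[0], cand[1]


def maxcal_effective_rates(
    params: MaxCalParamsSGAA,
    space: FSPStateSpace,
    delta_t: float,
    *,
    stationary: np.ndarray | None = None,
) -> dict[str, float]:
    """Extract (peff, peff*, reff) from a fitted SGAA MaxCal model.

    peff is the conditional mean production per frame at the low-state
    mode of the stationary count distribution divided by the frame
    interval, peff* the same at the high-state mode; the per-state
    degradation rate r(N) = (N - <l_A>_N) / (N dt) is averaged over the
    stationary law excluding N = 0 (where it is undefined), with the
    weights renormalized over N >= 1.
    """
    T = transition_matrix_sgaa(params, space)
    if stationary is None:
        stationary = stationary_distribution(T)
    NL, NH = find_two_modes(stationary)
    dists = [path_distribution_sgaa(N, params) for N in range(space.shape[0])]
    mean_prod = np.array([d.mean("l_alpha") for d in dists])
    mean_surv = np.array([d.mean("l_A") for d in dists])
    N = np.arange(space.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        r_of_N = (N - mean_surv) / (N * delta_t)
    w = stationary[1:] / stationary[1:].sum()
    reff = float(w @ r_of_N[1:])
    return {
        "peff": float(mean_prod[NL] / delta_t),
        "peff_star": float(mean_prod[NH] / delta_t),
        "reff": reff,
        "NL": int(NL),
        "NH": int(NH),
    }


def maxcal_effective_rates_ts(
    params: MaxCalParamsTS,
    space: FSPStateSpace,
    delta_t: float,
    *,
    stationary: np.ndarray | None = None,
) -> dict[str, float]:
    """TS variant: modes are the two joint modes (high A, low B) and
    (low A, high B); peff is the mean production of A per frame at the
    unrepressed mode, peff* at the repressed mode; r_A(N_A, N_B) is
    averaged over the joint stationary law excluding N_A = 0."""
    T = transition_matrix_ts(params, space)
    if stationary is None:
        stationary = stationary_distribution(T)
    joint = stationary.reshape(space.shape)
    NL, NH = find_two_modes(joint.sum(axis=1))
    # by exchange symmetry the two joint modes are (NH, NL) and (NL, NH)
    d_unrep = path_distribution_ts(NH, NL, params)
    d_rep = path_distribution_ts(NL, NH, params)
    nA, nB = space.shape
    mean_surv_A = np.zeros((nA, nB))
    for i in range(nA):
        for k in range(nB):
            mean_surv_A[i, k] = path_distribution_ts(i, k, params).mean("l_A")
    NA = np.arange(nA)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        rA = (NA - mean_surv_A) / (NA * delta_t)
    mask = np.zeros_like(joint, dtype=bool)
    mask[1:, :] = True
    w = joint * mask
    w = w / w.sum()
    reff = float((w * np.where(mask, rA, 0.0)).sum())
    return {
        "peff": float(d_unrep.mean("l_alpha") / delta_t),
        "peff_star": float(d_rep.mean("l_alpha") / delta_t),
        "reff": reff,
        "NL": int(NL),
        "NH": int(NH),
    }


def simulate_chain_sgaa(
    params: MaxCalParamsSGAA,
    space: FSPStateSpace,
    n_frames: int,
    seed: int,
    N0: int = 0,
) -> np.ndarray:
    """Sample a trajectory of the SGAA MaxCal chain itself (one step per
    frame), used to generate data from the model's own scheme."""
    T = transition_matrix_sgaa(params, space).P
    nmax = space.shape[0]
    cdf = np.cumsum(T[:nmax, :nmax], axis=0)
    cdf /= cdf[-1, :]  # condition on staying in the tracked range
    rng = np.random.default_rng(seed)
    u = rng.random(n_frames - 1)
    out = np.empty(n_frames, dtype=np.int64)
    out[0] = N0
    for t in range(1, n_frames):
        out[t] = np.searchsorted(cdf[:, out[t - 1]], u[t - 1])
    return out
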