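"""Independent oracles used by the test suite.

Everything here is deliberately written with plain Python loops and
``math`` so it shares no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def enum_path_probs_sgaa(NA: int, h_alpha: float, h_A: float, K_A: float,
                         M: int) -> tuple[dict, float]:
    """Exhaustively enumerate the per-frame path weights for one gene:
    returns ({(l_alpha, l_A): probability}, Q)."""
    weights = {}
    Q = 0.0
    for la in range(M + 1):
        for lA in range(NA + 1):
            w = math.comb(NA, lA) * math.exp(
                h_alpha * la + h_A * lA + K_A * la * lA)
            weights[(la, lA)] = w
            Q += w
    return {k: v / Q for k, v in weights.items()}, Q


def enum_transition_sgaa(nmax: int, h_alpha: float, h_A: float, K_A: float,
                         M: int) -> np.ndarray:
    """One-frame transition matrix (column convention, sink last) by
    brute-force enumeration of every path."""
    n = nmax + 1
    P = np.zeros((n, n))
    for i in range(nmax):
        probs, _ = enum_path_probs_sgaa(i, h_alpha, h_A, K_A, M)
        for (la, lA), p in probs.items():
            j = la + lA
            if j < nmax:
                P[j, i] += p
            else:
                P[nmax, i] += p
    P[nmax, nmax] = 1.0
    return P


def enum_path_probs_ts(NA: int, NB: int, h_alpha: float, h_A: float,
                       K_Aa: float, K_Ab: float, M: int) -> tuple[dict, float]:
    """Exhaustive enumeration of the two-gene path weights."""
    weights = {}
    Q = 0.0
    for la in range(M + 1):
        for lA in range(NA + 1):
            for lb in range(M + 1):
                for lB in range(NB + 1):
                    w = (math.comb(NA, lA) * math.comb(NB, lB) * math.exp(
                        h_alpha * (la + lb) + h_A * (lA + lB)
                        + K_Aa * (la * lA + lb * lB)
                        + K_Ab * (lb * lA + la * lB)))
                    weights[(la, lA, lb, lB)] = w
                    Q += w
    return {k: v / Q for k, v in weights.items()}, Q


def enum_transition_ts(nmax: int, h_alpha: float, h_A: float, K_Aa: float,
                       K_Ab: float, M: int) -> np.ndarray:
    """Brute-force two-gene one-frame transition matrix (sink last)."""
    n = nmax * nmax + 1
    P = np.zeros((n, n))
    for i in range(nmax):
        for k in range(nmax):
            probs, _ = enum_path_probs_ts(i, k, h_alpha, h_A, K_Aa, K_Ab, M)
            src = i * nmax + k
            for (la, lA, lb, lB), p in probs.items():
                j, l = la + lA, lb + lB
                if j < nmax and l < nmax:
                    P[j * nmax + l, src] += p
                else:
                    P[n - 1, src] += p
    P[n - 1, n - 1] = 1.0
    return P


def taylor_expm(W: np.ndarray, tau: float, terms: int = 30) -> np.ndarray:
    """Truncated Taylor series of expm(W tau)."""
    A = np.asarray(W, dtype=float) * tau
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms + 1):
        term = term @ A / k
        out = out + term
    return out


def random_generator(rng: np.random.Generator, n: int,
                     scale: float = 1.0) -> np.ndarray:
    """A random dense CTMC generator (columns sum to zero)."""
    W = rng.uniform(0, scale, size=(n, n))
    np.fill_diagonal(W, 0.0)
    W -= np.diag(W.sum(axis=0))
    return W
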