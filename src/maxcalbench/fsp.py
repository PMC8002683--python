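"""Finite State Projection machinery for truncated chemical master equations.

A state space is a Cartesian product of count axes (tracked range
[0, N-1] per axis, protein counts and/or binary promoter flags) plus a
single absorbing sink state, appended last, that aggregates every state
with any count beyond its tracked range.  Generator matrices follow the
column convention W[j, i] = rate from state i to state j, so every
column sums to zero and probability vectors evolve as p(t) = expm(W t) p(0).

The sink is absorbing: flux leaving the tracked range accumulates there
and the sink mass after propagation bounds the truncation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm

DEFAULT_DIMENSION_CAP = 50_000
DENSE_THRESHOLD = 4_000      # assemble sparse above this dimension
COLUMN_TOL = 1e-10
LEAK_WARN = 1e-6


class DimensionError(ValueError):
    """State-space dimension exceeds the configured cap."""


@dataclass(frozen=True)
class FSPStateSpace:
    """Truncated product state space with a terminal sink index."""

    axes: tuple[tuple[str, int], ...]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(card for _, card in self.axes)

    @property
    def n_tracked(self) -> int:
        return int(np.prod(self.shape))

    @property
    def dimension(self) -> int:
        return self.n_tracked + 1

    @property
    def sink_index(self) -> int:
        return self.n_tracked

    def index(self, state: Sequence[int]) -> int:
        """Linear index of a state tuple (sink if out of range)."""
        for v, card in zip(state, self.shape):
            if v < 0 or v >= card:
                return self.sink_index
        return int(np.ravel_multi_index(tuple(state), self.shape))

    def state(self, index: int) -> tuple[int, ...]:
        if index == self.sink_index:
            raise IndexError("the sink has no state tuple")
        return tuple(int(v) for v in np.unravel_index(index, self.shape))

    def grids(self) -> list[np.ndarray]:
        """One integer coordinate array per axis, each of shape ``shape``."""
        return list(np.indices(self.shape))


def build_state_space(
    axes_spec: Sequence[tuple[str, int]],
    *,
    dimension_cap: int = DEFAULT_DIMENSION_CAP,
) -> FSPStateSpace:
    axes = tuple((str(name), int(card)) for name, card in axes_spec)
    if any(card < 1 for _, card in axes):
        raise ValueError("axis cardinalities must be >= 1")
    space = FSPStateSpace(axes)
    if space.dimension > dimension_cap:
        raise DimensionError(
            f"state-space dimension {space.dimension} exceeds the cap "
            f"{dimension_cap}; reduce the count bounds or raise "
            f"`dimension_cap` explicitly if the matrix truly fits in memory"
        )
    return space


def auto_nmax(max_observed: int) -> int:
    """FSP bound from data: comfortably above the largest observed count."""
    return max(int(np.ceil(1.5 * max_observed)), max_observed + 20)


@dataclass
class Channel:
    """One reaction channel on a state space: a fixed per-axis state
    change and a propensity function evaluated on coordinate grids."""

    delta: tuple[int, ...]
    propensity: Callable[..., np.ndarray]
    name: str = ""


@dataclass
class GeneratorMatrix:
    space: FSPStateSpace
    W: np.ndarray | sp.spmatrix

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.W)

    def dense(self) -> np.ndarray:
        return self.W.toarray() if self.is_sparse else self.W


@dataclass
class PropagatorMatrix:
    space: FSPStateSpace
    P: np.ndarray
    horizon: float  # seconds (continuous-time) or frame count (chains)


def assemble_generator(
    channels: Sequence[Channel],
    space: FSPStateSpace,
    *,
    force_dense: bool | None = None,
) -> GeneratorMatrix:
    """Assemble the CME rate matrix over ``space`` from reaction channels.

    Transitions leaving any tracked range are routed to the sink; the
    sink itself is absorbing.  Columns sum to exactly zero by
    construction (the diagonal is the negated column outflow).
    """
    grids = space.grids()
    n = space.dimension
    src_flat = np.arange(space.n_tracked)
    rows, cols, vals = [], [], []
    diag = np.zeros(space.n_tracked)
    shape = space.shape
    for ch in channels:
        if len(ch.delta) != len(shape):
            raise ValueError(
                f"channel {ch.name!r}: delta has {len(ch.delta)} entries "
                f"for a {len(shape)}-axis space"
            )
        a = np.asarray(ch.propensity(*grids), dtype=float)
        if a.shape != tuple(shape):
            a = np.broadcast_to(a, shape).astype(float)
        a = a.reshape(-1)
        if (a < 0).any():
            raise ValueError(f"channel {ch.name!r}: negative propensity")
        active = a > 0
        if not active.any():
            continue
        coords = [g.reshape(-1)[active] + d for g, d in zip(grids, ch.delta)]
        in_range = np.ones(active.sum(), dtype=bool)
        for c, card in zip(coords, shape):
            in_range &= (c >= 0) & (c < card)
        src = src_flat[active]
        dest = np.full(src.shape, space.sink_index, dtype=np.int64)
        if in_range.any():
            dest[in_range] = np.ravel_multi_index(
                tuple(c[in_range] for c in coords), shape
            )
        rows.append(dest)
        cols.append(src)
        vals.append(a[active])
        np.add.at(diag, src, -a[active])
    rows.append(src_flat)
    cols.append(src_flat)
    vals.append(diag)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    use_dense = force_dense if force_dense is not None else n <= DENSE_THRESHOLD
    if use_dense:
        W = W.toarray()
    return GeneratorMatrix(space, W)


def _as_generator_array(W) -> tuple[np.ndarray, FSPStateSpace | None]:
    if isinstance(W, GeneratorMatrix):
        return W.dense(), W.space
    if sp.issparse(W):
        return W.toarray(), None
    return np.asarray(W, dtype=float), None


def propagate(W, tau: float) -> PropagatorMatrix | np.ndarray:
    """Matrix exponential propagator over ``tau`` seconds.

    Scaling-and-squaring via :func:`scipy.linalg.expm`; the result is
    column-stochastic to within 1e-10 for a valid generator.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    Wd, space = _as_generator_array(W)
    P = expm(Wd * tau)
    if not np.isfinite(P).all():
        raise FloatingPointError("non-finite entries in propagator")
    if space is not None:
        return PropagatorMatrix(space, P, tau)
    return P


def matrix_power(P, m: int):
    """m-step propagator by exponentiation-by-squaring."""
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    m = int(m)
    if isinstance(P, PropagatorMatrix):
        if m == 1:
            return P
        return PropagatorMatrix(P.space, np.linalg.matrix_power(P.P, m),
                                P.horizon * m)
    if m == 1:
        return P
    return np.linalg.matrix_power(np.asarray(P, dtype=float), m)


def check_column_stochastic(P: np.ndarray, tol: float = COLUMN_TOL) -> None:
    err = np.abs(P.sum(axis=0) - 1.0).max()
    if err > tol:
        raise AssertionError(f"columns deviate from 1 by {err:.2e} > {tol:.0e}")


def _dominant_column_eigvec(A: np.ndarray) -> np.ndarray:
    """Right eigenvector of the dominant (largest real part) eigenvalue,
    normalized to a probability vector; power-iteration fallback."""
    try:
        vals, vecs = np.linalg.eig(A)
        k = int(np.argmax(vals.real))
        v = vecs[:, k].real
    except np.linalg.LinAlgError:
        v = np.full(A.shape[0], 1.0 / A.shape[0])
        shift = np.abs(A).sum() + 1.0
        B = A + shift * np.eye(A.shape[0])
        for _ in range(10_000):
            v_new = B @ v
            v_new /= np.abs(v_new).sum()
            if np.abs(v_new - v).max() < 1e-12:
                v = v_new
                break
            v = v_new
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise ArithmeticError("failed to extract a dominant eigenvector")
    return v / total


def stationary_distribution(
    M,
    *,
    kind: str | None = None,
    leak_warn: float = LEAK_WARN,
) -> np.ndarray:
    """Relative-equilibrium distribution over the non-sink states.

    For a propagator (column-stochastic, ``kind='propagator'``) or a
    generator (zero column sums, ``kind='generator'``), restrict to the
    tracked states, take the dominant eigenvector, and renormalize.
    The sink makes the tracked chain slightly leaky; the per-frame leak
    under the returned distribution is reported via a warning when it
    exceeds ``leak_warn`` (propagators only).
    """
    if isinstance(M, PropagatorMatrix):
        A, kind = M.P, "propagator"
    elif isinstance(M, GeneratorMatrix):
        A, kind = M.dense(), "generator"
    else:
        A = np.asarray(M, dtype=float)
        if kind is None:
            colsum = A.sum(axis=0)
            kind = "propagator" if np.allclose(colsum[:-1], 1.0, atol=1e-6) \
                else "generator"
    R = A[:-1, :-1]
    if kind == "generator":
        # shift so the dominant eigenvalue of the leaky generator maps to
        # the dominant eigenvalue of a non-negative matrix
        shift = float(np.abs(np.diag(R)).max()) + 1.0
        pi = _dominant_column_eigvec(R + shift * np.eye(R.shape[0]))
    else:
        pi = _dominant_column_eigvec(R)
        leak = float(1.0 - R.sum(axis=0) @ pi)
        if leak > leak_warn:
            warnings.warn(
                f"per-frame sink leakage {leak:.2e} exceeds {leak_warn:.0e}; "
                "consider raising the FSP bound",
                stacklevel=2,
            )
    return pi
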