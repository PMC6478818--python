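"""Exact fixation quantities from the full configuration Markov chain.

The Moran birth-death process on a graph with N vertices is a Markov chain
over the 2^N subsets of vertices occupied by the mutant type.  The empty set
and the full set are the only absorbing configurations.  Solving the
absorbing-chain linear systems gives, for every starting configuration, the
fixation probability, the expected absorption time, and the expected
fixation time conditional on fixation -- all in Moran steps, where *every*
birth-death event counts, including events that do not change the
configuration (e.g. an offspring replacing an individual of its own type,
or a self-loop replacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import lu_factor, lu_solve
from scipy.sparse.linalg import splu

from .graphs import GraphError, ReplacementKernel, WeightedGraph

__all__ = ["MutantConfiguration", "FixationSolution", "step_distribution", "solve_fixation"]

#: beyond this many vertices the 2^N state space is deemed out of reach
DEFAULT_VERTEX_CAP = 14

_DENSE_STATE_LIMIT = 2048  # use dense LU below this many states


@dataclass(frozen=True)
class MutantConfiguration:
    """A set of mutant-occupied vertices, encoded as an n-bit mask."""

    n: int
    mask: int

    @classmethod
    def from_vertices(cls, n: int, vertices) -> "MutantConfiguration":
        mask = 0
        for v in vertices:
            if not 0 <= v < n:
                raise GraphError(f"vertex {v} out of range")
            mask |= 1 << v
        return cls(n, mask)

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(v for v in range(self.n) if self.mask >> v & 1)

    @property
    def k(self) -> int:
        return bin(self.mask).count("1")

    @property
    def is_absorbing(self) -> bool:
        return self.mask == 0 or self.mask == (1 << self.n) - 1


@dataclass(frozen=True)
class FixationSolution:
    """Per-starting-vertex fixation quantities for a single invading mutant.

    Attributes
    ----------
    rho : ndarray
        ``rho[v]`` -- probability that a single mutant started at vertex v
        takes over the population.
    absorb_time : ndarray
        Expected Moran steps until the population is homogeneous.
    cond_fix_time : ndarray
        Expected Moran steps conditional on eventual fixation.
    cond_ext_time : ndarray
        Expected Moran steps conditional on eventual extinction; together
        with the others it satisfies
        ``absorb = rho * fix + (1 - rho) * ext`` exactly.
    r : float
        Mutant relative fitness.
    """

    rho: np.ndarray
    absorb_time: np.ndarray
    cond_fix_time: np.ndarray
    cond_ext_time: np.ndarray
    r: float

    @property
    def n(self) -> int:
        return self.rho.shape[0]

    def __post_init__(self) -> None:
        if np.any(self.rho <= 0) or np.any(self.rho >= 1):
            raise GraphError("single-mutant fixation probabilities must lie in (0, 1)")


def step_distribution(
    kernel: ReplacementKernel, r: float, config: MutantConfiguration
) -> list[tuple[MutantConfiguration, float]]:
    """One-step transition distribution of the Moran process.

    A reproducer u is drawn with probability f(u)/F where f(u) = r for
    mutants and 1 for residents; the offspring lands on v with probability
    w(u, v) and converts v to u's type.  Same-type replacements (including
    self-loops) leave the configuration unchanged but still count as one
    Moran step.
    """
    if config.is_absorbing:
        raise GraphError("step distribution undefined for an absorbing configuration")
    if r <= 0:
        raise GraphError(f"fitness must be positive, got r={r}")
    n = kernel.n
    k = config.k
    total_f = r * k + (n - k)
    probs: dict[int, float] = {}
    for u in range(n):
        u_mut = config.mask >> u & 1
        p_u = (r if u_mut else 1.0) / total_f
        targets, ws = kernel.row(u)
        for v, w in zip(targets, ws):
            new = config.mask | (1 << int(v)) if u_mut else config.mask & ~(1 << int(v))
            probs[new] = probs.get(new, 0.0) + p_u * float(w)
    return [(MutantConfiguration(n, m), p) for m, p in sorted(probs.items())]


def _transition_matrix(kernel: ReplacementKernel, r: float) -> sparse.csr_matrix:
    """Sparse 2^n x 2^n one-step matrix, built vectorised over states."""
    n = kernel.n
    n_states = 1 << n
    states = np.arange(n_states, dtype=np.int64)
    k = np.bitwise_count(states).astype(np.float64)
    total_f = r * k + (n - k)
    rows, cols, vals = [], [], []
    for u in range(n):
        u_mut = (states >> u & 1).astype(bool)
        p_u = np.where(u_mut, r, 1.0) / total_f
        targets, ws = kernel.row(u)
        for v, w in zip(targets, ws):
            bit = np.int64(1 << int(v))
            new = np.where(u_mut, states | bit, states & ~bit)
            rows.append(states)
            cols.append(new)
            vals.append(p_u * float(w))
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_states, n_states),
    ).tocsr()
    # overwrite the absorbing rows with identity
    full = n_states - 1
    for s in (0, full):
        start, end = mat.indptr[s], mat.indptr[s + 1]
        mat.data[start:end] = 0.0
    mat = mat + sparse.csr_matrix(([1.0, 1.0], ([0, full], [0, full])), shape=mat.shape)
    mat.eliminate_zeros()
    return mat


def solve_fixation(
    kernel: ReplacementKernel, r: float, vertex_cap: int = DEFAULT_VERTEX_CAP
) -> FixationSolution:
    """Solve the absorbing chain exactly and return the single-mutant slices.

    The linear systems are, over transient configurations S,

    * fixation probability:  rho_S = sum_S' P(S,S') rho_S'  with rho at the
      full configuration equal to 1 and at the empty configuration 0;
    * absorption time:       a_S = 1 + sum_S' P(S,S') a_S';
    * conditional times via z_S = rho_S tau_S (and the mirrored system for
      extinction), which satisfy z_S = rho_S + sum_S' P(S,S') z_S'.

    Self-transitions P(S,S) > 0 are retained, so all times count every Moran
    step.
    """
    n = kernel.n
    if r <= 0:
        raise GraphError(f"fitness must be positive, got r={r}")
    if n > vertex_cap:
        raise GraphError(
            f"{n} vertices exceeds the full-state cap of {vertex_cap} "
            "(use the lumped solvers or the simulator)"
        )
    n_states = 1 << n
    full = n_states - 1
    P = _transition_matrix(kernel, r)
    transient = np.arange(1, full)
    Q = P[transient][:, transient]
    to_fix = P[:, [full]].toarray().ravel()[transient]
    A = sparse.identity(len(transient), format="csc") - Q.tocsc()

    if len(transient) <= _DENSE_STATE_LIMIT:
        lu = lu_factor(A.toarray())
        solve = lambda b: lu_solve(lu, b)  # noqa: E731
    else:
        fac = splu(A)
        solve = fac.solve

    rho = solve(to_fix)
    if not np.all(np.isfinite(rho)):
        raise GraphError("singular absorbing system: is the graph connected?")
    a = solve(np.ones(len(transient)))
    z_fix = solve(rho)
    z_ext = solve(1.0 - rho)

    idx = np.array([(1 << v) - 1 for v in range(n)])  # transient index of {v}
    rho_v = rho[idx]
    return FixationSolution(
        rho=rho_v,
        absorb_time=a[idx],
        cond_fix_time=z_fix[idx] / rho_v,
        cond_ext_time=z_ext[idx] / (1.0 - rho_v),
        r=float(r),
    )


def solve_fixation_graph(graph: WeightedGraph, r: float, **kw) -> FixationSolution:
    """Convenience wrapper: build the kernel and solve."""
    return solve_fixation(graph.kernel(), r, **kw)
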