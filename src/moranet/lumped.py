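"""Symmetry-reduced exact solvers for highly symmetric population structures.

Complete graphs reduce to a one-dimensional birth-death chain over the
mutant count; complete bipartite graphs (with optional uniform self-loops
on the large part) reduce to a two-dimensional chain over the pair
(i, j) = (mutants in the large part, mutants in the small part), because
all vertices within a part are automorphic.  The star graph is the special
case of a bipartite graph with a single-vertex small part.  These
reductions bring exact computation from 2^N configurations down to
(m+1)(s+1) states, reaching populations of a few thousand.

All times are in Moran steps and count every birth-death event, including
steps in which the configuration does not change (in particular self-loop
replacements, which dominate on the alpha-weighted bipartite graphs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solve_banded
from scipy.sparse.linalg import splu

from .graphs import GraphError

__all__ = [
    "BirthDeathChain",
    "LumpedResult",
    "complete_graph_rho",
    "complete_graph_stats",
    "star_stats",
    "bipartite_stats",
]

#: refuse bipartite chains with more states than this
DEFAULT_STATE_CAP = 2_000_000


@dataclass(frozen=True)
class LumpedResult:
    """Aggregated fixation quantities from a lumped exact solve."""

    rho: float
    absorb_time: float
    cond_fix_time: float
    #: per-starting-part detail: (rho, absorb, cond_fix) for a mutant in the
    #: large part and in the small part (identical entries for K_n).
    start_large: tuple[float, float, float] | None = None
    start_small: tuple[float, float, float] | None = None

    def astuple(self) -> tuple[float, float, float]:
        return (self.rho, self.absorb_time, self.cond_fix_time)


class BirthDeathChain:
    """Absorbing birth-death chain on states 0..K with holding probabilities.

    ``up[k]`` and ``down[k]`` are the per-Moran-step probabilities of the
    mutant count moving k -> k+1 and k -> k-1; the remainder is a hold.
    States 0 and K are absorbing.
    """

    def __init__(self, up: np.ndarray, down: np.ndarray):
        up = np.asarray(up, dtype=float)
        down = np.asarray(down, dtype=float)
        if up.shape != down.shape or up.ndim != 1 or up.shape[0] < 3:
            raise GraphError("need matching up/down vectors over at least 3 states")
        if np.any(up < 0) or np.any(down < 0) or np.any(up + down > 1 + 1e-12):
            raise GraphError("invalid transition probabilities")
        if up[0] or down[0] or up[-1] or down[-1]:
            raise GraphError("endpoint states must be absorbing")
        if np.any(up[1:-1] <= 0) or np.any(down[1:-1] <= 0):
            raise GraphError("interior states must communicate with both neighbours")
        self.up = up
        self.down = down
        self.K = up.shape[0] - 1

    def fixation_probabilities(self) -> np.ndarray:
        """rho_k for k = 0..K via the gamma-product formula, in log space."""
        K = self.K
        gamma = self.down[1:K] / self.up[1:K]
        logc = np.concatenate([[0.0], np.cumsum(np.log(gamma))])  # prod_{l<=j} gamma_l
        m = logc.max()
        terms = np.exp(logc - m)
        csum = np.concatenate([[0.0], np.cumsum(terms)])  # csum[k] = sum_{j<k}
        rho = csum / csum[K]
        rho[K] = 1.0
        return rho

    def _solve_interior(self, rhs: np.ndarray) -> np.ndarray:
        """Solve (I - P) x = rhs over interior states 1..K-1 (tridiagonal)."""
        K = self.K
        up, down = self.up[1:K], self.down[1:K]
        ab = np.zeros((3, K - 1))
        ab[0, 1:] = -up[:-1]      # superdiagonal
        ab[1, :] = up + down      # diagonal of I - P
        ab[2, :-1] = -down[1:]    # subdiagonal
        return solve_banded((1, 1), ab, rhs)

    def absorption_times(self) -> np.ndarray:
        """Expected steps to absorption from each state (0 at the endpoints)."""
        t = np.zeros(self.K + 1)
        t[1:self.K] = self._solve_interior(np.ones(self.K - 1))
        return t

    def conditional_fixation_times(self) -> np.ndarray:
        """Expected steps conditional on fixation, via z_k = rho_k tau_k."""
        rho = self.fixation_probabilities()
        tau = np.zeros(self.K + 1)
        z = self._solve_interior(rho[1:self.K])
        tau[1:self.K] = z / rho[1:self.K]
        return tau


def _complete_chain(n: int, r: float) -> BirthDeathChain:
    k = np.arange(n + 1, dtype=float)
    F = r * k + (n - k)
    up = np.zeros(n + 1)
    down = np.zeros(n + 1)
    interior = slice(1, n)
    ki = k[interior]
    up[interior] = (r * ki / F[interior]) * (n - ki) / (n - 1)
    down[interior] = ((n - ki) / F[interior]) * ki / (n - 1)
    return BirthDeathChain(up, down)


def complete_graph_rho(n: int, r: float) -> float:
    """Closed-form fixation probability on K_n: (1 - 1/r) / (1 - 1/r^n)."""
    if n < 2:
        raise GraphError("need n >= 2")
    if r <= 0:
        raise GraphError("need r > 0")
    if abs(r - 1.0) < 1e-14:
        return 1.0 / n
    return (1.0 - 1.0 / r) / (1.0 - r ** (-float(n)))


def complete_graph_stats(n: int, r: float) -> LumpedResult:
    """Exact (rho, absorption time, conditional fixation time) on K_n.

    The probability uses the closed form; the times come from the exact
    birth-death linear systems (not the N log N asymptotics).  All starting
    vertices are equivalent, so no initialization scheme is needed.
    """
    if n < 2:
        raise GraphError("need n >= 2")
    chain = _complete_chain(n, r)
    rho = complete_graph_rho(n, r)
    a1 = float(chain.absorption_times()[1])
    t1 = float(chain.conditional_fixation_times()[1])
    detail = (rho, a1, t1)
    return LumpedResult(rho, a1, t1, start_large=detail, start_small=detail)


# ---------------------------------------------------------------------------
# two-dimensional bipartite chain
# ---------------------------------------------------------------------------


def _bipartite_transient_system(m: int, s: int, loop: float, r: float):
    """Sparse (I - P) over transient states of the (i, j) chain.

    State (i, j): i mutants among the m large-part vertices (each with a
    self-loop of weight ``loop`` and unit edges to every small vertex),
    j mutants among the s small-part vertices (unit edges to every large
    vertex).  Index: i * (s + 1) + j; transient = all but (0,0), (m,s).
    """
    S = s + 1
    n_states = (m + 1) * S
    ids = np.arange(n_states)
    i = ids // S
    j = ids % S
    F = r * (i + j) + (m + s - i - j)
    denom = loop + s  # total out-weight of a large-part vertex

    rows, cols, vals = [], [], []

    def add(mask, target, prob):
        rows.append(ids[mask])
        cols.append(target[mask])
        vals.append(prob[mask])

    with np.errstate(divide="ignore", invalid="ignore"):
        # large-part mutant reproduces onto a resident small vertex: j += 1
        p = (r * i / F) * (s - j) / denom
        add((i > 0) & (j < s), ids + 1, p)
        # large-part resident reproduces onto a mutant small vertex: j -= 1
        p = ((m - i) / F) * j / denom
        add((i < m) & (j > 0), ids - 1, p)
        # small-part mutant reproduces onto a resident large vertex: i += 1
        p = (r * j / F) * (m - i) / m
        add((j > 0) & (i < m), ids + S, p)
        # small-part resident reproduces onto a mutant large vertex: i -= 1
        p = ((s - j) / F) * i / m
        add((j < s) & (i > 0), ids - S, p)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    # diagonal of I - P equals the total move-away probability
    move = np.zeros(n_states)
    np.add.at(move, rows, vals)

    transient = np.ones(n_states, bool)
    transient[0] = False
    transient[-1] = False
    tid = np.cumsum(transient) - 1  # state id -> transient index

    keep = transient[rows] & transient[cols]
    A = sparse.coo_matrix(
        (
            np.concatenate([move[transient], -vals[keep]]),
            (
                np.concatenate([tid[transient], tid[rows[keep]]]),
                np.concatenate([tid[transient], tid[cols[keep]]]),
            ),
        ),
        shape=(n_states - 2, n_states - 2),
    ).tocsc()

    # probability mass flowing straight into the fixation state (m, s)
    to_fix = np.zeros(n_states)
    hits_fix = transient[rows] & (cols == n_states - 1)
    np.add.at(to_fix, rows[hits_fix], vals[hits_fix])
    return A, to_fix[transient], tid


def bipartite_stats(
    m: int,
    s: int,
    selfloop_weight: float,
    r: float,
    init: str = "uniform",
    temperature_include_self_loops: bool = True,
    state_cap: int = DEFAULT_STATE_CAP,
) -> LumpedResult:
    """Exact fixation quantities on a complete bipartite graph, lumped.

    Parameters
    ----------
    m, s : int
        Part sizes, m >= s >= 1; large part carries the self-loops.
    selfloop_weight : float
        Weight of the self-loop on each large-part vertex (0 for the plain
        balanced bipartite graph).
    init : {"uniform", "temperature"}
        How the initial single mutant is placed.  Uniform puts it in the
        large part with probability m/(m+s); temperature weights the parts
        by their summed replacement rates.
    temperature_include_self_loops : bool
        Whether a vertex's own self-loop contributes to its temperature
        (a self-replacement is still a replacement event); set False to
        count only cross-part turnover.
    """
    if s > m or s < 1:
        raise GraphError(f"require m >= s >= 1, got m={m}, s={s}")
    if selfloop_weight < 0:
        raise GraphError("self-loop weight must be >= 0")
    if r <= 0:
        raise GraphError("need r > 0")
    n_states = (m + 1) * (s + 1)
    if n_states > state_cap:
        raise GraphError(f"{n_states} lumped states exceeds cap {state_cap}")

    A, to_fix, tid = _bipartite_transient_system(m, s, float(selfloop_weight), r)
    lu = splu(A)
    rho = lu.solve(to_fix)
    a = lu.solve(np.ones(A.shape[0]))
    z = lu.solve(rho)

    S = s + 1
    idx_large = tid[1 * S + 0]  # state (1, 0)
    idx_small = tid[0 * S + 1]  # state (0, 1)

    rL, rS = float(rho[idx_large]), float(rho[idx_small])
    aL, aS = float(a[idx_large]), float(a[idx_small])
    tL, tS = float(z[idx_large]) / rL, float(z[idx_small]) / rS

    pi_large, pi_small = _part_weights(
        m, s, float(selfloop_weight), init, temperature_include_self_loops
    )
    rho_agg = pi_large * rL + pi_small * rS
    absorb_agg = pi_large * aL + pi_small * aS
    fix_agg = (pi_large * rL * tL + pi_small * rS * tS) / rho_agg
    return LumpedResult(
        rho_agg,
        absorb_agg,
        fix_agg,
        start_large=(rL, aL, tL),
        start_small=(rS, aS, tS),
    )


def _part_weights(
    m: int, s: int, loop: float, init: str, include_loops: bool
) -> tuple[float, float]:
    n = m + s
    if init == "uniform":
        return m / n, s / n
    if init == "temperature":
        # temperature of one large vertex: self-loop share + inflow from the
        # s small vertices (each spreads 1/m over the large part)
        t_large = (loop / (loop + s) if include_loops and loop > 0 else 0.0) + s / m
        # temperature of one small vertex: inflow from the m large vertices
        t_small = m / (loop + s)
        w_large = m * t_large
        w_small = s * t_small
        tot = w_large + w_small
        return w_large / tot, w_small / tot
    raise GraphError(f"unknown initialization scheme {init!r}")


def star_stats(n: int, r: float, init: str = "uniform") -> LumpedResult:
    """Exact fixation quantities on the star S_n (center + n-1 leaves).

    The star is the bipartite chain with a large part of n-1 leaves and a
    single-vertex small part (the center), so this is exactly
    ``bipartite_stats(n - 1, 1, 0, r, init)``.
    """
    if n < 3:
        raise GraphError("star needs n >= 3")
    return bipartite_stats(n - 1, 1, 0.0, r, init=init)
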