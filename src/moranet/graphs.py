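"""Weighted population structures for evolutionary graph theory.

A population of N individuals occupies the vertices of a (possibly weighted,
possibly directed) graph.  Edge weights express the relative preference of a
reproducing individual at vertex u to place its offspring at vertex v; the
per-source normalisation of those weights is the replacement kernel
w(u, v) used by the Moran birth-death process.

This module provides the :class:`WeightedGraph` container, the
:class:`ReplacementKernel`, constructors for the graph families studied in
amplifier/accelerator analyses (complete, star, complete bipartite,
alpha-balanced and alpha-weighted bipartite, cycles, random trees,
Erdos-Renyi graphs, stars/cycles with extra edges), exhaustive enumeration
of small connected graphs up to isomorphism, the analytic census of such
graphs, and graph6 / TSV edge-list I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator

import igraph as _ig
import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GraphError",
    "WeightedGraph",
    "ReplacementKernel",
    "make_complete",
    "make_star",
    "make_complete_bipartite",
    "make_balanced_bipartite",
    "make_weighted_bipartite",
    "make_cycle",
    "make_random_tree",
    "make_erdos_renyi",
    "make_star_plus_edges",
    "make_cycle_plus_edges",
    "enumerate_connected_graphs",
    "count_connected_graphs",
    "read_graph6",
    "write_graph6",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
]


class GraphError(ValueError):
    """Invalid graph construction or graph input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightedGraph:
    """A weighted population structure.

    Parameters
    ----------
    n : int
        Number of vertices (the population size N); vertex ids are
        ``0 .. n-1``.
    edges : dict[tuple[int, int], float]
        Map ``(u, v) -> weight`` with strictly positive weights.  For an
        undirected graph each non-loop edge is stored once with ``u <= v``
        and stands for flow in both directions; self-loops are ``(v, v)``.
    directed : bool
        Whether edges are one-way.
    family : tuple or None
        Optional constructor metadata, e.g. ``("star", 8)`` or
        ``("complete_bipartite", m, s, loop_weight)``.  Used by the lumped
        solvers to recognise structures with within-part symmetry.
    """

    n: int
    edges: dict[tuple[int, int], float]
    directed: bool = False
    family: tuple | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GraphError(f"need at least one vertex, got n={self.n}")
        cleaned: dict[tuple[int, int], float] = {}
        for (u, v), w in self.edges.items():
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise GraphError(f"edge ({u},{v}) outside vertex range [0,{self.n})")
            if not w > 0:
                raise GraphError(f"edge ({u},{v}) has non-positive weight {w}")
            if not self.directed and u > v:
                u, v = v, u
            if (u, v) in cleaned:
                raise GraphError(f"duplicate edge ({u},{v})")
            cleaned[(u, v)] = float(w)
        object.__setattr__(self, "edges", cleaned)
        if self.n > 1 and not self._is_connected():
            kind = "strongly connected" if self.directed else "connected"
            raise GraphError(f"graph (ignoring self-loops) must be {kind}")

    # -- structure ---------------------------------------------------------

    def _is_connected(self) -> bool:
        mat = self.weight_matrix(include_self_loops=False)
        ncomp, _ = connected_components(
            mat, directed=self.directed, connection="strong" if self.directed else "weak"
        )
        return ncomp == 1

    def weight_matrix(self, include_self_loops: bool = True) -> sparse.csr_matrix:
        """Dense weight flow as a sparse matrix; undirected edges in both directions."""
        rows, cols, vals = [], [], []
        for (u, v), w in self.edges.items():
            if u == v:
                if include_self_loops:
                    rows.append(u)
                    cols.append(v)
                    vals.append(w)
                continue
            rows.append(u)
            cols.append(v)
            vals.append(w)
            if not self.directed:
                rows.append(v)
                cols.append(u)
                vals.append(w)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def kernel(self) -> "ReplacementKernel":
        return ReplacementKernel.from_graph(self)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: int) -> int:
        """Number of non-loop neighbours of v (undirected graphs)."""
        return sum(
            1
            for (a, b) in self.edges
            if a != b and (a == v or (b == v and not self.directed) or (self.directed and a == v))
        )

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges)

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.n))
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph | nx.DiGraph, family: tuple | None = None) -> "WeightedGraph":
        directed = g.is_directed()
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = {
            (mapping[u], mapping[v]): float(d.get("weight", 1.0))
            for u, v, d in g.edges(data=True)
        }
        return cls(len(mapping), edges, directed=directed, family=family)


@dataclass(frozen=True)
class ReplacementKernel:
    """Row-stochastic offspring-placement distribution w(u, v).

    ``w(u, v)`` is the probability that an individual reproducing at vertex
    u places its offspring at vertex v.  Rows are the per-source
    normalisation of the graph's edge weights and must sum to one.
    """

    n: int
    matrix: sparse.csr_matrix

    _ROW_SUM_TOL = 1e-12

    def __post_init__(self) -> None:
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.any(np.abs(rows - 1.0) > self._ROW_SUM_TOL):
            worst = float(np.max(np.abs(rows - 1.0)))
            raise GraphError(f"kernel rows must sum to 1 (max deviation {worst:.2e})")
        if self.matrix.shape != (self.n, self.n):
            raise GraphError("kernel shape mismatch")

    @classmethod
    def from_graph(cls, graph: WeightedGraph) -> "ReplacementKernel":
        mat = graph.weight_matrix(include_self_loops=True).tolil()
        out = np.asarray(mat.sum(axis=1)).ravel()
        if np.any(out <= 0):
            raise GraphError("every vertex needs positive out-weight")
        norm = sparse.diags(1.0 / out) @ mat.tocsr()
        norm.sort_indices()
        return cls(graph.n, norm.tocsr())

    def row(self, u: int) -> tuple[np.ndarray, np.ndarray]:
        """Target vertices and probabilities for a reproducer at u."""
        sl = slice(self.matrix.indptr[u], self.matrix.indptr[u + 1])
        return self.matrix.indices[sl], self.matrix.data[sl]

    def w(self, u: int, v: int) -> float:
        return float(self.matrix[u, v])

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


# ---------------------------------------------------------------------------
# named families
# ---------------------------------------------------------------------------


def make_complete(n: int) -> WeightedGraph:
    """Complete graph K_n -- the well-mixed population."""
    if n < 2:
        raise GraphError(f"complete graph needs n >= 2, got {n}")
    edges = {(u, v): 1.0 for u in range(n) for v in range(u + 1, n)}
    return WeightedGraph(n, edges, family=("complete", n))


def make_star(n: int) -> WeightedGraph:
    """Star S_n: vertex 0 is the center, vertices 1..n-1 are leaves."""
    if n < 3:
        raise GraphError(f"star graph needs n >= 3, got {n}")
    edges = {(0, v): 1.0 for v in range(1, n)}
    return WeightedGraph(n, edges, family=("star", n))


def make_complete_bipartite(m: int, s: int, selfloop_weight: float = 0.0) -> WeightedGraph:
    """Complete bipartite graph with parts of sizes m >= s.

    Vertices ``0..m-1`` form the large part, ``m..m+s-1`` the small part.
    Cross edges have weight 1.  ``selfloop_weight`` adds a self-loop of that
    weight to every vertex of the *large* part (the construction used to
    tame the turnover of the large part under temperature initialization).
    """
    if s > m:
        raise GraphError(f"parts swapped: require m >= s, got m={m}, s={s}")
    if s < 1:
        raise GraphError("small part needs at least one vertex")
    if m + s < 2:
        raise GraphError("need at least two vertices in total")
    if selfloop_weight < 0:
        raise GraphError(f"self-loop weight must be >= 0, got {selfloop_weight}")
    edges: dict[tuple[int, int], float] = {}
    for u in range(m):
        for v in range(m, m + s):
            edges[(u, v)] = 1.0
        if selfloop_weight > 0:
            edges[(u, u)] = float(selfloop_weight)
    return WeightedGraph(m + s, edges, family=("complete_bipartite", m, s, float(selfloop_weight)))


def _small_part_size(n_large: int, alpha: float) -> int:
    return max(1, round(n_large ** (1.0 - alpha)))


def make_balanced_bipartite(n_large: int, alpha: float) -> WeightedGraph:
    """alpha-balanced bipartite graph: parts of sizes N and round(N^(1-alpha)).

    The family interpolates between the star (alpha -> 1) and balanced
    complete bipartite graphs; for large N its uniform-initialization
    fixation probability approaches the star limit 1 - 1/r^2 while its
    fixation time grows only like N^(1+alpha) log N.
    """
    if not 0 < alpha < 1:
        raise GraphError(f"alpha must lie in (0, 1), got {alpha}")
    if n_large < 4:
        raise GraphError(f"need n_large >= 4, got {n_large}")
    s = _small_part_size(n_large, alpha)
    if s > n_large:
        raise GraphError("small part exceeds large part")
    g = make_complete_bipartite(n_large, s, 0.0)
    object.__setattr__(g, "family", ("balanced_bipartite", n_large, alpha, s))
    return g


def make_weighted_bipartite(n_large: int, alpha: float) -> WeightedGraph:
    """alpha-weighted bipartite graph: balanced bipartite plus self-loops.

    Each large-part vertex carries a self-loop of weight
    ``N^(1-alpha/2) - N^(1-alpha)`` (exact real value, no rounding) so that
    its total out-weight is about N^(1-alpha/2) and an offspring migrates to
    the small part only with probability about N^(-alpha/2).
    """
    if not 0 < alpha <= 1:
        raise GraphError(f"alpha must lie in (0, 1], got {alpha}")
    if n_large < 4:
        raise GraphError(f"need n_large >= 4, got {n_large}")
    loop = n_large ** (1.0 - alpha / 2.0) - n_large ** (1.0 - alpha)
    if loop <= 0:
        raise GraphError("self-loop weight must be positive")
    s = _small_part_size(n_large, alpha)
    g = make_complete_bipartite(n_large, s, loop)
    object.__setattr__(g, "family", ("weighted_bipartite", n_large, alpha, s, loop))
    return g


def make_cycle(n: int) -> WeightedGraph:
    if n < 3:
        raise GraphError(f"cycle needs n >= 3, got {n}")
    edges = {(v, (v + 1) % n): 1.0 for v in range(n)}
    edges = {(min(u, v), max(u, v)): 1.0 for (u, v) in edges}
    return WeightedGraph(n, edges, family=("cycle", n))


def make_random_tree(n: int, seed: int) -> WeightedGraph:
    """Uniform random labeled tree via a random Prufer sequence."""
    if n < 3:
        raise GraphError(f"random tree needs n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    prufer = [int(x) for x in rng.integers(0, n, size=n - 2)]
    tree = nx.from_prufer_sequence(prufer)
    return WeightedGraph.from_networkx(tree, family=("random_tree", n, seed))


_ER_MAX_RETRIES = 10_000


def make_erdos_renyi(n: int, p: float, seed: int) -> WeightedGraph:
    """G(n, p) conditioned on connectivity by rejection sampling."""
    if n < 3:
        raise GraphError(f"need n >= 3, got {n}")
    if not 0 <= p <= 1:
        raise GraphError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    for _ in range(_ER_MAX_RETRIES):
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if nx.is_connected(g):
            return WeightedGraph.from_networkx(g, family=("erdos_renyi", n, p, seed))
    raise GraphError(
        f"no connected G({n}, {p}) sample in {_ER_MAX_RETRIES} attempts"
    )


def _plus_edges(base: WeightedGraph, k_extra: int, seed: int, family: tuple) -> WeightedGraph:
    if k_extra < 0:
        raise GraphError("k_extra must be >= 0")
    n = base.n
    present = set(base.edges)
    missing = [
        (u, v) for u in range(n) for v in range(u + 1, n) if (u, v) not in present
    ]
    if k_extra > len(missing):
        raise GraphError(f"only {len(missing)} edges can be added, asked for {k_extra}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(missing), size=k_extra, replace=False) if k_extra else []
    edges = dict(base.edges)
    for i in chosen:
        edges[missing[int(i)]] = 1.0
    return WeightedGraph(n, edges, family=family)


def make_star_plus_edges(n: int, k_extra: int, seed: int) -> WeightedGraph:
    return _plus_edges(make_star(n), k_extra, seed, ("star_plus_edges", n, k_extra, seed))


def make_cycle_plus_edges(n: int, k_extra: int, seed: int) -> WeightedGraph:
    return _plus_edges(make_cycle(n), k_extra, seed, ("cycle_plus_edges", n, k_extra, seed))


# ---------------------------------------------------------------------------
# enumeration of small connected graphs
# ---------------------------------------------------------------------------


def _canonical_edges(n: int, edges: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Canonical relabeling of a simple graph (BLISS), as a sorted edge tuple."""
    g = _ig.Graph(n, edges)
    g = g.permute_vertices(g.canonical_permutation())
    return tuple(sorted(tuple(sorted(e)) for e in g.get_edgelist()))


def _unlabeled_graphs(n: int) -> list[tuple[tuple[int, int], ...]]:
    """All simple graphs on n vertices up to isomorphism, as canonical edge tuples.

    Built by vertex augmentation: every class on k vertices arises from some
    class on k-1 vertices by attaching the new vertex to a subset of the old
    ones, so trying all 2^(k-1) attachments of each (k-1)-class and deduping
    by canonical form is exhaustive.
    """
    level: list[tuple[tuple[int, int], ...]] = [()]
    for k in range(2, n + 1):
        seen: set[tuple[tuple[int, int], ...]] = set()
        nxt: list[tuple[tuple[int, int], ...]] = []
        for edges in level:
            base = list(edges)
            for bits in range(1 << (k - 1)):
                ne = base + [(i, k - 1) for i in range(k - 1) if bits >> i & 1]
                key = _canonical_edges(k, ne)
                if key not in seen:
                    seen.add(key)
                    nxt.append(key)
        level = nxt
    return level


def enumerate_connected_graphs(n: int) -> Iterator[WeightedGraph]:
    """Yield one representative per isomorphism class of connected simple
    graphs on n vertices, in a deterministic (sorted canonical-encoding)
    order.

    Practical for n <= 8 (11,117 classes, a few seconds); n = 9 has 261,080
    classes and takes substantially longer.
    """
    if n < 1:
        raise GraphError("n must be >= 1")
    if n == 1:
        yield WeightedGraph(1, {})
        return
    out = []
    for edges in _unlabeled_graphs(n):
        if len(edges) < n - 1:
            continue
        g = _ig.Graph(n, list(edges))
        if g.is_connected():
            out.append(edges)
    out.sort(key=lambda e: (len(e), e))
    for edges in out:
        yield WeightedGraph(n, {e: 1.0 for e in edges})


def _cycle_types(n: int) -> Iterator[list[int]]:
    """Integer partitions of n (cycle types of S_n)."""

    def gen(remaining: int, largest: int, prefix: list[int]) -> Iterator[list[int]]:
        if remaining == 0:
            yield prefix
            return
        for part in range(min(largest, remaining), 0, -1):
            yield from gen(remaining - part, part, prefix + [part])

    yield from gen(n, n, [])


def _count_all_graphs(n: int) -> int:
    """Unlabeled simple graphs on n vertices (Burnside over cycle types)."""
    total = Fraction(0)
    nfact = math.factorial(n)
    for parts in _cycle_types(n):
        # permutations with this cycle type
        counts: dict[int, int] = {}
        for p in parts:
            counts[p] = counts.get(p, 0) + 1
        size = nfact
        for length, mult in counts.items():
            size //= length**mult * math.factorial(mult)
        # edge orbits of such a permutation
        orbits = sum(p // 2 for p in parts)
        orbits += sum(
            math.gcd(parts[i], parts[j])
            for i in range(len(parts))
            for j in range(i + 1, len(parts))
        )
        total += Fraction(size * 2**orbits, nfact)
    assert total.denominator == 1
    return int(total)


def _mobius(n: int) -> int:
    if n == 1:
        return 1
    result, m, p = 1, n, 2
    while p * p <= m:
        if m % p == 0:
            m //= p
            if m % p == 0:
                return 0
            result = -result
        p += 1
    if m > 1:
        result = -result
    return result


def count_connected_graphs(n: int) -> int:
    """Number of isomorphism classes of connected simple graphs on n vertices.

    Computed analytically: Burnside count of all unlabeled graphs for every
    size up to n, then the inverse Euler transform to extract the connected
    ones (1 + sum g_k x^k = prod (1 - x^k)^(-c_k)).
    """
    if n < 1:
        raise GraphError("n must be >= 1")
    g = [Fraction(0)] + [Fraction(_count_all_graphs(k)) for k in range(1, n + 1)]
    # L = log(1 + G) as a power series, exact rational arithmetic
    L = [Fraction(0)] * (n + 1)
    gp = [Fraction(1)] + g[1:]  # coefficients of 1 + G
    # power-series log via L' (1+G) = G'
    for m in range(1, n + 1):
        acc = m * g[m]
        for k in range(1, m):
            acc -= k * L[k] * g[m - k]
        L[m] = acc / m
    b = [m * L[m] for m in range(n + 1)]  # b_m = sum_{d|m} d c_d
    acc = Fraction(0)
    for d in range(1, n + 1):
        if n % d == 0:
            acc += _mobius(n // d) * b[d]
    c_n = acc / n
    assert c_n.denominator == 1
    return int(c_n)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_graph6(graphs: Iterable[WeightedGraph], path: str) -> None:
    """Write unweighted undirected graphs as one graph6 line each."""
    with open(path, "wb") as fh:
        for g in graphs:
            if g.directed:
                raise GraphError("graph6 supports undirected graphs only")
            line = nx.to_graph6_bytes(g.to_networkx(), header=False)
            fh.write(line)


def read_graph6(path: str) -> list[WeightedGraph]:
    out = []
    with open(path, "rb") as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw:
                continue
            g = nx.from_graph6_bytes(raw)
            out.append(WeightedGraph.from_networkx(g))
    return out


def write_edgelist_tsv(graph: WeightedGraph, path: str) -> None:
    """TSV edge list ``source<TAB>target<TAB>weight`` with 0-based ids.

    Undirected graphs are stored with both directions explicit.
    """
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v), w in sorted(graph.edges.items()):
            fh.write(f"{u}\t{v}\t{w!r}\n")
            if not graph.directed and u != v:
                fh.write(f"{v}\t{u}\t{w!r}\n")


def read_edgelist_tsv(path: str, directed: bool = False) -> WeightedGraph:
    pairs: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("source"):
            raise GraphError("expected header 'source\\ttarget\\tweight'")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u_s, v_s, w_s = line.split("\t")
            pairs[(int(u_s), int(v_s))] = float(w_s)
    n = max(max(u, v) for u, v in pairs) + 1
    if directed:
        return WeightedGraph(n, pairs, directed=True)
    edges: dict[tuple[int, int], float] = {}
    for (u, v), w in pairs.items():
        key = (min(u, v), max(u, v))
        if key in edges and abs(edges[key] - w) > 1e-12:
            raise GraphError(f"asymmetric weights for undirected edge {key}")
        edges[key] = w
    return WeightedGraph(n, edges, directed=False)
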