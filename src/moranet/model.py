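"""Model/results front end for Moran dynamics on a population structure.

:class:`MoranProcess` bundles a population structure, a mutant fitness and
an initialization scheme; :meth:`MoranProcess.fit` computes the fixation
quantities with the requested backend and returns a
:class:`FixationResults` object carrying the aggregated estimates, their
uncertainties (for the Monte Carlo backend), per-vertex detail (for the
full-state backend) and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import exact, lumped, metrics, simulate
from .graphs import GraphError, ReplacementKernel, WeightedGraph
from .metrics import InitializationScheme, uniform_init

__all__ = ["MoranProcess", "FixationResults"]

_LUMPABLE = {"complete", "star", "complete_bipartite", "balanced_bipartite", "weighted_bipartite"}


@dataclass(frozen=True)
class FixationResults:
    """Fitted fixation quantities for one (graph, r, initialization).

    ``rho``, ``fix_time`` and ``absorb_time`` are aggregated over the
    initialization scheme; times are in Moran steps.  ``rho_se`` etc. are
    standard errors (NaN for exact backends).  ``per_vertex`` holds the
    full-state :class:`moranet.exact.FixationSolution` when available.
    """

    model: "MoranProcess"
    method: str
    rho: float
    fix_time: float
    absorb_time: float
    rho_se: float = float("nan")
    fix_time_se: float = float("nan")
    absorb_time_se: float = float("nan")
    n_runs: int | None = None
    seed: int | None = None
    per_vertex: exact.FixationSolution | None = None

    def effective_rate(self, mu: float) -> float:
        """Effective rate of evolution at mutation rate mu (1/generations)."""
        return metrics.effective_rate(self.model.n, mu, self.rho, self.fix_time)

    def classify(self, complete_results: "FixationResults | None" = None) -> metrics.ClassificationFlags:
        """Amplifier/suppressor and accelerator/decelerator flags versus the
        complete graph of the same size, fitness and initialization."""
        if complete_results is None:
            complete_results = MoranProcess(
                graph=None, n=self.model.n, r=self.model.r, init=self.model.init, family=("complete", self.model.n)
            ).fit(method="lumped")
        other = complete_results
        if other.model.n != self.model.n or other.model.r != self.model.r:
            raise GraphError("comparison requires identical N and r")
        return metrics.classify_vs_complete(self.rho, self.fix_time, other.rho, other.fix_time)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Moran birth-death fixation results",
            "=" * 46,
            f"{'population size N':<28}{m.n:>18}",
            f"{'mutant fitness r':<28}{m.r:>18.6g}",
            f"{'initialization':<28}{m.init.kind:>18}",
            f"{'backend':<28}{self.method:>18}",
            "-" * 46,
            f"{'fixation probability rho':<28}{self.rho:>18.10g}",
            f"{'fixation time (steps)':<28}{self.fix_time:>18.10g}",
            f"{'absorption time (steps)':<28}{self.absorb_time:>18.10g}",
        ]
        if self.method == "simulate":
            lines += [
                f"{'rho std. error':<28}{self.rho_se:>18.3g}",
                f"{'fix time std. error':<28}{self.fix_time_se:>18.3g}",
                f"{'absorb time std. error':<28}{self.absorb_time_se:>18.3g}",
                f"{'runs':<28}{self.n_runs:>18}",
                f"{'seed':<28}{self.seed:>18}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)


class MoranProcess:
    """Moran birth-death process of a single mutant on a structure.

    Parameters
    ----------
    graph : WeightedGraph or None
        The population structure.  May be None when ``family`` describes a
        lumpable structure (complete / star / bipartite), in which case the
        explicit graph is built lazily only if a non-lumped backend needs it.
    r : float
        Mutant relative fitness (residents have fitness 1).
    init : InitializationScheme
        Where the invading mutant appears (uniform by default).
    """

    def __init__(
        self,
        graph: WeightedGraph | None,
        r: float,
        init: InitializationScheme | None = None,
        n: int | None = None,
        family: tuple | None = None,
    ):
        if r <= 0:
            raise GraphError("need r > 0")
        if graph is None and family is None:
            raise GraphError("provide a graph or a lumpable family")
        self.graph = graph
        self.family = family if family is not None else (graph.family if graph else None)
        self.n = graph.n if graph is not None else int(n if n is not None else self._family_n())
        self.r = float(r)
        self.init = init or uniform_init()

    @classmethod
    def from_edgelist(
        cls, path: str, r: float, init: InitializationScheme | None = None, directed: bool = False
    ) -> "MoranProcess":
        from .graphs import read_edgelist_tsv

        return cls(read_edgelist_tsv(path, directed=directed), r, init=init)

    def _family_n(self) -> int:
        kind = self.family[0]
        if kind in ("complete", "star"):
            return self.family[1]
        if kind == "complete_bipartite":
            return self.family[1] + self.family[2]
        if kind in ("balanced_bipartite", "weighted_bipartite"):
            return self.family[1] + self.family[3]
        raise GraphError(f"cannot infer N for family {self.family!r}")

    def _kernel(self) -> ReplacementKernel:
        if self.graph is None:
            from . import graphs as G

            kind = self.family[0]
            if kind == "complete":
                self.graph = G.make_complete(self.family[1])
            elif kind == "star":
                self.graph = G.make_star(self.family[1])
            elif kind == "complete_bipartite":
                self.graph = G.make_complete_bipartite(*self.family[1:])
            elif kind == "balanced_bipartite":
                self.graph = G.make_balanced_bipartite(self.family[1], self.family[2])
            elif kind == "weighted_bipartite":
                self.graph = G.make_weighted_bipartite(self.family[1], self.family[2])
            else:
                raise GraphError(f"cannot materialise family {self.family!r}")
        return self.graph.kernel()

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        method: str = "auto",
        n_runs: int = 100_000,
        seed: int = 0,
        fast_forward: bool = False,
        **kw,
    ) -> FixationResults:
        """Compute the fixation quantities.

        ``method`` is one of ``"exact"`` (full 2^N chain), ``"lumped"``
        (symmetry-reduced chain; complete/star/bipartite families only),
        ``"simulate"`` (Monte Carlo), or ``"auto"`` which picks lumped when
        the family allows it, exact for small graphs, and simulation
        otherwise.
        """
        if method == "auto":
            if self.family and self.family[0] in _LUMPABLE:
                method = "lumped"
            elif self.n <= exact.DEFAULT_VERTEX_CAP:
                method = "exact"
            else:
                method = "simulate"
        if method == "exact":
            kernel = self._kernel()
            sol = exact.solve_fixation(kernel, self.r, **kw)
            rho, tau, absorb = metrics.aggregate_solution(sol, self.init, kernel)
            return FixationResults(self, "exact", rho, tau, absorb, per_vertex=sol)
        if method == "lumped":
            res = self._fit_lumped()
            return FixationResults(self, "lumped", res.rho, res.cond_fix_time, res.absorb_time)
        if method == "simulate":
            kernel = self._kernel()
            est = simulate.estimate(
                kernel, self.r, self.init, n_runs=n_runs, seed=seed, fast_forward=fast_forward
            )
            return FixationResults(
                self,
                "simulate",
                est.rho_hat,
                est.fix_time_hat,
                est.absorb_time_hat,
                rho_se=est.rho_se,
                fix_time_se=est.fix_time_se,
                absorb_time_se=est.absorb_time_se,
                n_runs=est.n_runs,
                seed=est.seed,
            )
        raise GraphError(f"unknown method {method!r}")

    def _fit_lumped(self) -> lumped.LumpedResult:
        fam = self.family
        if not fam or fam[0] not in _LUMPABLE:
            raise GraphError(f"no lumped solver for family {fam!r}")
        init = self.init.kind
        if init == "point":
            raise GraphError("lumped backend supports uniform/temperature initialization")
        incl = self.init.include_self_loops
        kind = fam[0]
        if kind == "complete":
            return lumped.complete_graph_stats(fam[1], self.r)
        if kind == "star":
            return lumped.star_stats(fam[1], self.r, init=init)
        if kind == "complete_bipartite":
            m, s, loop = fam[1], fam[2], fam[3]
        elif kind == "balanced_bipartite":
            m, s, loop = fam[1], fam[3], 0.0
        else:  # weighted_bipartite: (kind, n_large, alpha, s, loop)
            m, s, loop = fam[1], fam[3], fam[4]
        return lumped.bipartite_stats(
            m, s, loop, self.r, init=init, temperature_include_self_loops=incl
        )

    # -- simulation convenience -------------------------------------------

    def simulate_trajectory(self, start_vertices, seed: int, **kw) -> tuple[bool, int]:
        return simulate.simulate_once(self._kernel(), self.r, start_vertices, seed, **kw)

    def __repr__(self) -> str:
        fam = f", family={self.family!r}" if self.family else ""
        return f"MoranProcess(n={self.n}, r={self.r}, init={self.init.kind!r}{fam})"
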