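"""Initialization schemes, aggregation, and tradeoff analytics.

A new mutant can arise spontaneously -- at a vertex chosen uniformly at
random ("uniform initialization") -- or during reproduction, at a vertex
chosen proportionally to its replacement rate, the *temperature*
t(v) = (1/N) sum_u w(u, v) ("temperature initialization").  This module
turns per-starting-vertex fixation quantities into scheme-aggregated ones,
classifies structures against the well-mixed population (amplifier /
suppressor, accelerator / decelerator), extracts Pareto fronts of the
probability-time tradeoff, evaluates the absorption-time lower bound
(rho/r) N log N, and computes the effective rate of evolution
1 / (t1 + t2) with t1 = 1/(N mu rho) and t2 = tau/N generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exact import FixationSolution
from .graphs import GraphError, ReplacementKernel

__all__ = [
    "InitializationScheme",
    "uniform_init",
    "temperature_init",
    "point_init",
    "temperature",
    "aggregate_solution",
    "classify_vs_complete",
    "ClassificationFlags",
    "TradeoffRecord",
    "pareto_front",
    "effective_rate",
    "absorption_lower_bound",
]

_TIE_TOL = 1e-10
_DOMINANCE_TOL = 1e-12


def temperature(kernel: ReplacementKernel, include_self_loops: bool = True) -> np.ndarray:
    """Replacement rate t(v) = (1/N) sum_u w(u, v) for every vertex.

    Self-loop contributions w(v, v) are included by default (a
    self-replacement is a replacement event); pass
    ``include_self_loops=False`` to count only turnover caused by other
    vertices.  With self-loops included the temperatures sum to exactly 1.
    """
    mat = kernel.matrix
    t = np.asarray(mat.sum(axis=0)).ravel() / kernel.n
    if not include_self_loops:
        t = t - mat.diagonal() / kernel.n
        total = t.sum()
        if total <= 0:
            raise GraphError("no cross-vertex replacement mass")
        t = t / total
    return t


@dataclass(frozen=True)
class InitializationScheme:
    """Mutant-placement distribution over vertices."""

    kind: str
    include_self_loops: bool = True
    vertex: int | None = None

    def distribution(self, kernel: ReplacementKernel) -> np.ndarray:
        if self.kind == "uniform":
            return np.full(kernel.n, 1.0 / kernel.n)
        if self.kind == "temperature":
            return temperature(kernel, include_self_loops=self.include_self_loops)
        if self.kind == "point":
            pi = np.zeros(kernel.n)
            pi[self.vertex] = 1.0
            return pi
        raise GraphError(f"unknown initialization scheme {self.kind!r}")


def uniform_init() -> InitializationScheme:
    return InitializationScheme("uniform")


def temperature_init(include_self_loops: bool = True) -> InitializationScheme:
    return InitializationScheme("temperature", include_self_loops=include_self_loops)


def point_init(vertex: int) -> InitializationScheme:
    return InitializationScheme("point", vertex=vertex)


def aggregate_solution(
    sol: FixationSolution,
    scheme: InitializationScheme | np.ndarray,
    kernel: ReplacementKernel | None = None,
    tau_mode: str = "fixation_weighted",
) -> tuple[float, float, float]:
    """Aggregate per-vertex quantities into (rho, cond_fix_time, absorb_time).

    With placement distribution pi,

    * ``rho = sum_v pi(v) rho_v`` and ``absorb = sum_v pi(v) a_v`` are plain
      mixtures;
    * the conditional fixation time is by default the fixation-weighted
      mixture ``sum_v pi(v) rho_v tau_v / sum_v pi(v) rho_v`` -- the expected
      number of steps of the trajectories that fix, when the starting vertex
      is itself random.  ``tau_mode="plain"`` gives the unweighted mixture
      ``sum_v pi(v) tau_v`` instead.
    """
    if isinstance(scheme, InitializationScheme):
        if kernel is None:
            raise GraphError("aggregating a non-uniform scheme needs the kernel")
        pi = scheme.distribution(kernel)
    else:
        pi = np.asarray(scheme, dtype=float)
    if pi.shape != sol.rho.shape:
        raise GraphError("scheme and solution are over different vertex sets")
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise GraphError("placement distribution must be a probability vector")
    rho = float(pi @ sol.rho)
    absorb = float(pi @ sol.absorb_time)
    if rho <= 0:
        raise GraphError("conditional fixation time undefined: fixation impossible")
    if tau_mode == "fixation_weighted":
        tau = float(pi @ (sol.rho * sol.cond_fix_time)) / rho
    elif tau_mode == "plain":
        tau = float(pi @ sol.cond_fix_time)
    else:
        raise GraphError(f"unknown tau_mode {tau_mode!r}")
    return rho, tau, absorb


@dataclass(frozen=True)
class ClassificationFlags:
    amplifier: bool
    suppressor: bool
    accelerator: bool
    decelerator: bool


def classify_vs_complete(
    rho_g: float,
    fix_time_g: float,
    rho_complete: float,
    fix_time_complete: float,
    tol: float = _TIE_TOL,
) -> ClassificationFlags:
    """Compare a structure's aggregated (rho, tau) against the well-mixed
    population of the same size, fitness and initialization.

    Amplifiers increase the fixation probability, suppressors decrease it;
    accelerators shorten the conditional fixation time, decelerators
    lengthen it.  Differences within ``tol`` count as ties (no flag).
    """
    return ClassificationFlags(
        amplifier=rho_g > rho_complete + tol,
        suppressor=rho_g < rho_complete - tol,
        accelerator=fix_time_g < fix_time_complete - tol,
        decelerator=fix_time_g > fix_time_complete + tol,
    )


@dataclass(frozen=True)
class TradeoffRecord:
    """One structure's point in the probability-time tradeoff plane."""

    graph_id: str
    n: int
    r: float
    scheme: str
    rho: float
    fix_time: float
    absorb_time: float
    flags: ClassificationFlags | None = None
    on_pareto_front: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise GraphError(f"rho must lie in (0, 1), got {self.rho}")
        if self.fix_time <= 0 or self.absorb_time <= 0:
            raise GraphError("times must be positive")


def pareto_front(records: list[TradeoffRecord], tol: float = _DOMINANCE_TOL) -> list[TradeoffRecord]:
    """Non-dominated records under (maximize rho, minimize fixation time).

    A record dominates another if its rho is >= and its fixation time <=
    with at least one strict inequality (beyond ``tol``); ties are kept.
    """
    if not records:
        return []
    schemes = {(rec.scheme, rec.r) for rec in records}
    if len(schemes) > 1:
        raise GraphError("Pareto front requires a single (scheme, r) combination")
    front = []
    for a in records:
        dominated = any(
            (b.rho >= a.rho - tol and b.fix_time <= a.fix_time + tol)
            and (b.rho > a.rho + tol or b.fix_time < a.fix_time - tol)
            for b in records
        )
        if not dominated:
            front.append(a)
    return front


def effective_rate(n: int, mu: float, rho: float, fix_time_steps: float) -> float:
    """Effective rate of evolution 1/(t1 + t2), in inverse generations.

    t1 = 1/(N mu rho) is the expected number of generations to produce a
    mutant that eventually fixates; t2 = tau/N converts the fixation time
    tau (Moran steps) into generations.
    """
    if n < 1 or mu <= 0 or rho <= 0 or fix_time_steps <= 0:
        raise GraphError("all rate parameters must be positive")
    t1 = 1.0 / (n * mu * rho)
    t2 = fix_time_steps / n
    return 1.0 / (t1 + t2)


def absorption_lower_bound(rho: float, r: float, n: int) -> float:
    """Universal lower bound (rho/r) N ln N on the absorption time.

    Holds for the Moran process on every connected graph; it implies that
    no amplifier (nor any structure whose fixation probability stays
    bounded away from zero) can beat the well-mixed N log N absorption
    timescale asymptotically.
    """
    if not 0 < rho <= 1:
        raise GraphError("rho must lie in (0, 1]")
    if r <= 0 or n < 2:
        raise GraphError("need r > 0 and n >= 2")
    return (rho / r) * n * np.log(n)
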