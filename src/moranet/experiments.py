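"""Experiment drivers: exhaustive small-graph sweeps, effective-rate
curves, and family tradeoff tables.

These reproduce, at desk scale, the three computational studies of the
probability-time tradeoff: (i) solving the Moran process exactly for every
connected graph of a small size and extracting the Pareto front of
(fixation probability, fixation time); (ii) effective-rate-of-evolution
curves across mutation rates for complete, star, alpha-balanced and
alpha-weighted structures; (iii) Monte Carlo tradeoff estimates for graph
families (trees, Erdos-Renyi, cycles/stars with extra edges, bipartite) at
a fixed population size.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import exact, graphs, lumped, metrics, simulate
from .graphs import GraphError, WeightedGraph
from .metrics import (
    InitializationScheme,
    TradeoffRecord,
    classify_vs_complete,
    pareto_front,
    temperature_init,
    uniform_init,
)

__all__ = [
    "run_sweep",
    "run_rate_curves",
    "run_family_tradeoff",
    "parse_structure",
    "bipartite_parts_for_total",
    "sweep_to_frame",
]


def _scheme(name: str | InitializationScheme) -> InitializationScheme:
    if isinstance(name, InitializationScheme):
        return name
    if name == "uniform":
        return uniform_init()
    if name == "temperature":
        return temperature_init()
    raise GraphError(f"unknown scheme {name!r}")


def _graph_id(g: WeightedGraph) -> str:
    import networkx as nx

    return nx.to_graph6_bytes(g.to_networkx(), header=False).decode().strip()


def run_sweep(
    n: int,
    r: float,
    scheme: str | InitializationScheme = "uniform",
    graphs_iter: Iterable[WeightedGraph] | None = None,
) -> list[TradeoffRecord]:
    """Solve the Moran process exactly for every connected graph of size n.

    Returns one :class:`TradeoffRecord` per isomorphism class with
    amplifier/accelerator flags against K_n and Pareto-front marks.  Pass
    ``graphs_iter`` to sweep a subset (e.g. a stratified sample) instead of
    the full enumeration.
    """
    scheme = _scheme(scheme)
    complete = graphs.make_complete(n)
    kernel_K = complete.kernel()
    sol_K = exact.solve_fixation(kernel_K, r)
    rho_K, tau_K, _ = metrics.aggregate_solution(sol_K, scheme, kernel_K)

    records = []
    source = graphs_iter if graphs_iter is not None else graphs.enumerate_connected_graphs(n)
    for g in source:
        kernel = g.kernel()
        sol = exact.solve_fixation(kernel, r)
        rho, tau, absorb = metrics.aggregate_solution(sol, scheme, kernel)
        records.append(
            TradeoffRecord(
                graph_id=_graph_id(g),
                n=n,
                r=r,
                scheme=scheme.kind,
                rho=rho,
                fix_time=tau,
                absorb_time=absorb,
                flags=classify_vs_complete(rho, tau, rho_K, tau_K),
            )
        )
    front_ids = {id(rec) for rec in pareto_front(records)}
    records = [
        TradeoffRecord(
            rec.graph_id, rec.n, rec.r, rec.scheme, rec.rho, rec.fix_time,
            rec.absorb_time, rec.flags, on_pareto_front=id(rec) in front_ids,
        )
        for rec in records
    ]
    return records


def sweep_to_frame(records: Sequence[TradeoffRecord]) -> pd.DataFrame:
    rows = [
        {
            "graph_id": rec.graph_id,
            "n": rec.n,
            "r": rec.r,
            "scheme": rec.scheme,
            "rho": rec.rho,
            "fix_time_steps": rec.fix_time,
            "absorb_time_steps": rec.absorb_time,
            "is_amplifier": rec.flags.amplifier if rec.flags else None,
            "is_accelerator": rec.flags.accelerator if rec.flags else None,
            "on_pareto_front": rec.on_pareto_front,
        }
        for rec in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structures and part-size conventions
# ---------------------------------------------------------------------------


def bipartite_parts_for_total(total: int, alpha: float) -> tuple[int, int]:
    """Part sizes (m, s) with s = round(m^(1-alpha)) and m + s closest to
    ``total`` (ties resolved toward the smaller population)."""
    best = None
    for m in range(1, total + 1):
        s = max(1, round(m ** (1.0 - alpha)))
        if s > m:
            continue
        diff = abs(m + s - total)
        if best is None or diff < best[0]:
            best = (diff, m, s)
    if best is None:
        raise GraphError(f"no bipartite split for total {total}")
    return best[1], best[2]


def parse_structure(token: str) -> tuple[str, float | None]:
    """Parse a structure token: ``complete``, ``star``, ``balanced:0.5``,
    ``weighted:0.25``."""
    if token in ("complete", "star"):
        return token, None
    if ":" in token:
        kind, alpha_s = token.split(":", 1)
        if kind in ("balanced", "weighted"):
            alpha = float(alpha_s)
            if not 0 < alpha <= 1:
                raise GraphError(f"alpha out of range in {token!r}")
            return kind, alpha
    raise GraphError(f"unknown structure token {token!r}")


def _structure_stats(
    token: str,
    n_total: int,
    r: float,
    scheme: InitializationScheme,
    part_convention: str = "total",
) -> tuple[float, float, float]:
    """(rho, fix_time, absorb_time) for a named structure via lumped solves."""
    kind, alpha = parse_structure(token)
    init = scheme.kind
    if kind == "complete":
        res = lumped.complete_graph_stats(n_total, r)
    elif kind == "star":
        res = lumped.star_stats(n_total, r, init=init)
    else:
        if part_convention == "total":
            m, s = bipartite_parts_for_total(n_total, alpha)
        elif part_convention == "large-part":
            m = n_total
            s = max(1, round(m ** (1.0 - alpha)))
        else:
            raise GraphError(f"unknown part convention {part_convention!r}")
        loop = 0.0
        if kind == "weighted":
            loop = m ** (1.0 - alpha / 2.0) - m ** (1.0 - alpha)
        res = lumped.bipartite_stats(
            m, s, loop, r, init=init,
            temperature_include_self_loops=scheme.include_self_loops,
        )
    return res.rho, res.cond_fix_time, res.absorb_time


def run_rate_curves(
    structures: Sequence[str],
    n: int,
    r: float,
    mu_grid: Sequence[float],
    scheme: str | InitializationScheme = "uniform",
    part_convention: str = "total",
) -> pd.DataFrame:
    """Effective rate of evolution across mutation rates.

    For each structure token the exact lumped (rho, tau) is computed once;
    the table reports the effective rate 1/(t1 + t2) at every mu together
    with the rate relative to the complete graph of the same total size.
    """
    scheme = _scheme(scheme)
    mu_grid = list(mu_grid)
    if not mu_grid or not structures:
        raise GraphError("need non-empty structure and mu grids")
    stats = {tok: _structure_stats(tok, n, r, scheme, part_convention) for tok in structures}
    if "complete" in stats:
        rho_K, tau_K, _ = stats["complete"]
    else:
        rho_K, tau_K, _ = _structure_stats("complete", n, r, scheme, part_convention)
    rows = []
    for tok in structures:
        rho, tau, _absorb = stats[tok]
        for mu in mu_grid:
            rate = metrics.effective_rate(n, mu, rho, tau)
            rate_K = metrics.effective_rate(n, mu, rho_K, tau_K)
            rows.append(
                {
                    "structure": tok,
                    "n": n,
                    "r": r,
                    "scheme": scheme.kind,
                    "mu": mu,
                    "rho": rho,
                    "fix_time_steps": tau,
                    "effective_rate": rate,
                    "relative_rate": rate / rate_K,
                }
            )
    return pd.DataFrame(rows)


def log_mu_grid(mu_from: float, mu_to: float, per_decade: int) -> list[float]:
    n_points = int(round(math.log10(mu_to / mu_from) * per_decade)) + 1
    return list(np.logspace(math.log10(mu_from), math.log10(mu_to), n_points))


# ---------------------------------------------------------------------------
# family tradeoff (Monte Carlo with exact cross-checks)
# ---------------------------------------------------------------------------


def _family_graph(spec: dict, n: int, seed: int) -> WeightedGraph:
    kind = spec["kind"]
    if kind == "tree":
        return graphs.make_random_tree(n, seed)
    if kind == "erdos_renyi":
        return graphs.make_erdos_renyi(n, spec.get("p", 2 * math.log(n) / n), seed)
    if kind == "cycle":
        return graphs.make_cycle(n)
    if kind == "cycle_plus_edges":
        return graphs.make_cycle_plus_edges(n, spec.get("k_extra", 3), seed)
    if kind == "star":
        return graphs.make_star(n)
    if kind == "star_plus_edges":
        return graphs.make_star_plus_edges(n, spec.get("k_extra", 3), seed)
    if kind == "complete":
        return graphs.make_complete(n)
    if kind == "balanced_bipartite":
        m, s = bipartite_parts_for_total(n, spec["alpha"])
        return graphs.make_complete_bipartite(m, s, 0.0)
    if kind == "weighted_bipartite":
        m, s = bipartite_parts_for_total(n, spec["alpha"])
        loop = m ** (1.0 - spec["alpha"] / 2.0) - m ** (1.0 - spec["alpha"])
        return graphs.make_complete_bipartite(m, s, loop)
    raise GraphError(f"unknown family {kind!r}")


def run_family_tradeoff(
    n: int,
    r: float,
    scheme: str | InitializationScheme,
    families: Sequence[dict],
    n_runs: int = 10_000,
    seed: int = 0,
    fast_forward: bool = True,
) -> pd.DataFrame:
    """Monte Carlo (rho, tau) estimates for selected graph families.

    Bipartite families are additionally solved exactly by the lumped chain,
    reported in the ``rho_exact`` / ``fix_time_exact`` columns.
    """
    scheme = _scheme(scheme)
    rows = []
    for i, spec in enumerate(families):
        g = _family_graph(spec, n, seed + 1000 * i)
        est = simulate.estimate(
            g, r, scheme, n_runs=n_runs, seed=seed + 1000 * i, fast_forward=fast_forward
        )
        row = {
            "family": spec["kind"],
            "params": ";".join(f"{k}={v}" for k, v in spec.items() if k != "kind"),
            "n": g.n,
            "r": r,
            "scheme": scheme.kind,
            "n_runs": n_runs,
            "seed": seed + 1000 * i,
            "rho_hat": est.rho_hat,
            "rho_se": est.rho_se,
            "fix_time_hat": est.fix_time_hat,
            "fix_time_se": est.fix_time_se,
            "absorb_time_hat": est.absorb_time_hat,
            "absorb_time_se": est.absorb_time_se,
            "rho_exact": np.nan,
            "fix_time_exact": np.nan,
        }
        if g.family and g.family[0] == "complete_bipartite":
            m, s, loop = g.family[1], g.family[2], g.family[3]
            res = lumped.bipartite_stats(
                m, s, loop, r, init=scheme.kind,
                temperature_include_self_loops=scheme.include_self_loops,
            )
            row["rho_exact"] = res.rho
            row["fix_time_exact"] = res.cond_fix_time
        elif g.family and g.family[0] == "complete":
            res = lumped.complete_graph_stats(n, r)
            row["rho_exact"] = res.rho
            row["fix_time_exact"] = res.cond_fix_time
        elif g.family and g.family[0] == "star":
            res = lumped.star_stats(n, r, init=scheme.kind)
            row["rho_exact"] = res.rho
            row["fix_time_exact"] = res.cond_fix_time
        rows.append(row)
    return pd.DataFrame(rows)
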