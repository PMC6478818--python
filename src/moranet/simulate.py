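"""Seeded Monte Carlo simulation of the Moran birth-death process.

For populations beyond the reach of the exact solvers, fixation
probabilities and times are estimated by simulating independent invasion
trajectories.  Each Moran step draws a reproducer proportionally to fitness
(two-level scheme: mutant pool vs resident pool by aggregate fitness, then
uniform within the pool) and places the offspring according to the
replacement kernel.  Step counts include no-change events (same-type
replacements and self-loops); an optional fast-forward mode samples the
number of consecutive no-change steps from the geometric distribution
instead of iterating them, which is distributionally exact and pays off on
self-loop-heavy structures.

Runs are reproducible: per-run seeds are derived from the master seed by a
counter scheme, so the same (graph, r, init, seed, n_runs) always yields
the identical estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .graphs import GraphError, ReplacementKernel, WeightedGraph
from .metrics import InitializationScheme, uniform_init

__all__ = ["SimulationEstimate", "simulate_once", "estimate", "sample_reproducers"]

DEFAULT_STEP_CAP = 10_000_000_000


@dataclass(frozen=True)
class SimulationEstimate:
    """Monte Carlo estimates with run-level standard errors."""

    n_runs: int
    seed: int
    rho_hat: float
    rho_se: float
    fix_time_hat: float
    fix_time_se: float
    absorb_time_hat: float
    absorb_time_se: float
    n_fixed: int

    @property
    def se_defined(self) -> bool:
        return self.n_runs > 1 and 0 < self.n_fixed


@njit(cache=True)
def _pick_reproducer(is_mut, mut_list, res_list, k, n, r):  # pragma: no cover
    total = r * k + (n - k)
    if np.random.random() * total < r * k:
        return mut_list[np.random.randint(k)]
    return res_list[np.random.randint(n - k)]


@njit(cache=True)
def _sample_reproducers_core(n, r, mut_mask, n_samples, seed):  # pragma: no cover
    np.random.seed(seed)
    is_mut = mut_mask.copy()
    mut_list = np.empty(n, np.int64)
    res_list = np.empty(n, np.int64)
    k = 0
    nr = 0
    for v in range(n):
        if is_mut[v]:
            mut_list[k] = v
            k += 1
        else:
            res_list[nr] = v
            nr += 1
    counts = np.zeros(n, np.int64)
    for _ in range(n_samples):
        u = _pick_reproducer(is_mut, mut_list, res_list, k, n, r)
        counts[u] += 1
    return counts


@njit(cache=True)
def _run_once(indptr, indices, cumw, n, r, start_mask, seed, fast_forward, step_cap):  # pragma: no cover
    """One trajectory; returns (fixed, steps) or steps = -1 on cap overrun."""
    np.random.seed(seed)
    is_mut = start_mask.copy()
    mut_list = np.empty(n, np.int64)
    res_list = np.empty(n, np.int64)
    pos = np.empty(n, np.int64)  # position of v in its current list
    k = 0
    nr = 0
    for v in range(n):
        if is_mut[v]:
            pos[v] = k
            mut_list[k] = v
            k += 1
        else:
            pos[v] = nr
            res_list[nr] = v
            nr += 1
    steps = 0
    while 0 < k < n:
        if fast_forward:
            # probability that the next step changes the configuration
            total = r * k + (n - k)
            p_change = 0.0
            for u in range(n):
                fu = r if is_mut[u] else 1.0
                for e in range(indptr[u], indptr[u + 1]):
                    v = indices[e]
                    if is_mut[v] != is_mut[u]:
                        w = cumw[e] - (cumw[e - 1] if e > indptr[u] else 0.0)
                        p_change += fu / total * w
            # held steps ~ Geometric(p_change), counting the changing step too
            u01 = np.random.random()
            if p_change >= 1.0 or u01 <= 0.0:
                held = 0
            else:
                held = int(math.floor(math.log(u01) / math.log(1.0 - p_change)))
            steps += held + 1
            if steps > step_cap:
                return False, np.int64(-1)
            # sample the changing (u, v) event proportionally to f(u) w(u,v)
            x = np.random.random() * p_change
            acc = 0.0
            flip_v = -1
            last_cross = -1
            for u in range(n):
                fu = r if is_mut[u] else 1.0
                for e in range(indptr[u], indptr[u + 1]):
                    v = indices[e]
                    if is_mut[v] != is_mut[u]:
                        last_cross = v
                        w = cumw[e] - (cumw[e - 1] if e > indptr[u] else 0.0)
                        acc += fu / total * w
                        if acc >= x:
                            flip_v = v
                            break
                if flip_v >= 0:
                    break
            if flip_v < 0:  # numerical corner: take the last cross-type target
                flip_v = last_cross
            v = flip_v
        else:
            u = _pick_reproducer(is_mut, mut_list, res_list, k, n, r)
            # offspring target by inverse CDF over the kernel row of u
            x = np.random.random()
            v = indices[indptr[u + 1] - 1]
            for e in range(indptr[u], indptr[u + 1]):
                if x < cumw[e]:
                    v = indices[e]
                    break
            steps += 1
            if steps > step_cap:
                return False, np.int64(-1)
            if is_mut[v] == is_mut[u]:
                continue
        # flip vertex v to the reproducer's type
        if is_mut[v]:
            # mutant -> resident
            is_mut[v] = False
            last = mut_list[k - 1]
            mut_list[pos[v]] = last
            pos[last] = pos[v]
            k -= 1
            res_list[nr] = v
            pos[v] = nr
            nr += 1
        else:
            is_mut[v] = True
            last = res_list[nr - 1]
            res_list[pos[v]] = last
            pos[last] = pos[v]
            nr -= 1
            mut_list[k] = v
            pos[v] = k
            k += 1
    return k == n, np.int64(steps)


def _row_cumulative(kernel: ReplacementKernel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mat = kernel.matrix
    cumw = mat.data.copy()
    for u in range(kernel.n):
        sl = slice(mat.indptr[u], mat.indptr[u + 1])
        cumw[sl] = np.cumsum(mat.data[sl])
        cumw[mat.indptr[u + 1] - 1] = 1.0 + 1e-15  # guard the last bin
    return mat.indptr.astype(np.int64), mat.indices.astype(np.int64), cumw


def simulate_once(
    kernel: ReplacementKernel,
    r: float,
    start_vertices,
    seed: int,
    fast_forward: bool = False,
    step_cap: int = DEFAULT_STEP_CAP,
) -> tuple[bool, int]:
    """Run a single trajectory from the given mutant set to absorption."""
    if r <= 0:
        raise GraphError("need r > 0")
    n = kernel.n
    mask = np.zeros(n, np.bool_)
    for v in start_vertices:
        mask[v] = True
    k = int(mask.sum())
    if k == 0 or k == n:
        raise GraphError("starting configuration is absorbing")
    indptr, indices, cumw = _row_cumulative(kernel)
    fixed, steps = _run_once(
        indptr, indices, cumw, n, float(r), mask, np.uint32(seed), fast_forward, step_cap
    )
    if steps < 0:
        raise GraphError(f"trajectory exceeded the step cap of {step_cap}")
    return bool(fixed), int(steps)


def estimate(
    graph: WeightedGraph | ReplacementKernel,
    r: float,
    init: InitializationScheme | None = None,
    n_runs: int = 100_000,
    seed: int = 0,
    fast_forward: bool = False,
    step_cap: int = DEFAULT_STEP_CAP,
) -> SimulationEstimate:
    """Estimate (rho, fixation time, absorption time) from independent runs.

    The starting vertex of each run is drawn from the initialization
    scheme; each run receives its own RNG stream derived from ``seed`` and
    the run counter.  Fixation-time statistics are over fixing runs only.
    """
    if n_runs < 1:
        raise GraphError("need n_runs >= 1")
    kernel = graph.kernel() if isinstance(graph, WeightedGraph) else graph
    init = init or uniform_init()
    pi = init.distribution(kernel)
    master = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    starts = master.choice(kernel.n, size=n_runs, p=pi)
    run_seeds = master.integers(0, 2**32, size=n_runs, dtype=np.uint64).astype(np.uint32)
    indptr, indices, cumw = _row_cumulative(kernel)

    fixed = np.zeros(n_runs, np.bool_)
    steps = np.zeros(n_runs, np.int64)
    mask = np.zeros(kernel.n, np.bool_)
    for i in range(n_runs):
        mask[:] = False
        mask[starts[i]] = True
        ok, st = _run_once(
            indptr, indices, cumw, kernel.n, float(r), mask, run_seeds[i], fast_forward, step_cap
        )
        if st < 0:
            raise GraphError(f"run {i} exceeded the step cap of {step_cap}")
        fixed[i] = ok
        steps[i] = st

    n_fixed = int(fixed.sum())
    rho_hat = n_fixed / n_runs
    rho_se = math.sqrt(rho_hat * (1 - rho_hat) / n_runs) if n_runs > 1 else math.nan
    absorb_hat = float(steps.mean())
    absorb_se = float(steps.std(ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else math.nan
    if n_fixed > 0:
        fix_steps = steps[fixed]
        fix_hat = float(fix_steps.mean())
        fix_se = (
            float(fix_steps.std(ddof=1) / math.sqrt(n_fixed)) if n_fixed > 1 else math.nan
        )
    else:
        fix_hat = math.nan
        fix_se = math.nan
    return SimulationEstimate(
        n_runs=n_runs,
        seed=seed,
        rho_hat=rho_hat,
        rho_se=rho_se,
        fix_time_hat=fix_hat,
        fix_time_se=fix_se,
        absorb_time_hat=absorb_hat,
        absorb_time_se=absorb_se,
        n_fixed=n_fixed,
    )


def sample_reproducers(
    kernel: ReplacementKernel, r: float, mutant_vertices, n_samples: int, seed: int
) -> np.ndarray:
    """Frequency of each vertex being picked to reproduce in a frozen
    configuration -- exposes the simulator's fitness-proportional sampling
    for validation."""
    n = kernel.n
    mask = np.zeros(n, np.bool_)
    for v in mutant_vertices:
        mask[v] = True
    if mask.all() or not mask.any():
        raise GraphError("configuration must contain both types")
    return _sample_reproducers_core(n, float(r), mask, n_samples, np.uint32(seed))
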