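"""Temperatures, aggregation, effective rate, Pareto front, lower bound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moranet as mn
from moranet.exact import MutantConfiguration, step_distribution
from moranet.graphs import GraphError
from moranet.metrics import TradeoffRecord, pareto_front


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------


def test_complete_graph_is_isothermal():
    t = mn.temperature(mn.make_complete(7).kernel())
    assert np.allclose(t, 1 / 7, atol=1e-14)


def test_star_temperatures():
    t = mn.temperature(mn.make_star(8).kernel())
    assert t[0] == pytest.approx(7 / 8)       # every leaf reproduces onto the center
    assert np.allclose(t[1:], 1 / 56)         # center spreads 1/7 over 8 vertices' worth


def test_temperatures_sum_to_one(small_graph_corpus):
    for g in small_graph_corpus:
        assert mn.temperature(g.kernel()).sum() == pytest.approx(1.0, abs=1e-12)


def test_temperature_excluding_self_loops():
    g = mn.make_complete_bipartite(4, 2, selfloop_weight=3.0)
    k = g.kernel()
    t_in = mn.temperature(k, include_self_loops=True)
    t_ex = mn.temperature(k, include_self_loops=False)
    assert t_ex.sum() == pytest.approx(1.0)
    # removing self-loops shifts initialization mass toward the small part
    assert t_ex[4] > t_in[4]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_point_mass_aggregation_is_identity():
    g = mn.make_star(6)
    k = g.kernel()
    sol = mn.solve_fixation(k, 1.1)
    for v in (0, 3):
        rho, tau, absorb = mn.aggregate_solution(sol, mn.point_init(v), k)
        assert rho == pytest.approx(sol.rho[v])
        assert tau == pytest.approx(sol.cond_fix_time[v])
        assert absorb == pytest.approx(sol.absorb_time[v])


def test_regular_graph_schemes_coincide():
    g = mn.make_cycle(7)
    k = g.kernel()
    sol = mn.solve_fixation(k, 1.2)
    assert mn.aggregate_solution(sol, mn.uniform_init(), k) == pytest.approx(
        mn.aggregate_solution(sol, mn.temperature_init(), k)
    )


def test_neutral_uniform_rho_is_one_over_n():
    g = mn.make_star_plus_edges(7, 2, seed=4)
    k = g.kernel()
    sol = mn.solve_fixation(k, 1.0)
    rho, _, _ = mn.aggregate_solution(sol, mn.uniform_init(), k)
    assert rho == pytest.approx(1 / 7, abs=1e-10)


def test_uniform_aggregation_is_plain_mean_for_rho_and_absorb():
    g = mn.make_complete_bipartite(5, 2)
    k = g.kernel()
    sol = mn.solve_fixation(k, 1.4)
    rho, tau, absorb = mn.aggregate_solution(sol, mn.uniform_init(), k)
    assert rho == pytest.approx(sol.rho.mean())
    assert absorb == pytest.approx(sol.absorb_time.mean())
    # but the conditional time is NOT the plain mean of tau_v
    assert tau != pytest.approx(sol.cond_fix_time.mean())


def _truncated_fixation_time_oracle(kernel, r, pi, tol=1e-13):
    """E[steps | fixation] with a random start, by forward-propagating the
    configuration distribution until the unabsorbed mass is negligible."""
    n = kernel.n
    full = (1 << n) - 1
    dist = {1 << v: pi[v] for v in range(n)}
    mass_fix = 0.0
    time_fix = 0.0
    step = 0
    while sum(p for m, p in dist.items() if m not in (0, full)) > tol:
        step += 1
        new: dict[int, float] = {}
        for mask, p in dist.items():
            if mask in (0, full):
                new[mask] = new.get(mask, 0.0) + p
                continue
            for cfg, q in step_distribution(kernel, r, MutantConfiguration(n, mask)):
                new[cfg.mask] = new.get(cfg.mask, 0.0) + p * q
        arrived = new.get(full, 0.0) - dist.get(full, 0.0)
        mass_fix += arrived
        time_fix += arrived * step
        dist = new
    return time_fix / mass_fix


def test_conditional_time_aggregation_against_trajectory_oracle():
    """The fixation-weighted mixture is the true conditional expectation of
    the absorption step count on trajectories that fix, with random start."""
    g = mn.make_star(3)  # path P_3; small enough to propagate exactly
    k = g.kernel()
    r = 1.1
    pi = np.full(3, 1 / 3)
    sol = mn.solve_fixation(k, r)
    _, tau, _ = mn.aggregate_solution(sol, pi)
    oracle = _truncated_fixation_time_oracle(k, r, pi)
    assert tau == pytest.approx(oracle, rel=1e-9)


def test_aggregation_input_validation():
    g = mn.make_complete(4)
    sol = mn.solve_fixation(g.kernel(), 1.1)
    with pytest.raises(GraphError):
        mn.aggregate_solution(sol, np.array([0.5, 0.5]))  # wrong size
    with pytest.raises(GraphError):
        mn.aggregate_solution(sol, np.array([0.5, 0.5, 0.5, 0.5]))  # not a distribution


# ---------------------------------------------------------------------------
# effective rate of evolution
# ---------------------------------------------------------------------------


def test_effective_rate_waiting_time_dominated():
    # N=100, mu=1e-3, rho=0.1: t1 = 1/(N mu rho) = 100 generations
    rate = mn.effective_rate(100, 1e-3, 0.1, fix_time_steps=1.0)
    assert 1 / rate == pytest.approx(100 + 1 / 100)


def test_effective_rate_high_mutation_limit():
    # mu -> infinity: the rate saturates at N / tau
    rate = mn.effective_rate(100, 1e9, 0.5, fix_time_steps=500.0)
    assert rate == pytest.approx(100 / 500, rel=1e-6)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    rho=st.floats(1e-6, 1 - 1e-6),
    mu=st.floats(1e-9, 1.0),
    tau=st.floats(1e-3, 1e9),
    factor=st.floats(1.01, 10.0),
)
def test_effective_rate_monotonicity(rho, mu, tau, factor):
    # the inequalities are strict mathematically but can saturate in floating
    # point when the perturbed term is dwarfed by the other timescale
    base = mn.effective_rate(100, mu, rho, tau)
    assert mn.effective_rate(100, min(mu * factor, 1e12), rho, tau) >= base
    assert mn.effective_rate(100, mu, min(rho * factor, 1.0), tau) >= base
    assert mn.effective_rate(100, mu, rho, tau * factor) <= base


def test_effective_rate_strict_monotonicity_at_balanced_scales():
    base = mn.effective_rate(100, 1e-3, 0.2, 500.0)
    assert mn.effective_rate(100, 2e-3, 0.2, 500.0) > base
    assert mn.effective_rate(100, 1e-3, 0.4, 500.0) > base
    assert mn.effective_rate(100, 1e-3, 0.2, 1000.0) < base


def test_effective_rate_domain_errors():
    with pytest.raises(GraphError):
        mn.effective_rate(100, 0.0, 0.1, 1.0)
    with pytest.raises(GraphError):
        mn.effective_rate(100, 1e-3, -0.1, 1.0)


# ---------------------------------------------------------------------------
# Pareto front and lower bound
# ---------------------------------------------------------------------------


def _rec(gid, rho, tau):
    return TradeoffRecord(gid, 8, 1.1, "uniform", rho, tau, tau)


def test_pareto_front_dominance():
    fast_weak = _rec("a", 0.10, 50.0)
    slow_strong = _rec("b", 0.20, 300.0)
    dominated = _rec("c", 0.15, 400.0)
    front = pareto_front([fast_weak, slow_strong, dominated])
    assert {r.graph_id for r in front} == {"a", "b"}


def test_pareto_equal_rho_keeps_only_faster():
    a = _rec("a", 0.15, 100.0)
    b = _rec("b", 0.15, 200.0)
    assert pareto_front([a, b]) == [a]


def test_pareto_single_and_empty():
    a = _rec("a", 0.15, 100.0)
    assert pareto_front([a]) == [a]
    assert pareto_front([]) == []


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.01, 0.99), st.floats(1.0, 1e4)), min_size=1, max_size=25))
def test_pareto_front_is_idempotent(points):
    recs = [_rec(str(i), rho, tau) for i, (rho, tau) in enumerate(points)]
    front = pareto_front(recs)
    assert pareto_front(front) == front


def test_pareto_requires_common_scheme():
    a = _rec("a", 0.15, 100.0)
    b = TradeoffRecord("b", 8, 1.1, "temperature", 0.15, 100.0, 100.0)
    with pytest.raises(GraphError):
        pareto_front([a, b])


def test_absorption_lower_bound_formula():
    # rho = r collapses the bound to N ln N
    assert mn.absorption_lower_bound(1.0, 1.0, 20) == pytest.approx(20 * np.log(20))
    assert mn.absorption_lower_bound(1e-9, 1.1, 20) < 1e-6


def test_absorption_lower_bound_holds_on_small_corpus(small_graph_corpus):
    for g in small_graph_corpus:
        k = g.kernel()
        sol = mn.solve_fixation(k, 1.1)
        rho, _, absorb = mn.aggregate_solution(sol, mn.uniform_init(), k)
        assert absorb > mn.absorption_lower_bound(rho, 1.1, g.n)
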