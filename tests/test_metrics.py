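"""Conductance, communicability and hitting times against their oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from graphfix import (
    LevelProfile,
    biased_cycle,
    communicability,
    cycle_step_hitting_time,
    cycle_tipping_point,
    dual_circular_flow,
    first_step_hitting_times,
    fixture_graph,
    graph_conductance,
    hitting_times,
    partial_bipartite,
    partial_bipartite_closed_forms,
    single_link,
    single_link_closed_forms,
    single_link_equality_conditions,
    subset_conductance,
    saddle_point_search,
)
from graphfix.graphs import generic_graph
from graphfix.spectral import ReducibleGraphError

ALL_FAMILIES = [
    biased_cycle(5, Fraction(3, 10)),
    biased_cycle(9, 0.62),
    dual_circular_flow(LevelProfile.uniform((1, 2, 3), 0.3)),
    dual_circular_flow(LevelProfile.uniform((2, 3, 4), 0.75)),
    partial_bipartite(3, 4, 0.2, 0.5),
    partial_bipartite(2, 5, 0.6, 0.1),
    single_link(3, 4, 0.4, 0.6),
    single_link(2, 5, 0.3, 0.3),
    fixture_graph("row_stochastic", 7, 11),
    fixture_graph("doubly_stochastic", 6, 5),
]


# ---------------------------------------------------------------------- #
# conductance


def test_cycle_block_conductance():
    N = 7
    g = biased_cycle(N, Fraction(2, 7))
    for k in range(1, N):
        S = list(range(k))  # a contiguous block of k vertices
        c = subset_conductance(g, S)
        assert c.value == Fraction(N, k * (N - k))


def test_partial_bipartite_block_conductances():
    s, n, p, q = 3, 4, Fraction(1, 5), Fraction(1, 2)
    g = partial_bipartite(s, n, p, q)
    N = s + n
    assert subset_conductance(g, range(s)).value == Fraction(N, n) * (1 - p)
    assert subset_conductance(g, range(s, N)).value == Fraction(N, s) * (1 - q)


def test_flow_level_conductance():
    sizes = (1, 2, 3)
    g = dual_circular_flow(LevelProfile.uniform(sizes, Fraction(1, 4)))
    N = sum(sizes)
    offs = np.cumsum([0] + list(sizes))
    for lvl, n_s in enumerate(sizes):
        S = range(offs[lvl], offs[lvl + 1])
        assert subset_conductance(g, S).value == Fraction(N, N - n_s)


def test_single_link_conductances_match_closed_form():
    s, n = 3, 4
    for p, q in [(0.2, 0.5), (0.7, 0.3)]:
        g = single_link(s, n, p, q)
        cf = single_link_closed_forms(s, n, p, q)
        assert float(subset_conductance(g, [0, 1]).value) == pytest.approx(
            float(cf["C_Vs_minus_link"])
        )
        assert float(subset_conductance(g, [4, 5, 6]).value) == pytest.approx(
            float(cf["C_Vn_minus_link"])
        )
        assert float(subset_conductance(g, [2]).value) == pytest.approx(
            float(cf["C_link"])
        )
        assert float(subset_conductance(g, [0, 1, 2]).value) == pytest.approx(
            cf["C_Vs"]
        )
        assert float(subset_conductance(g, [3, 4, 5, 6]).value) == pytest.approx(
            cf["C_Vn"]
        )


def test_graph_conductance_exhaustive_and_disconnected():
    g = biased_cycle(5, 0.5)
    best = graph_conductance(g)
    brute = min(
        float(subset_conductance(g, S).value)
        for size in range(1, 5)
        for S in __import__("itertools").combinations(range(5), size)
    )
    assert float(best.value) == pytest.approx(brute)
    assert float(graph_conductance(partial_bipartite(3, 4, 1, 1)).value) == 0.0


def test_subset_conductance_rejects_trivial_subsets():
    g = biased_cycle(5, 0.5)
    with pytest.raises(ValueError):
        subset_conductance(g, [])
    with pytest.raises(ValueError):
        subset_conductance(g, range(5))


# ---------------------------------------------------------------------- #
# communicability


def test_cycle_trace_symmetric_in_p_with_max_at_half():
    vals = {}
    for p in (0.1, 0.25, 0.5, 0.75, 0.9):
        vals[p] = communicability(biased_cycle(5, p)).average
    assert vals[0.1] == pytest.approx(vals[0.9], abs=1e-12)
    assert vals[0.25] == pytest.approx(vals[0.75], abs=1e-12)
    assert vals[0.5] > vals[0.25] > vals[0.1]


def test_series6_close_to_exact_everywhere():
    for g in ALL_FAMILIES:
        exact = communicability(g, mode="exact").V
        series = communicability(g, mode="series6").V
        assert np.abs(exact - series).max() < 3e-4
        assert np.all(exact >= -1e-12)


def test_empty_graph_communicability_is_identity():
    class Z:  # minimal stand-in with a zero weight matrix
        W = np.zeros((4, 4))
        N = 4

    rep = communicability(Z())
    assert np.allclose(rep.V, np.eye(4))
    assert rep.average == pytest.approx(1.0)


def test_partial_bipartite_communicability_closed_forms():
    for s, n in [(2, 3), (3, 4), (2, 5), (3, 5), (4, 5)]:
        for p, q in [(0.2, 0.2), (0.2, 0.5), (0.5, 0.2), (0.8, 0.7)]:
            g = partial_bipartite(s, n, p, q)
            V = communicability(g).V
            cf = partial_bipartite_closed_forms(s, n, p, q)
            assert V[0, 0] == pytest.approx(cf["V_ss"], abs=1e-12)
            assert V[s, s] == pytest.approx(cf["V_nn"], abs=1e-12)
            assert V[0, s] == pytest.approx(cf["V_sn"], abs=1e-12)
            assert V[s, 0] == pytest.approx(cf["V_ns"], abs=1e-12)
            assert V[0, 1] == pytest.approx(cf["V_ss_offdiag"], abs=1e-12)
            assert np.trace(V) == pytest.approx(cf["trace"], abs=1e-12)


def test_trace_minimum_at_eigenvalue_equality_point():
    def avg(x):
        return communicability(partial_bipartite(3, 4, x[0], x[1])).average

    res = saddle_point_search(avg, [(0.05, 0.95), (0.05, 0.95)])
    assert len(res) == 1
    assert res[0].kind == "minimum"
    assert res[0].point[0] == pytest.approx(1 / 3, abs=1e-6)
    assert res[0].point[1] == pytest.approx(1 / 2, abs=1e-6)


def test_saddle_classification_on_quadratic():
    res = saddle_point_search(lambda x: x[0] ** 2 - x[1] ** 2, [(-1, 1), (-1, 1)])
    assert res[0].kind == "saddle"
    assert abs(res[0].point[0]) < 1e-8 and abs(res[0].point[1]) < 1e-8


def test_single_link_trace_stationary_point_is_saddle():
    def avg(x):
        return communicability(single_link(3, 4, x[0], x[1]), mode="series6").average

    res = saddle_point_search(avg, [(0.05, 0.95), (0.05, 0.95)], grid=5)
    assert len(res) == 1
    assert res[0].kind == "saddle"
    # the exact-expm surface has its saddle at nearly the same spot
    def avg_exact(x):
        return communicability(single_link(3, 4, x[0], x[1])).average

    res_exact = saddle_point_search(avg_exact, [(0.05, 0.95), (0.05, 0.95)], grid=5)
    assert np.allclose(res[0].point, res_exact[0].point, atol=2e-3)


# ---------------------------------------------------------------------- #
# hitting times


def test_hitting_times_match_first_step_oracle_on_all_families():
    for g in ALL_FAMILIES:
        M = hitting_times(g).M
        O = first_step_hitting_times(g)
        assert np.abs(M - O).max() < 1e-9


def test_balanced_three_cycle_adjacent_hitting_time():
    # first-step: h = 1 + h'/2, h' = 1 + h/2  =>  h = 2
    assert cycle_step_hitting_time(3, 0.5, 1) == pytest.approx(2.0)


def test_deterministic_cycle_one_step():
    # p = 0 makes the increasing-index step certain: one-step hit in 1
    assert cycle_step_hitting_time(5, 1e-12, 1, direction="ccw") == pytest.approx(
        1.0, abs=1e-9
    )


def test_cycle_tipping_point_mirror_symmetry():
    p_ccw = cycle_tipping_point(5, tol=1e-7)
    p_cw = cycle_tipping_point(5, direction="cw", tol=1e-7)
    assert p_ccw + p_cw == pytest.approx(1.0, abs=1e-5)
    assert p_ccw == pytest.approx(0.68806, abs=1e-4)


def test_partial_bipartite_hitting_closed_forms():
    for s, n in [(2, 3), (3, 4), (2, 5), (3, 5), (4, 5)]:
        for p, q in [(0.2, 0.2), (0.2, 0.5), (0.5, 0.2), (0.5, 0.5)]:
            M = hitting_times(partial_bipartite(s, n, p, q)).M
            cf = partial_bipartite_closed_forms(s, n, p, q)
            assert M[0, 1] == pytest.approx(cf["h_ss"], abs=1e-8)
            assert M[s, s + 1] == pytest.approx(cf["h_nn"], abs=1e-8)
            assert M[0, s] == pytest.approx(cf["h_sn"], abs=1e-8)
            assert M[s, 0] == pytest.approx(cf["h_ns"], abs=1e-8)


def test_partial_bipartite_hitting_limit_along_p_equals_q_cubed():
    # approaching the disconnection corner along p = q^k the within-block
    # hitting time tends to (1+k)(s-1)
    s, n, k = 3, 4, 3
    q = 1 - 1e-7
    cf = partial_bipartite_closed_forms(s, n, q**k, q)
    assert cf["h_ss"] == pytest.approx((1 + k) * (s - 1), rel=1e-5)


def test_partial_bipartite_hitting_balance_condition():
    # h_ss = h_nn on the closed-form balance locus
    for s, n in [(3, 4), (2, 5)]:
        for p in (0.2, 0.5):
            cf = partial_bipartite_closed_forms(s, n, p, 0)
            q = cf["h_balance_q"]
            if not 0 <= q <= 1:
                continue
            M = hitting_times(partial_bipartite(s, n, p, q)).M
            assert M[0, 1] == pytest.approx(M[s, s + 1], abs=1e-8)


def test_single_link_full_hitting_table():
    for p, q in [(0.2, 0.5), (0.5, 0.5), (0.7, 0.3), (0.4, 0.8)]:
        M = hitting_times(single_link(3, 4, p, q)).M
        cf = single_link_closed_forms(3, 4, p, q)["hitting"]
        for (i, j), val in cf.items():
            assert M[i - 1, j - 1] == pytest.approx(val, abs=1e-9), (i, j)


def test_single_link_constant_entries_and_equality_conditions():
    conds = single_link_equality_conditions()
    pairs = {
        "h11_h55": ((1, 1), (5, 5)),
        "h33_h44": ((3, 3), (4, 4)),
        "h34_h43": ((3, 4), (4, 3)),
        "h53_h14": ((5, 3), (1, 4)),
        "h12_h56": ((1, 2), (5, 6)),
        "h31_h45": ((3, 1), (4, 5)),
        "h41_h35": ((4, 1), (3, 5)),
        "h15_h51": ((1, 5), (5, 1)),
    }
    for name, ((a, b), (c, d)) in pairs.items():
        for p in (0.3, 0.5, 0.7):
            q = conds[name](p)
            if not 0 < q < 1:
                continue
            M = hitting_times(single_link(3, 4, p, q)).M
            assert M[a - 1, b - 1] == pytest.approx(M[c - 1, d - 1], abs=1e-7), name
    # h13 and h54 are constant and never equal
    for p, q in [(0.2, 0.5), (0.6, 0.9)]:
        M = hitting_times(single_link(3, 4, p, q)).M
        assert M[0, 2] == pytest.approx(2.0, abs=1e-9)
        assert M[4, 3] == pytest.approx(3.0, abs=1e-9)


def test_hitting_time_divergence_reported_at_endpoints():
    cf = single_link_closed_forms(3, 4, 1, 0.5)["hitting"]
    assert cf[(1, 4)] == math.inf  # crossing edge has zero probability
    with pytest.raises(ReducibleGraphError):
        hitting_times(single_link(3, 4, 1, 1))
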