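"""Laplacian spectra: stationary vectors, closed-form polynomials, bias factor."""

from fractions import Fraction

import numpy as np
import pytest

from graphfix import (
    LevelProfile,
    biased_cycle,
    closed_form_spectra,
    dual_circular_flow,
    eigenvalue_equality_point,
    fixture_graph,
    laplacian,
    partial_bipartite,
    single_link,
    spectral_report,
    stationary_distribution,
)
from graphfix.spectral import ReducibleGraphError, charpoly_residuals, cycle_coefficients


def sorted_key(z):
    return (round(complex(z).real, 9), round(complex(z).imag, 9))


def test_cycle_stationary_uniform_and_laplacian_is_I_minus_W():
    g = biased_cycle(5, Fraction(7, 10))
    phi = stationary_distribution(g, exact=True)
    assert phi == [Fraction(1, 5)] * 5
    Delta, Delta_A = laplacian(g)
    assert np.allclose(Delta, np.eye(5) - g.W, atol=1e-14)
    # balanced cycle: symmetric W, Delta_A = 0
    _, A_bal = laplacian(biased_cycle(5, Fraction(1, 2)))
    assert np.abs(A_bal).max() < 1e-15


def test_partial_bipartite_stationary_closed_form():
    s, n, p, q = 3, 4, Fraction(1, 5), Fraction(1, 2)
    phi = stationary_distribution(partial_bipartite(s, n, p, q), exact=True)
    scale = s * n * (2 - p - q)
    expected = [n * (1 - q) / scale] * s + [s * (1 - p) / scale] * n
    assert phi == expected
    # left-eigenvector residual in floats
    g = partial_bipartite(2, 5, 0.3, 0.1)
    ph = stationary_distribution(g)
    assert np.abs(ph @ g.W - ph).max() < 1e-12


def test_reducible_graph_stationary_errors():
    with pytest.raises(ReducibleGraphError):
        stationary_distribution(partial_bipartite(3, 4, 1, 1))


def test_cycle_coefficient_recurrence_values():
    # C^N_0 = 1, C^N_1 = N and the two-step recurrence; spot values from
    # expanding the circulant product directly
    assert cycle_coefficients(3) == [1, 3]
    assert cycle_coefficients(4) == [1, 4, 2]
    assert cycle_coefficients(6) == [1, 6, 9, 2]
    assert cycle_coefficients(7) == [1, 7, 14, 7]


@pytest.mark.parametrize("N", range(3, 10))
@pytest.mark.parametrize("p", [0, Fraction(1, 4), 0.5, 0.68, 1])
def test_cycle_charpoly_vanishes_on_spectrum(N, p):
    rep = spectral_report(biased_cycle(N, p))
    cp = closed_form_spectra("cycle", N=N, p=p)
    assert cp.degree == N
    assert charpoly_residuals(cp, rep.eigenvalues).max() < 1e-8


def test_cycle_endpoint_eigenvalues_are_roots_of_unity():
    cp = closed_form_spectra("cycle", N=4, p=1)
    got = sorted(np.round(np.array(cp.eigenvalues), 9), key=sorted_key)
    expected = sorted([0, 2, 1 + 1j, 1 - 1j], key=sorted_key)
    assert np.allclose(got, expected)
    rep = spectral_report(biased_cycle(4, 1))
    assert charpoly_residuals(cp, rep.eigenvalues).max() < 1e-8


@pytest.mark.parametrize("sizes", [(1, 2, 3), (2, 3, 5), (1, 2, 3, 4), (1, 1, 2)])
@pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
def test_flow_charpoly_is_shifted_cycle_factor(sizes, p):
    rep = spectral_report(dual_circular_flow(LevelProfile.uniform(sizes, p)))
    cp = closed_form_spectra("flow", sizes=sizes, p=p)
    assert charpoly_residuals(cp, rep.eigenvalues).max() < 1e-8
    # multiplicity of eigenvalue 1 is at least N - (levels)
    ones = np.sum(np.abs(rep.eigenvalues - 1) < 1e-8)
    assert ones >= sum(sizes) - len(sizes)


@pytest.mark.parametrize("sizes", [(1, 2, 3), (2, 3, 5), (1, 2, 3, 4)])
def test_flow_delta_A_eigenvalues_carry_bias_factor(sizes):
    # nonzero eigenvalues of Delta_A are imaginary and proportional to 1-2p
    ref = None
    for p in (0.1, 0.3, 0.7, 0.9):
        rep = spectral_report(dual_circular_flow(LevelProfile.uniform(sizes, p)))
        nz = rep.eigenvalues_A[np.abs(rep.eigenvalues_A) > 1e-10]
        assert np.abs(nz.real).max() < 1e-10
        scaled = np.sort_complex(nz / (1 - 2 * p))
        if ref is None:
            ref = scaled
        else:
            assert np.abs(scaled - ref).max() < 1e-9
        # closed-form Delta_A eigenvalues agree
        cf = closed_form_spectra("flow", sizes=sizes, p=p).extras["eigenvalues_A"]
        got = sorted(rep.eigenvalues_A, key=sorted_key)
        want = sorted(cf, key=sorted_key)
        assert np.abs(np.array(got) - np.array(want)).max() < 1e-9
    # balanced flow has no bias at all
    rep = spectral_report(dual_circular_flow(LevelProfile.uniform(sizes, 0.5)))
    assert np.abs(rep.eigenvalues_A).max() < 1e-12


@pytest.mark.parametrize("s,n", [(3, 4), (2, 5), (3, 5)])
@pytest.mark.parametrize("p,q", [(0.2, 0.5), (0.7, 0.3), (0, 0)])
def test_partial_bipartite_spectrum_closed_form(s, n, p, q):
    rep = spectral_report(partial_bipartite(s, n, p, q))
    cp = closed_form_spectra("partial_bipartite", s=s, n=n, p=p, q=q)
    assert charpoly_residuals(cp, rep.eigenvalues).max() < 1e-8
    expected = sorted(
        [0.0, 2 - p - q] + [1 + p / (s - 1)] * (s - 1) + [1 + q / (n - 1)] * (n - 1)
    )
    assert np.allclose(np.sort(rep.eigenvalues.real), expected, atol=1e-9)
    assert np.abs(rep.eigenvalues.imag).max() < 1e-9


def test_partial_bipartite_is_reversible_so_delta_A_vanishes():
    rep = spectral_report(partial_bipartite(3, 4, 0.2, 0.5))
    assert np.abs(rep.Delta_A).max() < 1e-13
    assert np.allclose(rep.Delta, rep.Delta.T, atol=1e-13)


def test_disconnected_partial_bipartite_second_zero_eigenvalue():
    rep = spectral_report(partial_bipartite(3, 4, 1, 1))
    assert rep.zero_multiplicity == 2
    assert rep.Delta is None and rep.reducible_reason


@pytest.mark.parametrize("s,n", [(3, 4), (2, 5), (4, 5)])
@pytest.mark.parametrize("p,q", [(0.2, 0.5), (0.7, 0.3), (Fraction(1, 2), Fraction(1, 2))])
def test_single_link_charpoly_and_lumped_roots(s, n, p, q):
    rep = spectral_report(single_link(s, n, p, q))
    cp = closed_form_spectra("single_link", s=s, n=n, p=p, q=q)
    assert charpoly_residuals(cp, rep.eigenvalues).max() < 1e-8
    eigs = np.sort(rep.eigenvalues.real)
    # s-2 roots at s/(s-1) and n-2 roots at n/(n-1), plus the zero root
    for lam, mult in [(s / (s - 1), s - 2), (n / (n - 1), n - 2), (0.0, 1)]:
        assert np.sum(np.abs(eigs - lam) < 1e-8) >= mult


def test_single_link_disconnects_at_endpoints():
    rep = spectral_report(single_link(3, 4, 1, 1))
    assert rep.zero_multiplicity == 2


def test_spectrum_bounds_all_families():
    graphs = [
        biased_cycle(6, 0.3),
        dual_circular_flow(LevelProfile.uniform((1, 2, 3), 0.7)),
        partial_bipartite(2, 5, 0.4, 0.1),
        single_link(3, 4, 0.3, 0.6),
        fixture_graph("row_stochastic", 6, 3),
    ]
    for g in graphs:
        rep = spectral_report(g)
        eigs = rep.eigenvalues
        assert np.min(np.abs(eigs)) < 1e-10  # lambda_0 = 0
        assert np.all(eigs.real >= -1e-10)
        # eigenvalues of I - W lie in the unit disc around 1
        assert np.abs(eigs - 1).max() <= 1 + 1e-10


@pytest.mark.parametrize("s,n,expected", [
    ((3), 4, (Fraction(1, 3), Fraction(1, 2))),
    (2, 5, (Fraction(1, 6), Fraction(4, 6))),
    (4, 4, (Fraction(3, 7), Fraction(3, 7))),
])
def test_eigenvalue_equality_point(s, n, expected):
    pq = eigenvalue_equality_point(s, n)
    assert pq == expected
    p, q = pq
    # all three nonzero eigenvalues coincide there
    vals = {1 + p / (s - 1), 1 + q / (n - 1), 2 - p - q}
    assert len(vals) == 1
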