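"""Stationary distributions, the graph Laplacian, and closed-form spectra.

The Laplacian used here is the directed-graph form
``Delta = Phi^(1/2) (I - W) Phi^(-1/2)`` where ``Phi`` is the diagonal
matrix of the stationary distribution ``phi`` of the edge-weight matrix
(``phi . W = phi``).  Because that is a similarity transform, the spectrum
of ``Delta`` always equals the spectrum of ``I - W``; the matrix itself is
only defined when every vertex carries positive stationary mass.  The
antisymmetric part ``Delta_A = (Delta - Delta^T) / 2`` measures
directional bias: for biased cycles and circular flows all its nonzero
eigenvalues are imaginary and proportional to ``1 - 2p``.

Closed-form characteristic polynomials are provided for all four graph
families, each cross-checked against the numeric spectrum in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import sympy as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .exact import rref
from .graphs import WeightedDigraph, as_fraction

__all__ = [
    "SpectralReport",
    "CharPolyCoefficients",
    "stationary_distribution",
    "laplacian",
    "spectral_report",
    "cycle_coefficients",
    "closed_form_spectra",
    "eigenvalue_equality_point",
    "charpoly_residuals",
    "ReducibleGraphError",
]

ZERO_EIG_TOL = 1e-10


class ReducibleGraphError(ValueError):
    """The edge-weight matrix is not irreducible."""


def _strong_components(graph: WeightedDigraph) -> int:
    ncomp, _ = connected_components(
        csr_matrix(graph.W > 0), directed=True, connection="strong"
    )
    return ncomp


def stationary_distribution(graph: WeightedDigraph, exact: bool = False):
    """Stationary row vector phi with ``phi . W = phi``, normalised to sum 1.

    Requires an irreducible weight matrix (otherwise the stationary
    distribution is not unique and an error is raised).
    """
    if _strong_components(graph) != 1:
        raise ReducibleGraphError(
            "weight matrix is reducible (multiple strongly connected "
            "components); the stationary distribution is not unique"
        )
    N = graph.N
    if exact:
        # phi (W - I) = 0 with sum(phi) = 1, solved by exact RREF of the
        # transposed system augmented with the normalisation row.
        rows = [
            [graph.W_exact[i][j] - (1 if i == j else 0) for i in range(N)]
            for j in range(N)
        ]
        rows.append([Fraction(1)] * N)
        rhs = [Fraction(0)] * N + [Fraction(1)]
        aug = [row + [rhs[k]] for k, row in enumerate(rows)]
        red, pivots = rref(aug)
        if N in pivots:
            raise ReducibleGraphError("stationary system inconsistent")
        phi = [Fraction(0)] * N
        for rr, c in enumerate(pivots):
            phi[c] = red[rr][N]
        return phi
    A = graph.W.T - np.eye(N)
    A[-1, :] = 1.0
    b = np.zeros(N)
    b[-1] = 1.0
    phi = np.linalg.solve(A, b)
    resid = np.abs(phi @ graph.W - phi).max()
    if resid > 1e-11:
        raise ReducibleGraphError(
            f"stationary solve residual {resid:.3g} too large; "
            "graph parameters are likely at a degenerate endpoint"
        )
    return phi


def laplacian(graph: WeightedDigraph) -> tuple[np.ndarray, np.ndarray]:
    """The Laplacian ``Delta`` and its antisymmetric part ``Delta_A``.

    Errors when any vertex has nonpositive stationary mass, since the
    similarity transform ``Phi^(1/2)`` is then undefined.
    """
    phi = stationary_distribution(graph)
    if np.any(phi <= 0):
        bad = [graph.vertex_labels[i] for i in np.where(phi <= 0)[0]]
        raise ReducibleGraphError(
            f"stationary mass is zero on vertices {bad}; the Laplacian "
            "similarity transform Phi^(1/2) is undefined there"
        )
    root = np.sqrt(phi)
    Delta = (root[:, None] * (np.eye(graph.N) - graph.W)) / root[None, :]
    Delta_A = 0.5 * (Delta - Delta.T)
    return Delta, Delta_A


def _sorted_eigs(M: np.ndarray) -> np.ndarray:
    eigs = np.linalg.eigvals(M)
    order = np.lexsort((eigs.imag, eigs.real))
    return eigs[order]


@dataclass
class SpectralReport:
    """Spectrum of the Laplacian and of its antisymmetric part.

    ``eigenvalues`` always come from ``I - W`` (similar to ``Delta``), so
    they are available even when the graph is reducible and the Laplacian
    matrix itself cannot be formed; in that case ``Delta`` and ``Delta_A``
    are None and ``reducible_reason`` explains why.
    """

    phi: np.ndarray | None
    Delta: np.ndarray | None
    Delta_A: np.ndarray | None
    eigenvalues: np.ndarray
    eigenvalues_A: np.ndarray | None
    zero_multiplicity: int
    reducible_reason: str | None = None


def spectral_report(graph: WeightedDigraph) -> SpectralReport:
    eigs = _sorted_eigs(np.eye(graph.N) - graph.W)
    zero_mult = int(np.sum(np.abs(eigs) < ZERO_EIG_TOL))
    try:
        Delta, Delta_A = laplacian(graph)
        phi = stationary_distribution(graph)
        eigsA = _sorted_eigs(Delta_A)
        reason = None
    except ReducibleGraphError as err:
        phi = Delta = Delta_A = eigsA = None
        reason = str(err)
    return SpectralReport(
        phi=phi,
        Delta=Delta,
        Delta_A=Delta_A,
        eigenvalues=eigs,
        eigenvalues_A=eigsA,
        zero_multiplicity=zero_mult,
        reducible_reason=reason,
    )


# ---------------------------------------------------------------------------
# closed-form characteristic polynomials
# ---------------------------------------------------------------------------

_lam = sp.Symbol("lambda")


@dataclass
class CharPolyCoefficients:
    """A closed-form characteristic polynomial of the Laplacian.

    ``poly`` is a sympy expression in ``lambda`` (exact when the family
    parameters are rational); ``coefficients`` lists floats from the
    highest degree down; ``eigenvalues`` holds explicit roots where the
    family admits them; ``factors`` records the closed-form factorisation
    as (expression, multiplicity) pairs.
    """

    family: str
    poly: sp.Expr
    coefficients: list[complex]
    factors: list[tuple[sp.Expr, int]] = field(default_factory=list)
    eigenvalues: list | None = None
    extras: dict = field(default_factory=dict)

    @property
    def degree(self) -> int:
        return sp.Poly(self.poly, _lam).degree()


def cycle_coefficients(N: int, kmax: int | None = None) -> list[int]:
    """The biased-cycle characteristic-polynomial coefficients C^N_k.

    Defined by ``C^N_0 = 1``, ``C^N_1 = N`` and the two-step recurrence
    ``C^N_j = C^(N-1)_j + C^(N-2)_(j-1)``; ``C^N_k`` multiplies
    ``(-1)^k p^k (1-p)^k (lambda - 1)^(N - 2k)``.
    """
    if kmax is None:
        kmax = N // 2
    table: dict[tuple[int, int], int] = {}

    def get(M: int, j: int) -> int:
        # terms with 2j > M do not occur in the degree-M polynomial
        return 0 if 2 * j > M else table[(M, j)]

    for M in range(1, N + 1):
        table[(M, 0)] = 1
        if M >= 2:
            table[(M, 1)] = M
        for j in range(2, M // 2 + 1):
            table[(M, j)] = get(M - 1, j) + get(M - 2, j - 1)
    return [table[(N, j)] for j in range(min(kmax, N // 2) + 1)]


def _cycle_charpoly(N: int, p) -> sp.Expr:
    # floats convert to their exact binary rational so all polynomial
    # algebra downstream stays exact
    pe = sp.Rational(as_fraction(p))
    x = _lam - 1
    C = cycle_coefficients(N)
    if N % 2 == 1:
        poly = sum(
            (-1) ** k * C[k] * pe**k * (1 - pe) ** k * x ** (N - 2 * k)
            for k in range((N - 1) // 2 + 1)
        )
        poly += pe**N + (1 - pe) ** N
    else:
        poly = sum(
            (-1) ** k * C[k] * pe**k * (1 - pe) ** k * x ** (N - 2 * k)
            for k in range((N - 2) // 2 + 1)
        )
        half = N // 2
        if N % 4 == 0:
            K = (pe**half - (1 - pe) ** half) ** 2
        else:
            K = (pe**half + (1 - pe) ** half) ** 2
        poly -= K
    return sp.expand(poly)


def _is_rationalish(x) -> bool:
    return isinstance(x, (int, Fraction, str))


def _coeff_list(poly: sp.Expr) -> list[complex]:
    p = sp.Poly(sp.expand(poly), _lam)
    return [complex(c) for c in p.all_coeffs()]


def closed_form_spectra(family: str, **params) -> CharPolyCoefficients:
    """Closed-form Laplacian characteristic polynomial for a graph family.

    Supported families and parameters:

    * ``cycle``: ``N``, ``p``.  Coefficient recurrence polynomial; at
      ``p in {0, 1}`` the eigenvalues are ``1 - e^(2 pi i k / N)`` (N odd)
      or ``1 + e^(2 pi i k / N)`` (N even).
    * ``flow``: ``sizes``, ``p`` (uniform).  ``(lambda - 1)^(N - k - 1)``
      times the characteristic polynomial of the biased cycle on ``k + 1``
      vertices (one per level).
    * ``partial_bipartite``: ``s``, ``n``, ``p``, ``q``.  Eigenvalues
      ``0``, ``(s-1+p)/(s-1)`` (x s-1), ``(n-1+q)/(n-1)`` (x n-1) and
      ``2 - p - q``.  The chain is reversible, so ``Delta_A = 0`` and its
      polynomial (in extras) is ``lambda^N``.
    * ``single_link``: ``s``, ``n``, ``p``, ``q``.  ``s - 2`` roots
      ``s/(s-1)``, ``n - 2`` roots ``n/(n-1)``, the root 0, and a cubic
      obtained exactly from the 4x4 equitable-partition quotient of W.
    """
    if family == "cycle":
        N, p = params["N"], params["p"]
        poly = _cycle_charpoly(N, p)
        eigenvalues = None
        pe = as_fraction(p)
        if pe in (0, 1):
            sign = 1 if N % 2 == 0 else -1
            eigenvalues = [
                1 + sign * np.exp(2j * np.pi * k / N) for k in range(N)
            ]
        # Delta = I - W for cycles, so Delta_A is circulant with explicit
        # eigenvalues (1 - 2p) i sin(2 pi j / N) -- all imaginary, all
        # carrying the directional-bias factor 1 - 2p.
        pf = float(as_fraction(p))
        eigsA = [
            (1 - 2 * pf) * 1j * np.sin(2 * np.pi * j / N) for j in range(N)
        ]
        return CharPolyCoefficients(
            family="cycle",
            poly=poly,
            coefficients=_coeff_list(poly),
            eigenvalues=eigenvalues,
            extras={"C": cycle_coefficients(N), "eigenvalues_A": eigsA},
        )

    if family == "flow":
        sizes = tuple(params["sizes"])
        p = params["p"]
        L = len(sizes)  # number of levels = k + 1
        N = sum(sizes)
        cycle_factor = _cycle_charpoly(L, p) if L >= 3 else _two_level_factor(p)
        poly = sp.expand((_lam - 1) ** (N - L) * cycle_factor)
        # Delta_A inherits the cycle's imaginary pair structure; the extra
        # N - L eigenvalues are zero.
        pf = float(as_fraction(p))
        eigsA = [0.0j] * (N - L) + [
            (1 - 2 * pf) * 1j * np.sin(2 * np.pi * j / L) for j in range(L)
        ]
        return CharPolyCoefficients(
            family="flow",
            poly=poly,
            coefficients=_coeff_list(poly),
            factors=[((_lam - 1), N - L), (cycle_factor, 1)],
            extras={"eigenvalues_A": eigsA},
        )

    if family == "partial_bipartite":
        s, n = params["s"], params["n"]
        p = sp.Rational(as_fraction(params["p"]))
        q = sp.Rational(as_fraction(params["q"]))
        lam = _lam
        e_s = 1 + p / (s - 1) if s > 1 else None
        e_n = 1 + q / (n - 1) if n > 1 else None
        factors = [(lam, 1)]
        eigenvalues = [sp.Integer(0)]
        if s > 1:
            factors.append((lam - e_s, s - 1))
            eigenvalues += [e_s] * (s - 1)
        if n > 1:
            factors.append((lam - e_n, n - 1))
            eigenvalues += [e_n] * (n - 1)
        factors.append((lam - (2 - p - q), 1))
        eigenvalues.append(2 - p - q)
        poly = sp.expand(sp.prod(f**m for f, m in factors))
        N = s + n
        # The partial bipartite chain is reversible (phi_i w_ij = phi_j w_ji
        # holds on every edge), so the similarity Laplacian is symmetric and
        # its antisymmetric part vanishes identically: poly_A = lambda^N.
        return CharPolyCoefficients(
            family="partial_bipartite",
            poly=poly,
            coefficients=_coeff_list(poly),
            factors=factors,
            eigenvalues=eigenvalues,
            extras={"poly_A": lam**N, "reversible": True},
        )

    if family == "single_link":
        return _single_link_charpoly(**params)

    raise ValueError(f"unsupported family {family!r}")


def _two_level_factor(p) -> sp.Expr:
    # two-level flows collapse both directions onto the same neighbouring
    # level; the quotient is the complete bipartite 2x2 doubly stochastic
    # block with eigenvalues 1 and -1, i.e. lambda(lambda - 2)
    _ = p
    return sp.expand(_lam * (_lam - 2))


def _single_link_charpoly(s: int, n: int, p, q) -> CharPolyCoefficients:
    pe = sp.Rational(as_fraction(p))
    qe = sp.Rational(as_fraction(q))
    lam = _lam
    # Equitable partition {non-link V_s}, {link V_s}, {link V_n}, {non-link V_n}
    # of the weight matrix; the quotient carries the four non-lumped
    # eigenvalues (incl. the Perron root), the complement spaces contribute
    # (lambda - s/(s-1))^(s-2) and (lambda - n/(n-1))^(n-2).
    B = sp.Matrix(
        [
            [
                (s - 2) * sp.Rational(1, s - 1),
                sp.Rational(1, s - 1),
                0,
                0,
            ],
            [pe, 0, 1 - pe, 0],
            [0, 1 - qe, 0, qe],
            [
                0,
                0,
                sp.Rational(1, n - 1),
                (n - 2) * sp.Rational(1, n - 1),
            ],
        ]
    )
    quart = sp.expand(((lam - 1) * sp.eye(4) + B).det())
    cubic = sp.simplify(sp.cancel(quart / lam))
    factors = [
        (lam - sp.Rational(s, s - 1), s - 2),
        (lam - sp.Rational(n, n - 1), n - 2),
        (lam, 1),
        (sp.expand(cubic), 1),
    ]
    poly = sp.expand(
        (lam - sp.Rational(s, s - 1)) ** (s - 2)
        * (lam - sp.Rational(n, n - 1)) ** (n - 2)
        * quart
    )
    return CharPolyCoefficients(
        family="single_link",
        poly=poly,
        coefficients=_coeff_list(poly),
        factors=factors,
        extras={"cubic": cubic},
    )


def eigenvalue_equality_point(s: int, n: int) -> tuple[Fraction, Fraction]:
    """The (p, q) at which all three nonzero Laplacian eigenvalues coincide.

    Solving ``(s-1+p)/(s-1) = (n-1+q)/(n-1) = 2-p-q`` gives exactly
    ``(p, q) = (s-1, n-1) / (n+s-1)``.
    """
    if s < 2 or n < 2:
        raise ValueError("need s, n >= 2")
    return Fraction(s - 1, n + s - 1), Fraction(n - 1, n + s - 1)


def charpoly_residuals(
    cp: CharPolyCoefficients, eigenvalues: Sequence[complex]
) -> np.ndarray:
    """|closed-form polynomial| evaluated at each numeric eigenvalue."""
    coeffs = np.array(cp.coefficients, dtype=complex)
    return np.abs([np.polyval(coeffs, ev) for ev in eigenvalues])
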