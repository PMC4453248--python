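"""Conductance, communicability and expected hitting times, with closed forms.

Three structural measures of a row-stochastic weighted digraph ``(G, W)``:

* **subset conductance** (Cheeger-type):
  ``C(S) = N / (|S| |V \\ S|) * sum_{i in S, j not in S} w_ij`` --
  inversely related to the mixing time of a walk started in ``S``;
* **communicability**: the matrix ``V = e^W``, whose diagonal entries
  weight closed walks (vertex centrality) and whose normalised trace
  ``Tr(e^W)/N`` is the average centrality; both the exact matrix
  exponential and the literal sixth-order Taylor truncation are offered;
* **expected hitting times**: ``h_ij``, the expected number of steps for
  the Markov chain to first reach ``j`` from ``i``, computed via the
  Kemeny-Snell fundamental matrix ``Z = [I - (W - A)]^-1`` (``A`` has the
  stationary row ``phi`` in every row) as ``M = (I - Z + J Z*) D`` with
  ``D = diag(1/phi_j)``; diagonal entries of ``M`` are expected return
  times.  An independent first-step-analysis solver is provided as an
  oracle for the fundamental-matrix route.

Closed-form expressions for the partial bipartite and single-link families
(block hitting times, communicability entries, conductances, equality
loci) are implemented as reference formulas; every one of them is gated by
agreement with the numeric operations in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import root

from .graphs import WeightedDigraph, as_fraction, biased_cycle
from .spectral import ReducibleGraphError, stationary_distribution

__all__ = [
    "ConductanceValue",
    "CommunicabilityReport",
    "HittingTimeMatrix",
    "SaddleResult",
    "subset_conductance",
    "graph_conductance",
    "communicability",
    "hitting_times",
    "first_step_hitting_times",
    "closed_form_metrics",
    "partial_bipartite_closed_forms",
    "single_link_closed_forms",
    "single_link_equality_conditions",
    "saddle_point_search",
    "cycle_step_hitting_time",
    "cycle_tipping_point",
    "golden_section_max",
]

CONDUCTANCE_CAP = 20


@dataclass(frozen=True)
class ConductanceValue:
    subset: tuple[int, ...]
    value: object  # Fraction or float
    complement_size: int

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class CommunicabilityReport:
    V: np.ndarray
    centralities: np.ndarray
    average: float
    mode: str


@dataclass
class HittingTimeMatrix:
    """Expected hitting times with the matrices used to build them.

    ``M[i, j]`` is the expected first-passage time from i to j for i != j;
    the diagonal holds expected *return* times ``1/phi_j`` (the
    Kemeny-Snell convention).
    """

    M: np.ndarray
    Z: np.ndarray
    A: np.ndarray
    D: np.ndarray
    phi: np.ndarray
    diagonal: str = "return-times"


def subset_conductance(
    graph: WeightedDigraph, S: Sequence[int]
) -> ConductanceValue:
    """Conductance of a vertex subset (0-based indices)."""
    N = graph.N
    S = tuple(sorted(set(int(i) for i in S)))
    if not S or len(S) == N:
        raise ValueError("S must be a proper nonempty subset of the vertices")
    if any(i < 0 or i >= N for i in S):
        raise ValueError("subset indices out of range")
    inside = set(S)
    boundary = sum(
        graph.W_exact[i][j]
        for i in S
        for j in range(N)
        if j not in inside
    )
    value = Fraction(N, len(S) * (N - len(S))) * boundary
    return ConductanceValue(subset=S, value=value, complement_size=N - len(S))


def graph_conductance(graph: WeightedDigraph) -> ConductanceValue:
    """Minimum subset conductance over all proper nonempty subsets.

    Exhaustive (2^N - 2 subsets); refuses N beyond CONDUCTANCE_CAP.
    """
    N = graph.N
    if N > CONDUCTANCE_CAP:
        raise ValueError(
            f"exhaustive conductance minimisation capped at N = {CONDUCTANCE_CAP}"
        )
    W = graph.W
    best = None
    best_S = None
    # complements are scanned too, so subsets of size <= N/2 suffice for the
    # undirected case but not for directed boundaries: scan everything.
    for size in range(1, N):
        coeff = N / (size * (N - size))
        for S in combinations(range(N), size):
            mask = np.zeros(N, dtype=bool)
            mask[list(S)] = True
            val = coeff * W[mask][:, ~mask].sum()
            if best is None or val < best:
                best, best_S = val, S
    return subset_conductance(graph, best_S)


def communicability(
    graph: WeightedDigraph, mode: str = "exact"
) -> CommunicabilityReport:
    """Communicability matrix ``e^W``, exact or as the order-6 series.

    ``mode="exact"`` uses scipy's scaling-and-squaring expm;
    ``mode="series6"`` evaluates ``I + W + W^2/2 + ... + W^6/720``
    literally (the truncation a desk calculation would use; for a
    row-stochastic W the entrywise remainder is below ``e - sum_{k<=6} 1/k!
    ~ 2.3e-4``).
    """
    W = graph.W
    if mode == "exact":
        V = expm(W)
    elif mode == "series6":
        V = np.eye(graph.N)
        term = np.eye(graph.N)
        for k in range(1, 7):
            term = term @ W / k
            V = V + term
    else:
        raise ValueError(f"unknown communicability mode {mode!r}")
    cent = np.diag(V).copy()
    return CommunicabilityReport(
        V=V, centralities=cent, average=float(np.trace(V)) / graph.N, mode=mode
    )


def hitting_times(graph: WeightedDigraph) -> HittingTimeMatrix:
    """Expected hitting times via the Kemeny-Snell fundamental matrix.

    Requires an irreducible chain; at degenerate parameter endpoints the
    stationary solve raises a targeted error (some hitting times diverge
    whenever a transition required to reach the target has zero
    probability).
    """
    phi = stationary_distribution(graph)
    N = graph.N
    A = np.tile(phi, (N, 1))
    Z = np.linalg.inv(np.eye(N) - (graph.W - A))
    Zstar = np.diag(np.diag(Z))
    J = np.ones((N, N))
    D = np.diag(1.0 / phi)
    M = (np.eye(N) - Z + J @ Zstar) @ D
    return HittingTimeMatrix(M=M, Z=Z, A=A, D=D, phi=phi)


def first_step_hitting_times(graph: WeightedDigraph) -> np.ndarray:
    """Hitting times by first-step analysis: an independent oracle.

    For each target ``j`` solves ``h_i = 1 + sum_{k != j} w_ik h_k`` over
    ``i != j``; the diagonal is filled with the return time
    ``1 + sum_k w_jk h_kj`` for comparability with the fundamental-matrix
    construction.
    """
    N = graph.N
    W = graph.W
    M = np.zeros((N, N))
    for j in range(N):
        others = [i for i in range(N) if i != j]
        A = np.eye(N - 1) - W[np.ix_(others, others)]
        try:
            h = np.linalg.solve(A, np.ones(N - 1))
        except np.linalg.LinAlgError:
            raise ReducibleGraphError(
                f"vertex {j + 1} is not reachable from every other vertex; "
                "some hitting times are infinite"
            ) from None
        for row, i in enumerate(others):
            M[i, j] = h[row]
        M[j, j] = 1.0 + sum(W[j, k] * M[k, j] for k in others)
    return M


# ---------------------------------------------------------------------------
# closed forms for the two-component families
# ---------------------------------------------------------------------------


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num != 0 else math.nan
    return num / den


def partial_bipartite_closed_forms(s: int, n: int, p, q) -> dict:
    """Closed-form metrics of the (s, n) partial bipartite graph.

    Block hitting times (h_ss between two s-block vertices, etc.),
    communicability entries of ``e^W`` (exact, via the equitable-partition
    spectral decomposition: W has eigenvalues 1, p+q-1, -p/(s-1) and
    -q/(n-1)), the trace, the block conductances, and the conductance
    balance threshold.  Entries diverge (+inf) at parameter endpoints where
    the required transitions have zero probability.
    """
    p, q = float(as_fraction(p)), float(as_fraction(q))
    N = s + n
    d = 2.0 - p - q
    out = {}
    out["h_ss"] = _safe_div(s * (s - 1) * d, (1 - q) * (s - 1 + p))
    out["h_nn"] = _safe_div(n * (n - 1) * d, (1 - p) * (n - 1 + q))
    out["h_sn"] = _safe_div(
        (n - 1) * (2 * n - 1) - (n - 1) ** 2 * p - n * (n - 2) * q,
        (1 - p) * (n - 1 + q),
    )
    out["h_ns"] = _safe_div(
        (s - 1) * (2 * s - 1) - (s - 1) ** 2 * q - s * (s - 2) * p,
        (1 - q) * (s - 1 + p),
    )
    # communicability: lifted 2x2 quotient R = [[p, 1-p], [1-q, q]] with
    # eigenvalues 1 and theta = p + q - 1, plus the within-block complement
    # eigenvalues -p/(s-1), -q/(n-1)
    theta = p + q - 1.0
    e1, eth = math.e, math.exp(theta)
    cs = math.exp(-p / (s - 1)) if s > 1 else None
    cn = math.exp(-q / (n - 1)) if n > 1 else None
    if d == 0:  # p = q = 1: disconnected, e^R diagonal
        R11, R12, R21, R22 = e1, 0.0, 0.0, e1
    else:
        R11 = (e1 * (1 - q) + eth * (1 - p)) / d
        R12 = (1 - p) * (e1 - eth) / d
        R21 = (1 - q) * (e1 - eth) / d
        R22 = (e1 * (1 - p) + eth * (1 - q)) / d
    if s > 1:
        out["V_ss"] = R11 / s + cs * (s - 1) / s
        out["V_ss_offdiag"] = (R11 - cs) / s
    else:
        out["V_ss"] = R11 / s
    if n > 1:
        out["V_nn"] = R22 / n + cn * (n - 1) / n
        out["V_nn_offdiag"] = (R22 - cn) / n
    else:
        out["V_nn"] = R22 / n
    out["V_sn"] = R12 / n
    out["V_ns"] = R21 / s
    out["trace"] = (
        e1
        + eth
        + (s - 1) * (cs if cs is not None else 0.0)
        + (n - 1) * (cn if cn is not None else 0.0)
    )
    out["C_Vs"] = N * (1 - p) / n
    out["C_Vn"] = N * (1 - q) / s
    # q at which h_ss = h_nn (the 2-p-q factor cancels; linear in q)
    numer = n * (n - 1) * (s - 1 + p) - s * (s - 1) * (1 - p) * (n - 1)
    denom = s * (s - 1) * (1 - p) + n * (n - 1) * (s - 1 + p)
    out["h_balance_q"] = _safe_div(numer, denom)
    out["eigenvalues"] = [0.0, 1 + p / (s - 1), 1 + q / (n - 1), d]
    return out


def single_link_closed_forms(s: int, n: int, p, q) -> dict:
    """Closed-form metrics of the (s, n) single-link graph.

    The five conductances hold for any (s, n); the full hitting-time table
    is implemented for the (3, 4) case, keyed by the 1-based vertex labels
    v1, v2 (non-linking first component), v3 (its linking vertex), v4 (the
    second component's linking vertex), v5..v7 (non-linking second
    component).  Diverging entries are returned as +inf.
    """
    p, q = float(as_fraction(p)), float(as_fraction(q))
    N = s + n
    out = {
        "C_Vs_minus_link": Fraction(N, (s - 1) * (n + 1)),
        "C_Vn_minus_link": Fraction(N, (s + 1) * (n - 1)),
        "C_link": Fraction(N, N - 1),
        "C_Vs": N * (1 - p) / (s * n),
        "C_Vn": N * (1 - q) / (s * n),
    }
    if (s, n) == (3, 4):
        f = 2 + p + 2 * q - 5 * p * q
        h = {
            (1, 1): _safe_div(f, p * (1 - q)),
            (3, 3): _safe_div(f, 1 - q),
            (5, 5): _safe_div(f, q * (1 - p)),
            (4, 4): _safe_div(f, 1 - p),
            (1, 2): _safe_div(2 * f, 3 * p * (1 - q)),
            (5, 6): _safe_div(3 * f, 4 * q * (1 - p)),
            (1, 3): 2.0,
            (3, 1): _safe_div(2 * (4 - p + 4 * q - 7 * p * q), 3 * p * (1 - q)),
            (1, 4): _safe_div(3.0, 1 - p),
            (4, 1): _safe_div(8 + p + 8 * q - 5 * p * q, 3 * p * (1 - q)),
            (1, 5): _safe_div(3 * (2 + p + 2 * q - 3 * p * q), 2 * q * (1 - p)),
            (5, 1): _safe_div(2 * (4 + 5 * p + 4 * q - 7 * p * q), 3 * p * (1 - q)),
            (3, 4): _safe_div(1 + 2 * p, 1 - p),
            (4, 3): _safe_div(1 + 3 * q, 1 - q),
            (3, 5): _safe_div(6 + 3 * p + 2 * q - 5 * p * q, 2 * q * (1 - p)),
            (5, 3): _safe_div(4.0, 1 - q),
            (4, 5): _safe_div(3 * (2 + p - 3 * p * q), 2 * q * (1 - p)),
            (5, 4): 3.0,
        }
        out["hitting"] = h
    return out


def single_link_equality_conditions() -> dict[str, Callable[[float], float]]:
    """Equality loci q(p) for the natural hitting-time pairs of the (3,4) graph.

    Each condition is derived exactly from the closed-form table (and is
    confirmed against the numeric hitting times in the tests):

    * ``h11 = h55`` and ``h33 = h44``:  q = p
    * ``h34 = h43``:                    q = 3p / (4 - p)
    * ``h53 = h14``:                    q = (4p - 1) / 3
    * ``h12 = h56``:                    q = 9p / (8 + p)
    * ``h31 = h45``, ``h41 = h35``, ``h15 = h51``: quadratic-in-q loci with
      the radicands given below.

    ``h13`` (identically 2) never equals ``h54`` (identically 3).
    """

    def h31_h45(pp: float) -> float:
        disc = math.sqrt(409 * pp**2 + 400 * pp + 64)
        return (-20 * pp**2 + pp + (1 - pp) * disc - 8) / (pp**2 - 44 * pp + 16)

    def h41_h35(pp: float) -> float:
        disc = math.sqrt(76 * pp**4 - 292 * pp**3 - 39 * pp**2 + 272 * pp + 64)
        return (11 * pp**2 - pp + 8 - disc) / (5 * pp**2 + 20 * pp - 16)

    def h15_h51(pp: float) -> float:
        disc = math.sqrt(73 * pp**4 - 184 * pp**3 - 192 * pp**2 + 320 * pp + 64)
        return (-8 * pp**2 - 2 * pp - 8 + disc) / (pp**2 - 26 * pp + 16)

    return {
        "h11_h55": lambda pp: pp,
        "h33_h44": lambda pp: pp,
        "h34_h43": lambda pp: 3 * pp / (4 - pp),
        "h53_h14": lambda pp: (4 * pp - 1) / 3,
        "h12_h56": lambda pp: 9 * pp / (8 + pp),
        "h31_h45": h31_h45,
        "h41_h35": h41_h35,
        "h15_h51": h15_h51,
    }


def closed_form_metrics(family: str, **params) -> dict:
    """Dispatch to the family-specific closed-form reference values."""
    if family == "partial_bipartite":
        return partial_bipartite_closed_forms(**params)
    if family == "single_link":
        return single_link_closed_forms(**params)
    raise ValueError(f"no closed-form metrics for family {family!r}")


# ---------------------------------------------------------------------------
# stationary-point search and cycle tipping points
# ---------------------------------------------------------------------------


@dataclass
class SaddleResult:
    point: tuple[float, ...]
    kind: str  # "minimum" | "maximum" | "saddle" | "degenerate"
    grad_norm: float
    hessian_eigenvalues: tuple[float, ...] = field(default_factory=tuple)


def _fd_grad(f: Callable, x: np.ndarray, h: float) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _fd_hessian(f: Callable, x: np.ndarray, h: float) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def saddle_point_search(
    objective: Callable[[Sequence[float]], float],
    box: Sequence[tuple[float, float]],
    grid: int = 4,
    gtol: float = 1e-10,
    h: float = 1e-5,
) -> list[SaddleResult]:
    """Stationary points of a smooth objective inside a box.

    Multi-start quasi-Newton (scipy hybr) on the central-difference
    gradient from a ``grid x grid`` lattice of interior starts; converged
    points with gradient norm below ``gtol`` are deduplicated and
    classified by the eigenvalues of the central-difference Hessian.
    Raises if no stationary point is found in the box.
    """
    box = [(float(a), float(b)) for a, b in box]
    k = len(box)

    def f(x):
        return float(objective(np.asarray(x, dtype=float)))

    def grad(x):
        return _fd_grad(f, np.asarray(x, dtype=float), h)

    starts = []
    axes = [
        np.linspace(a + 0.1 * (b - a), b - 0.1 * (b - a), grid) for a, b in box
    ]
    mesh = np.meshgrid(*axes)
    for idx in range(mesh[0].size):
        starts.append(np.array([m.flat[idx] for m in mesh]))

    found: list[SaddleResult] = []
    for x0 in starts:
        sol = root(grad, x0, method="hybr", tol=1e-13)
        x = sol.x
        if not all(a - 1e-9 <= xi <= b + 1e-9 for xi, (a, b) in zip(x, box)):
            continue
        gn = float(np.linalg.norm(grad(x)))
        if gn > gtol:
            continue
        if any(np.linalg.norm(x - np.array(r.point)) < 1e-6 for r in found):
            continue
        H = _fd_hessian(f, x, max(h, 1e-4))
        eigs = np.sort(np.linalg.eigvalsh(H))
        scale = max(abs(eigs).max(), 1e-12)
        if eigs[0] > 1e-6 * scale:
            kind = "minimum"
        elif eigs[-1] < -1e-6 * scale:
            kind = "maximum"
        elif eigs[0] < -1e-6 * scale < 1e-6 * scale < eigs[-1]:
            kind = "saddle"
        else:
            kind = "degenerate"
        found.append(
            SaddleResult(
                point=tuple(float(v) for v in x),
                kind=kind,
                grad_norm=gn,
                hessian_eigenvalues=tuple(float(v) for v in eigs),
            )
        )
    if not found:
        raise ValueError(
            f"no stationary point with |grad| < {gtol} found in box {box} "
            f"from {len(starts)} starts"
        )
    return found


def cycle_step_hitting_time(
    N: int, p, steps: int = 1, direction: str = "ccw"
) -> float:
    """Expected k-step hitting time around a biased cycle.

    ``direction="ccw"`` measures the hitting time from a vertex to the
    target ``steps`` positions away in increasing-index order (v1 toward
    v2), the step executed with probability ``1 - p`` under the package's
    weight convention; ``"cw"`` measures the mirrored transition (the
    ``p`` step).  By the mirror symmetry, ``h_cw(p) = h_ccw(1 - p)``, so
    the two one-step tipping points sum to 1 (0.68806 and 0.31194 for
    N = 5).
    """
    g = biased_cycle(N, p)
    M = hitting_times(g).M
    if direction == "ccw":
        target = steps % N
    elif direction == "cw":
        target = (-steps) % N
    else:
        raise ValueError("direction must be 'ccw' or 'cw'")
    return float(M[0, target])


def golden_section_max(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-6
) -> float:
    """Argmax of a unimodal scalar function by golden-section search."""
    invphi = (math.sqrt(5) - 1) / 2
    a, b = float(lo), float(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def cycle_tipping_point(
    N: int, steps: int = 1, direction: str = "ccw", tol: float = 1e-6
) -> float:
    """The p maximising the k-step hitting time of the N-cycle.

    This is the tipping point between the two rotational strategies: below
    it the direct transition is favoured, above it the walk is better off
    going the long way round.
    """
    eps = 1e-9

    def h(p: float) -> float:
        return cycle_step_hitting_time(N, p, steps=steps, direction=direction)

    return golden_section_max(h, eps, 1 - eps, tol=tol)
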