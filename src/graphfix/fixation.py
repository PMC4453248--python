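"""Birth-death fixation probabilities from the full state-space master equations.

Each step of the birth-death process picks a reproducing individual with
probability proportional to fitness (mutants have fitness ``r``, residents
1) and replaces a neighbour chosen by edge weight.  A population state is
a binary occupancy vector ``v`` over the N vertices (1 = mutant); the
probability ``x_v`` of eventual mutant fixation from state ``v`` satisfies

    [ sum_i r a_i(v) v'_i + sum_i b_i(v) v_i ] x_v
        = sum_i r a_i(v) v'_i x_{v + e_i}  +  sum_i b_i(v) v_i x_{v - e_i}

with ``a(v) = v . W`` (mutant reproductive weight into each vertex),
``b(v) = v' . W`` (resident weight), and boundary conditions ``x = 0`` at
extinction and ``x = 1`` at fixation.  Because rows of W sum to 1, the
bracket equals ``N + (r - 1) m - r a(v).v - b(v).v'`` with ``m`` the
mutant count.  That leaves ``2^N - 2`` linear equations, solved densely
here, in floats or in exact rational arithmetic.

State indexing: bit ``k - 1`` of the integer index corresponds to vertex
``k``, so a lone mutant at vertex ``k`` is state ``2^(k-1)`` -- the labels
``x_1, x_2, x_4, x_8, ...`` refer to single-mutant starts at vertices
1, 2, 3, 4, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .exact import SingularSystemError, solve_exact
from .graphs import LevelProfile, WeightedDigraph, as_fraction

__all__ = [
    "PopulationState",
    "MasterSystem",
    "FixationSolution",
    "build_master_system",
    "solve_fixation",
    "lumped_flow_fixation",
    "moran_probability",
    "bipartite_fixation_closed_form",
    "bisect_root",
    "crossing_finder",
    "flow_rho",
    "flow_moran_crossing",
    "flow_level_crossing",
    "bipartite_rho",
    "bipartite_moran_crossing",
    "bipartite_equality_q",
    "NoSignChangeError",
]

#: condition-number estimate beyond which the float solve is distrusted
COND_LIMIT = 1e12

DEFAULT_STATE_CAP = 12


@dataclass(frozen=True)
class PopulationState:
    """A binary occupancy state with its integer index and mutant count."""

    v: tuple[int, ...]

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.v):
            raise ValueError("occupancy entries must be 0 or 1")

    @classmethod
    def from_index(cls, index: int, N: int) -> "PopulationState":
        return cls(tuple((index >> k) & 1 for k in range(N)))

    @property
    def index(self) -> int:
        return sum(b << k for k, b in enumerate(self.v))

    @property
    def m(self) -> int:
        return sum(self.v)

    @property
    def complement(self) -> "PopulationState":
        return PopulationState(tuple(1 - b for b in self.v))


@dataclass
class MasterSystem:
    """Assembled interior master equations ``A x = rhs`` for one graph and r."""

    graph: WeightedDigraph
    r: object  # float or Fraction
    backend: str
    A: object  # ndarray or list of Fraction rows
    rhs: object
    states: list[int]  # interior state indices, in row order

    @property
    def dimension(self) -> int:
        return len(self.states)


@dataclass
class FixationSolution:
    """Fixation probabilities for every initial state of one graph.

    ``x`` maps the state key (integer bitmask for the full solver, level
    occupancy tuple for the lumped solver) to its fixation probability.
    ``single_vertex`` maps a 1-based vertex number (full solver) or level
    index (lumped solver) to the corresponding single-mutant probability.
    ``rho`` is the average single-vertex fixation probability, weighted by
    multiplicity where states are lumped.
    """

    x: dict
    single_vertex: dict
    rho: object
    backend: str
    meta: dict = field(default_factory=dict)

    def as_float(self) -> "FixationSolution":
        return FixationSolution(
            x={k: float(v) for k, v in self.x.items()},
            single_vertex={k: float(v) for k, v in self.single_vertex.items()},
            rho=float(self.rho),
            backend=self.backend,
            meta=self.meta,
        )


class NoSignChangeError(ValueError):
    """The comparison function has equal signs at both bracket ends."""


def _trapped_states(graph: WeightedDigraph, interior_zero_rate: list[int]) -> str:
    names = ", ".join(
        f"{s} ({PopulationState.from_index(s, graph.N).v})"
        for s in interior_zero_rate[:8]
    )
    more = "" if len(interior_zero_rate) <= 8 else ", ..."
    return (
        "master system is singular: the graph is reducible and the following "
        f"interior states cannot reach an absorbing state: {names}{more}"
    )


def build_master_system(
    graph: WeightedDigraph, r, backend: str = "float"
) -> MasterSystem:
    """Assemble the ``2^N - 2`` interior master equations.

    Boundary states (extinction, fixation) are substituted, never solved
    for: transitions into the fixation state contribute to the right-hand
    side, transitions into extinction contribute nothing.
    """
    N = graph.N
    if backend not in ("float", "rational"):
        raise ValueError(f"unknown backend {backend!r}")
    full = (1 << N) - 1
    states = list(range(1, full))
    dim = len(states)

    if backend == "float":
        r = float(r)
        if r <= 0:
            raise ValueError("fitness r must be positive")
        W = graph.W
        A = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        zero_rate = []
        for row, S in enumerate(states):
            v = np.array([(S >> k) & 1 for k in range(N)], dtype=float)
            a = v @ W
            b = (1.0 - v) @ W
            gains = r * a * (1.0 - v)
            losses = b * v
            total = gains.sum() + losses.sum()
            if total == 0.0:
                zero_rate.append(S)
                continue
            A[row, row] = total
            for i in range(N):
                if gains[i] > 0.0:
                    tgt = S | (1 << i)
                    if tgt == full:
                        rhs[row] += gains[i]
                    else:
                        A[row, tgt - 1] -= gains[i]
                if losses[i] > 0.0:
                    tgt = S & ~(1 << i)
                    if tgt != 0:
                        A[row, tgt - 1] -= losses[i]
        if zero_rate:
            raise SingularSystemError(_trapped_states(graph, zero_rate))
        return MasterSystem(graph, r, backend, A, rhs, states)

    # exact rational assembly
    r = as_fraction(r)
    if r <= 0:
        raise ValueError("fitness r must be positive")
    Wx = graph.W_exact
    zero = Fraction(0)
    A = [[zero] * dim for _ in range(dim)]
    rhs = [zero] * dim
    zero_rate = []
    for row, S in enumerate(states):
        bits = [(S >> k) & 1 for k in range(N)]
        a = [sum(Wx[j][i] for j in range(N) if bits[j]) for i in range(N)]
        b = [sum(Wx[j][i] for j in range(N) if not bits[j]) for i in range(N)]
        total = zero
        for i in range(N):
            if not bits[i] and a[i] != 0:
                g = r * a[i]
                total += g
                tgt = S | (1 << i)
                if tgt == full:
                    rhs[row] += g
                else:
                    A[row][tgt - 1] -= g
            if bits[i] and b[i] != 0:
                total += b[i]
                tgt = S & ~(1 << i)
                if tgt != 0:
                    A[row][tgt - 1] -= b[i]
        if total == 0:
            zero_rate.append(S)
            continue
        A[row][row] = total
    if zero_rate:
        raise SingularSystemError(_trapped_states(graph, zero_rate))
    return MasterSystem(graph, r, backend, A, rhs, states)


def solve_fixation(
    graph: WeightedDigraph,
    r,
    backend: str = "float",
    state_cap: int = DEFAULT_STATE_CAP,
) -> FixationSolution:
    """Solve the full master system for all ``2^N`` fixation probabilities."""
    N = graph.N
    if N > state_cap:
        raise ValueError(
            f"N = {N} exceeds the full-state-space cap ({state_cap}); "
            "for dual circular flows use lumped_flow_fixation instead"
        )
    system = build_master_system(graph, r, backend)
    full = (1 << N) - 1
    if backend == "float":
        try:
            sol = np.linalg.solve(system.A, system.rhs)
        except np.linalg.LinAlgError as err:
            raise SingularSystemError(
                "float master system is singular (graph likely reducible); "
                f"numpy says: {err}"
            ) from None
        cond = np.linalg.cond(system.A) if system.dimension <= 256 else None
        if cond is not None and cond > COND_LIMIT:
            raise SingularSystemError(
                f"master system is numerically singular (cond ~ {cond:.3g}); "
                "use the rational backend or check graph parameters"
            )
        x = {0: 0.0, full: 1.0}
        one = 1.0
    else:
        sol = solve_exact(system.A, system.rhs)
        x = {0: Fraction(0), full: Fraction(1)}
        one = Fraction(1)
    for row, S in enumerate(system.states):
        x[S] = sol[row]
    single = {k: x[1 << (k - 1)] for k in range(1, N + 1)}
    rho = sum(single.values()) / N
    _ = one
    return FixationSolution(
        x=x,
        single_vertex=single,
        rho=rho,
        backend=backend,
        meta={"N": N, "r": r, "family": graph.family, "params": graph.params},
    )


# ---------------------------------------------------------------------------
# lumped solver for dual circular flows with uniform p
# ---------------------------------------------------------------------------


def lumped_flow_fixation(
    profile: LevelProfile | Sequence[int],
    r,
    p=None,
    backend: str = "float",
) -> FixationSolution:
    """Fixation probabilities of a uniform-p dual circular flow, lumped by level.

    Vertices within a level are exchangeable, so the state space reduces to
    occupancy vectors ``m = (m_0, ..., m_k)`` with ``0 <= m_i <= n_i``:
    ``prod(n_i + 1) - 2`` interior unknowns instead of ``2^N - 2``.  In one
    step the mutant count of level ``s`` rises by one with probability
    weight ``r (n_s - m_s)[m_{s+1} p + m_{s-1}(1 - p)] / n_s`` and falls
    with weight ``m_s [(n_{s+1} - m_{s+1}) p + (n_{s-1} - m_{s-1})(1 - p)] / n_s``.

    Accepts either a LevelProfile with uniform weights or ``(sizes, r, p)``.
    """
    if isinstance(profile, LevelProfile):
        if not profile.is_uniform:
            raise ValueError(
                "the lumped solver requires a uniform per-level weight; "
                "use solve_fixation on the full graph for tuned flows"
            )
        sizes = profile.sizes
        p = profile.weights[0]
    else:
        if p is None:
            raise ValueError("p is required when sizes are given directly")
        sizes = tuple(int(n) for n in profile)
        p = as_fraction(p)

    L = len(sizes)
    N = sum(sizes)
    exact = backend == "rational"
    if exact:
        r = as_fraction(r)
        pv = as_fraction(p)
        zero = Fraction(0)
    else:
        r = float(r)
        pv = float(p)
        zero = 0.0
    if r <= 0:
        raise ValueError("fitness r must be positive")

    dims = tuple(n + 1 for n in sizes)
    all_states = [tuple(m) for m in np.ndindex(*dims)]
    fixed = tuple(sizes)
    extinct = tuple(0 for _ in sizes)
    interior = [m for m in all_states if m != extinct and m != fixed]
    idx = {m: i for i, m in enumerate(interior)}
    dim = len(interior)

    if exact:
        A = [[zero] * dim for _ in range(dim)]
        rhs = [zero] * dim
    else:
        A = np.zeros((dim, dim))
        rhs = np.zeros(dim)

    zero_rate = []
    for row, m in enumerate(interior):
        total = zero
        for s in range(L):
            up, dn = (s + 1) % L, (s - 1) % L
            inc = (
                r
                * (sizes[s] - m[s])
                * (m[up] * pv + m[dn] * (1 - pv))
                / sizes[s]
            )
            dec = (
                m[s]
                * ((sizes[up] - m[up]) * pv + (sizes[dn] - m[dn]) * (1 - pv))
                / sizes[s]
            )
            if inc != 0:
                total += inc
                tgt = tuple(mm + (1 if t == s else 0) for t, mm in enumerate(m))
                if tgt == fixed:
                    rhs[row] += inc
                else:
                    A[row][idx[tgt]] -= inc
            if dec != 0:
                total += dec
                tgt = tuple(mm - (1 if t == s else 0) for t, mm in enumerate(m))
                if tgt != extinct:
                    A[row][idx[tgt]] -= dec
        if total == 0:
            zero_rate.append(m)
            continue
        A[row][row] = total
    if zero_rate:
        raise SingularSystemError(
            "lumped master system is singular; trapped occupancy states: "
            + ", ".join(map(str, zero_rate[:8]))
        )

    if exact:
        sol = solve_exact(A, rhs)
        x = {extinct: Fraction(0), fixed: Fraction(1)}
    else:
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise SingularSystemError(f"lumped system singular: {err}") from None
        x = {extinct: 0.0, fixed: 1.0}
    for row, m in enumerate(interior):
        x[m] = sol[row]

    single = {}
    for lvl in range(L):
        e = tuple(1 if t == lvl else 0 for t in range(L))
        single[lvl] = x[e]
    rho = sum(sizes[lvl] * single[lvl] for lvl in range(L)) / N
    return FixationSolution(
        x=x,
        single_vertex=single,
        rho=rho,
        backend=backend,
        meta={"sizes": sizes, "p": p, "r": r, "lumped": True},
    )


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def moran_probability(N: int, r, k: int = 1):
    """k-mutant fixation probability on the complete graph.

    ``rho_{M,k} = (r^{N-1} + ... + r^{N-k}) / (1 + r + ... + r^{N-1})``;
    ``k = 1`` is the classic single-mutant Moran probability
    ``(1 - 1/r) / (1 - 1/r^N)``.  ``r = 1`` gives the neutral value k/N.
    Exact if ``r`` is a Fraction or int.
    """
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    exact = isinstance(r, (int, Fraction)) or isinstance(r, str)
    r = as_fraction(r) if exact else float(r)
    if r <= 0:
        raise ValueError("fitness r must be positive")
    if r == 1:
        return Fraction(k, N) if exact else k / N
    num = sum(r ** (N - j) for j in range(1, k + 1))
    den = sum(r**j for j in range(N))
    return num / den


def bipartite_fixation_closed_form(s: int, n: int, r):
    """Single-mutant fixation probability on the complete bipartite graph K_{s,n}.

    Evaluates the closed form

        rho = r^(n+s-1) (snr + n^2 - sn + s^2) (nr + s)^(n-s-1) (r^2 - 1)
              / [ (sr + n) ( r^(n+s) (nr + s)^(n-s) - (sr + n)^(n-s) ) ]

    which reduces to the Moran probability at ``s = n`` and to ``1/(s+n)``
    at ``r = 1`` (taken as the analytic limit).  The formula is validated
    against the exact master-equation solver in the test suite.
    """
    if s < 1 or n < 1:
        raise ValueError("component sizes must be >= 1")
    exact = isinstance(r, (int, Fraction, str))
    r = as_fraction(r) if exact else float(r)
    if r <= 0:
        raise ValueError("fitness r must be positive")
    if r == 1:
        return Fraction(1, s + n) if exact else 1.0 / (s + n)
    num = (
        r ** (n + s - 1)
        * (s * n * r + n * n - s * n + s * s)
        * (n * r + s) ** (n - s - 1)
        * (r * r - 1)
    )
    den = (s * r + n) * (
        r ** (n + s) * (n * r + s) ** (n - s) - (s * r + n) ** (n - s)
    )
    return num / den


# ---------------------------------------------------------------------------
# crossing finders
# ---------------------------------------------------------------------------


def bisect_root(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = 1e-7,
    maxiter: int = 200,
) -> float:
    """Bisection root of a scalar sign-changing function on [lo, hi]."""
    flo, fhi = float(f(lo)), float(f(hi))
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if (flo > 0) == (fhi > 0):
        raise NoSignChangeError(
            f"no sign change on [{lo}, {hi}]: f(lo) = {flo:.6g}, f(hi) = {fhi:.6g}"
        )
    for _ in range(maxiter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        fm = float(f(mid))
        if fm == 0.0:
            return mid
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
    return 0.5 * (lo + hi)


def crossing_finder(
    comparison: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float = 1e-7,
) -> float:
    """Locate the zero of a scalar comparison function by bisection.

    ``comparison`` is typically a difference of fixation probabilities as a
    function of fitness ``r`` or of a weight parameter.  Raises
    :class:`NoSignChangeError` when the bracket does not straddle a root.
    """
    lo, hi = bracket
    return bisect_root(comparison, float(lo), float(hi), tol=tol)


def flow_rho(sizes: Sequence[int], p, r) -> float:
    """Multiplicity-weighted average single-vertex fixation of a uniform flow."""
    return float(lumped_flow_fixation(tuple(sizes), r, p=p).rho)


def flow_moran_crossing(
    sizes: Sequence[int],
    p,
    bracket: tuple[float, float] = (1.01, 20.0),
    tol: float = 1e-5,
) -> float:
    """Fitness at which the flow's average fixation crosses the Moran value."""
    N = sum(sizes)

    def diff(r: float) -> float:
        return flow_rho(sizes, p, r) - float(moran_probability(N, float(r)))

    return crossing_finder(diff, bracket, tol=tol)


def flow_level_crossing(
    sizes: Sequence[int],
    p,
    level_a: int,
    level_b: int,
    bracket: tuple[float, float] = (1.5, 10.0),
    tol: float = 1e-5,
) -> float:
    """Fitness at which single-vertex fixation from two levels coincides."""

    def diff(r: float) -> float:
        sol = lumped_flow_fixation(tuple(sizes), r, p=p)
        return float(sol.single_vertex[level_a] - sol.single_vertex[level_b])

    return crossing_finder(diff, bracket, tol=tol)


def bipartite_rho(s: int, n: int, p, q, r, eps: float = 1e-5) -> float:
    """Average single-vertex fixation of the (s, n) partial bipartite graph.

    At the endpoints ``p = 1`` or ``q = 1`` one block stops receiving any
    reproductive weight and the master system is singular: some states
    never absorb, and the strict hitting probability of fixation jumps
    discontinuously to zero from most starts.  The analytically meaningful
    quantity there is the limit of the solution along the parameter, which
    this function computes by Richardson extrapolation (solutions are
    rational in p and q, so ``2 f(1 - eps) - f(1 - 2 eps)`` carries an
    O(eps^2) error).  Interior parameter values are solved directly.
    """
    from .graphs import partial_bipartite

    pf, qf = float(as_fraction(p)), float(as_fraction(q))
    if pf < 1.0 and qf < 1.0:
        return float(solve_fixation(partial_bipartite(s, n, p, q), r).rho)

    def at(e: float) -> float:
        pp = min(pf, 1.0 - e)
        qq = min(qf, 1.0 - e)
        return float(solve_fixation(partial_bipartite(s, n, pp, qq), r).rho)

    return 2.0 * at(eps) - at(2.0 * eps)


def bipartite_moran_crossing(
    s: int,
    n: int,
    p,
    q,
    bracket: tuple[float, float] = (1.05, 20.0),
    tol: float = 1e-5,
    rational_guard: float = 1e-12,
) -> float:
    """Fitness where the partial bipartite average fixation re-crosses Moran.

    If a float evaluation lands within ``rational_guard`` of zero its sign
    is recomputed with the exact rational backend (at the binary-exact
    rational value of the evaluation point) before it is trusted.  Endpoint
    parameters (p or q equal to 1) are handled by the analytic-continuation
    rule of :func:`bipartite_rho`.
    """
    from .graphs import partial_bipartite

    N = s + n
    endpoint = float(as_fraction(p)) >= 1.0 or float(as_fraction(q)) >= 1.0

    def exact_sign(r: float) -> float:
        rx = as_fraction(float(r))
        if endpoint:
            # exact Richardson step at rational offsets from the endpoint
            e = Fraction(1, 100000)
            vals = []
            for ee in (e, 2 * e):
                pp = min(as_fraction(p), 1 - ee)
                qq = min(as_fraction(q), 1 - ee)
                g = partial_bipartite(s, n, pp, qq)
                vals.append(solve_fixation(g, rx, backend="rational").rho)
            dx = 2 * vals[0] - vals[1] - moran_probability(N, rx)
        else:
            g = partial_bipartite(s, n, p, q)
            dx = solve_fixation(g, rx, backend="rational").rho - moran_probability(
                N, rx
            )
        if dx == 0:
            return 0.0
        return rational_guard if dx > 0 else -rational_guard

    def diff(r: float) -> float:
        d = bipartite_rho(s, n, p, q, r) - float(moran_probability(N, float(r)))
        if abs(d) < rational_guard:
            return exact_sign(r)
        return d

    return crossing_finder(diff, bracket, tol=tol)


def bipartite_equality_q(
    s: int,
    n: int,
    p,
    r,
    bracket: tuple[float, float] = (1e-6, 1 - 1e-6),
    tol: float = 1e-9,
) -> float:
    """The weight q at which single-mutant fixation from the two blocks is equal.

    Compares ``x`` for a lone mutant in the s-block against one in the
    n-block of the (s, n) partial bipartite graph at fixed ``p`` and ``r``.
    """
    from .graphs import partial_bipartite

    def diff(q: float) -> float:
        sol = solve_fixation(partial_bipartite(s, n, p, q), r)
        return float(sol.single_vertex[1] - sol.single_vertex[s + 1])

    return crossing_finder(diff, bracket, tol=tol)
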