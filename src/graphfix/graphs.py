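"""Weighted digraph families for structured-population models.

A population of N individuals is a directed graph whose edge weight
``w_ij`` is the probability that vertex ``i``'s offspring replaces vertex
``j`` in one birth-death step, so every row of the weight matrix W sums
to 1.  Four parametric families are provided:

* **biased cycles** -- an N-cycle with probability ``p`` in one rotational
  direction and ``1 - p`` in the other (always doubly stochastic);
* **dual circular flows** -- a ring of vertex *levels* of sizes
  ``(n_0, ..., n_k)`` with edges only between adjacent levels; a vertex at
  level ``i`` spreads weight ``p_i`` uniformly over level ``i-1`` (mod
  ``k+1``) and ``1 - p_i`` over level ``i+1``;
* **partial bipartite graphs** -- two internally complete blocks of sizes
  ``s`` and ``n`` with internal weights ``p/(s-1)``, ``q/(n-1)`` and
  all-to-all cross weights ``(1-p)/n``, ``(1-q)/s``;
* **single-link graphs** -- two internally complete components coupled by
  one directed edge in each direction through a linking vertex per side.

All constructors build the weight matrix in exact rational arithmetic
(:class:`fractions.Fraction`), so row sums are exactly 1 and downstream
exact solvers can run without rounding.  A float view is always available.

Direction convention for flows: ``p_i`` is the probability of propagating
toward the *lower*-index level (mod ``k+1``), so a uniform ``p = 1`` flow
is the funnel (everything drains toward level 0) and ``p = 0`` is the
cascade.  The biased cycle uses the same convention: ``w[i][i-1] = p``.
With vertices drawn clockwise by increasing index, ``p`` is the
counter-clockwise transition probability.  This makes a cycle exactly the
unit-level-size flow, entry by entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence, Union

import numpy as np

__all__ = [
    "WeightedDigraph",
    "LevelProfile",
    "biased_cycle",
    "dual_circular_flow",
    "partial_bipartite",
    "single_link",
    "generic_graph",
    "as_fraction",
]

Numberlike = Union[int, float, str, Fraction]

#: tolerance on float row sums for generic matrices
ROW_SUM_TOL = 1e-12


def as_fraction(x: Numberlike) -> Fraction:
    """Convert a number to an exact Fraction.

    Strings may be ``"2/3"`` or decimal (parsed as exact decimals);
    floats convert to their exact binary value.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, str):
        return Fraction(x)
    return Fraction(x)


def _check_probability(name: str, x: Fraction) -> None:
    if not 0 <= x <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


class WeightedDigraph:
    """An N-vertex digraph with a row-stochastic edge-weight matrix.

    Parameters
    ----------
    W_exact
        N x N nested sequence of Fractions (or things convertible to
        Fraction).  Rows must sum to 1 (exactly, or within ``ROW_SUM_TOL``
        in float for generic input).
    family
        One of ``cycle``, ``flow``, ``partial_bipartite``, ``single_link``,
        ``generic``.
    params
        Family parameters used to build the matrix.
    vertex_labels
        Ordered 1-based labels; defaults to ``v1 .. vN``.
    """

    def __init__(
        self,
        W_exact: Sequence[Sequence[Numberlike]],
        family: str = "generic",
        params: dict | None = None,
        vertex_labels: Sequence[str] | None = None,
    ):
        rows = [[as_fraction(x) for x in row] for row in W_exact]
        N = len(rows)
        if N < 2:
            raise ValueError("a population graph needs at least 2 vertices")
        if any(len(row) != N for row in rows):
            raise ValueError("weight matrix must be square")
        bad = []
        for i, row in enumerate(rows):
            if any(x < 0 or x > 1 for x in row):
                raise ValueError(f"row {i + 1}: weights must lie in [0, 1]")
            if sum(row) != 1:
                if abs(float(sum(row)) - 1.0) > ROW_SUM_TOL:
                    bad.append((i + 1, float(sum(row))))
        if bad:
            detail = ", ".join(f"row {i} sums to {s:.17g}" for i, s in bad)
            raise ValueError(f"weight matrix is not row-stochastic: {detail}")

        self.W_exact: list[list[Fraction]] = rows
        self.W: np.ndarray = np.array(
            [[float(x) for x in row] for row in rows], dtype=float
        )
        self.family = family
        self.params = dict(params or {})
        if vertex_labels is None:
            vertex_labels = [f"v{i + 1}" for i in range(N)]
        if len(vertex_labels) != N:
            raise ValueError("vertex_labels length must equal N")
        self.vertex_labels = list(vertex_labels)
        self.has_self_loops = any(rows[i][i] != 0 for i in range(N))

    # -- basic properties -------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.W_exact)

    def column_sums_exact(self) -> list[Fraction]:
        """Exact column sums (the vertex temperatures)."""
        N = self.N
        return [sum(self.W_exact[i][j] for i in range(N)) for j in range(N)]

    def is_doubly_stochastic(self, exact: bool = True) -> bool:
        if exact:
            return all(c == 1 for c in self.column_sums_exact())
        return bool(np.allclose(self.W.sum(axis=0), 1.0, atol=ROW_SUM_TOL))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeightedDigraph(N={self.N}, family={self.family!r}, "
            f"params={self.params!r})"
        )


@dataclass(frozen=True)
class LevelProfile:
    """Level sizes and per-level back-propagation weights of a flow.

    ``sizes = (n_0, ..., n_k)`` are the level populations and
    ``weights = (p_0, ..., p_k)`` the probabilities that a level-``i``
    vertex propagates toward level ``i-1`` (mod ``k+1``).
    """

    sizes: tuple[int, ...]
    weights: tuple[Fraction, ...]

    def __post_init__(self):
        if len(self.sizes) < 2:
            raise ValueError("a flow needs at least 2 levels")
        if any(int(n) != n or n < 1 for n in self.sizes):
            raise ValueError("level sizes must be positive integers")
        if len(self.weights) != len(self.sizes):
            raise ValueError("need one weight per level")
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))
        object.__setattr__(
            self, "weights", tuple(as_fraction(p) for p in self.weights)
        )
        for p in self.weights:
            _check_probability("level weight", p)

    @classmethod
    def uniform(cls, sizes: Sequence[int], p: Numberlike) -> "LevelProfile":
        sizes = tuple(int(n) for n in sizes)
        return cls(sizes, tuple(as_fraction(p) for _ in sizes))

    @property
    def N(self) -> int:
        return sum(self.sizes)

    @property
    def levels(self) -> int:
        return len(self.sizes)

    @property
    def is_uniform(self) -> bool:
        return len(set(self.weights)) == 1


def biased_cycle(N: int, p: Numberlike) -> WeightedDigraph:
    """Biased cycle on ``N >= 3`` vertices.

    ``w[i][(i-1) mod N] = p`` and ``w[i][(i+1) mod N] = 1 - p``; the matrix
    is doubly stochastic.  ``N = 3`` is the smallest non-degenerate cycle
    (for ``N = 2`` both neighbours coincide).
    """
    if N < 3:
        raise ValueError("biased cycle needs N >= 3 (a 2-cycle degenerates)")
    p = as_fraction(p)
    _check_probability("p", p)
    W = [[Fraction(0)] * N for _ in range(N)]
    for i in range(N):
        W[i][(i - 1) % N] += p
        W[i][(i + 1) % N] += 1 - p
    return WeightedDigraph(W, family="cycle", params={"N": N, "p": p})


def dual_circular_flow(profile: LevelProfile) -> WeightedDigraph:
    """Dual circular flow over a :class:`LevelProfile`.

    Each vertex at level ``i`` sends ``p_i / n_{i-1}`` to every vertex of
    level ``i-1`` (mod ``k+1``) and ``(1 - p_i) / n_{i+1}`` to every vertex
    of level ``i+1``; there are no intra-level edges.  Vertices are ordered
    level 0 first.  For a two-level profile the two directions target the
    same level and the weights accumulate (the complete bipartite case).
    """
    L = profile.levels
    sizes = profile.sizes
    N = profile.N
    offsets = np.cumsum([0] + list(sizes))
    W = [[Fraction(0)] * N for _ in range(N)]
    for lvl in range(L):
        p = profile.weights[lvl]
        down, up = (lvl - 1) % L, (lvl + 1) % L
        for i in range(offsets[lvl], offsets[lvl + 1]):
            if p > 0:
                for j in range(offsets[down], offsets[down + 1]):
                    W[i][j] += p / sizes[down]
            if p < 1:
                for j in range(offsets[up], offsets[up + 1]):
                    W[i][j] += (1 - p) / sizes[up]
    return WeightedDigraph(
        W,
        family="flow",
        params={"sizes": sizes, "weights": profile.weights},
    )


def partial_bipartite(
    s: int, n: int, p: Numberlike, q: Numberlike
) -> WeightedDigraph:
    """Partial bipartite graph on blocks of sizes ``s`` and ``n``.

    Within the first block every ordered pair carries weight ``p/(s-1)``,
    within the second ``q/(n-1)``; cross weights are ``(1-p)/n`` from the
    first block and ``(1-q)/s`` from the second.  ``p = q = 0`` is the
    complete bipartite graph K_{s,n}.  Block V_s comes first.
    """
    p, q = as_fraction(p), as_fraction(q)
    _check_probability("p", p)
    _check_probability("q", q)
    if s < 1 or n < 1:
        raise ValueError("block sizes must be >= 1")
    if s == 1 and p != 0:
        raise ValueError("s = 1 requires p = 0 (internal weight divides by s - 1)")
    if n == 1 and q != 0:
        raise ValueError("n = 1 requires q = 0 (internal weight divides by n - 1)")
    N = s + n
    W = [[Fraction(0)] * N for _ in range(N)]
    for i in range(s):
        for j in range(s):
            if i != j:
                W[i][j] = p / (s - 1)
        for j in range(s, N):
            W[i][j] = (1 - p) / n
    for i in range(s, N):
        for j in range(s, N):
            if i != j:
                W[i][j] = q / (n - 1)
        for j in range(s):
            W[i][j] = (1 - q) / s
    return WeightedDigraph(
        W, family="partial_bipartite", params={"s": s, "n": n, "p": p, "q": q}
    )


def single_link(s: int, n: int, p: Numberlike, q: Numberlike) -> WeightedDigraph:
    """Single-link graph: two complete components joined through one vertex each.

    Vertex order: the ``s - 1`` non-linking vertices of the first component,
    its linking vertex, the second component's linking vertex, then the
    ``n - 1`` non-linking vertices of the second component.  Non-linking
    vertices spread weight ``1/(s-1)`` (resp. ``1/(n-1)``) over the other
    vertices of their component; the linking vertex keeps ``p/(s-1)`` per
    internal edge (resp. ``q/(n-1)``) and sends ``1 - p`` (resp. ``1 - q``)
    across the link.
    """
    p, q = as_fraction(p), as_fraction(q)
    _check_probability("p", p)
    _check_probability("q", q)
    if s < 2 or n < 2:
        raise ValueError("single-link components need s, n >= 2")
    N = s + n
    link_s, link_n = s - 1, s  # 0-based positions of the two linking vertices
    comp_s = list(range(s))
    comp_n = list(range(s, N))
    W = [[Fraction(0)] * N for _ in range(N)]
    for i in comp_s:
        if i == link_s:
            for j in comp_s:
                if j != i:
                    W[i][j] = p / (s - 1)
            W[i][link_n] = 1 - p
        else:
            for j in comp_s:
                if j != i:
                    W[i][j] = Fraction(1, s - 1)
    for i in comp_n:
        if i == link_n:
            for j in comp_n:
                if j != i:
                    W[i][j] = q / (n - 1)
            W[i][link_s] = 1 - q
        else:
            for j in comp_n:
                if j != i:
                    W[i][j] = Fraction(1, n - 1)
    return WeightedDigraph(
        W, family="single_link", params={"s": s, "n": n, "p": p, "q": q}
    )


def generic_graph(
    W: Sequence[Sequence[Numberlike]] | np.ndarray,
    vertex_labels: Sequence[str] | None = None,
) -> WeightedDigraph:
    """Wrap an arbitrary row-stochastic matrix as a WeightedDigraph."""
    if isinstance(W, np.ndarray):
        W = W.tolist()
    return WeightedDigraph(W, family="generic", vertex_labels=vertex_labels)
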