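"""Vertex temperatures and temperature-profile tuning for circular flows.

The *temperature* of a vertex is its total incoming edge weight (column
sum of W): hot vertices are replaced often.  In a generalized dual
circular flow with level sizes ``(n_0, ..., n_k)`` and per-level weights
``p_i`` (probability of propagating toward level ``i - 1``), every vertex
at level ``i`` has temperature

    t_i = [ n_{i+1} p_{i+1} + n_{i-1} (1 - p_{i-1}) ] / n_i     (mod k+1)

Tuning inverts this: given target temperatures ``t`` the weights must
satisfy the cyclic linear system ``n_{i+1} p_{i+1} - n_{i-1} p_{i-1} =
t_i n_i - n_{i-1}``.  With an odd number of levels the system couples all
weights into a single chain and the solution is a one-parameter affine
family; with an even number it splits into two independent alternating
chains (two parameters), each subject to a sum consistency condition.
All algebra is exact rational; feasibility intervals (keeping every
``p_i`` in [0, 1]) have exact Fraction endpoints.

A graph tuned to the flat profile ``t = 1`` is doubly stochastic and by
the isothermal theorem has the Moran fixation probability; matching any
other profile does *not* pin down fixation (distinct members of the same
family generally fix at different rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .exact import rref
from .graphs import LevelProfile, WeightedDigraph, as_fraction, dual_circular_flow

__all__ = [
    "TuningInfeasibleError",
    "TuningSolution",
    "temperatures",
    "flow_temperatures",
    "tune_profile",
    "isothermal_tuning",
]


class TuningInfeasibleError(ValueError):
    """No weights in [0,1]^L can realise the requested temperature profile."""


def temperatures(graph: WeightedDigraph) -> list[Fraction]:
    """Per-vertex temperatures (exact column sums of W)."""
    return graph.column_sums_exact()


def flow_temperatures(profile: LevelProfile) -> list[Fraction]:
    """Per-level temperatures of a flow from the closed form."""
    L = profile.levels
    n = profile.sizes
    p = profile.weights
    return [
        (n[(i + 1) % L] * p[(i + 1) % L] + n[(i - 1) % L] * (1 - p[(i - 1) % L]))
        / Fraction(n[i])
        for i in range(L)
    ]


@dataclass
class TuningSolution:
    """Affine family of per-level weights matching a temperature profile.

    ``p_i = base[i] + sum_m coeffs[i][m] * f_m`` over the free parameters
    ``f_m`` (the weights at the level indices in ``free``, chosen as the
    highest-index weight of each decoupled chain).  ``feasible[m]`` is the
    exact closed interval of ``f_m`` keeping every dependent weight in
    [0, 1]; an empty family raises at construction instead.
    """

    sizes: tuple[int, ...]
    t: tuple[Fraction, ...]
    free: tuple[int, ...]
    base: tuple[Fraction, ...]
    coeffs: tuple[tuple[Fraction, ...], ...]  # L x len(free)
    feasible: dict[int, tuple[Fraction, Fraction]] = field(default_factory=dict)

    @property
    def is_unique(self) -> bool:
        return all(lo == hi for lo, hi in self.feasible.values())

    def weights(self, values: dict[int, object] | None = None) -> tuple[Fraction, ...]:
        """Concrete per-level weights for given free-parameter values.

        ``values`` maps a free level index to its weight; omitted free
        parameters default to the midpoint of their feasibility interval.
        """
        values = dict(values or {})
        fvals = []
        for m, idx in enumerate(self.free):
            lo, hi = self.feasible[idx]
            v = as_fraction(values.pop(idx, (lo + hi) / 2))
            if not lo <= v <= hi:
                raise TuningInfeasibleError(
                    f"p_{idx} = {v} outside feasibility interval [{lo}, {hi}]"
                )
            fvals.append(v)
        if values:
            raise ValueError(f"unknown free level indices: {sorted(values)}")
        return tuple(
            self.base[i] + sum(self.coeffs[i][m] * fvals[m] for m in range(len(fvals)))
            for i in range(len(self.sizes))
        )

    def graph(self, values: dict[int, object] | None = None) -> WeightedDigraph:
        return dual_circular_flow(LevelProfile(self.sizes, self.weights(values)))


def tune_profile(sizes: Sequence[int], t: Sequence) -> TuningSolution:
    """Solve for per-level weights matching a target temperature profile.

    Raises :class:`TuningInfeasibleError` when the profile is inconsistent
    (total temperature-weighted mass must equal N since all rows of W sum
    to 1), when an even level count violates the alternating-chain sum
    conditions, or when the affine family never enters the box [0, 1]^L
    (the certificate names the violated bound).
    """
    sizes = tuple(int(x) for x in sizes)
    L = len(sizes)
    if L < 2:
        raise ValueError("need at least two levels")
    t = tuple(as_fraction(x) for x in t)
    if len(t) != L:
        raise ValueError("need one temperature per level")
    if any(x < 0 for x in t):
        raise ValueError("temperatures must be nonnegative")
    N = sum(sizes)
    mass = sum(ti * ni for ti, ni in zip(t, sizes))
    if mass != N:
        raise TuningInfeasibleError(
            f"inconsistent profile: sum(t_i n_i) = {mass} but must equal N = {N} "
            "(every row of W sums to 1)"
        )

    # cyclic system n_{i+1} p_{i+1} - n_{i-1} p_{i-1} = t_i n_i - n_{i-1}
    rows = []
    for i in range(L):
        row = [Fraction(0)] * (L + 1)
        row[(i + 1) % L] += Fraction(sizes[(i + 1) % L])
        row[(i - 1) % L] -= Fraction(sizes[(i - 1) % L])
        row[L] = t[i] * sizes[i] - sizes[(i - 1) % L]
        rows.append(row)
    red, pivots = rref(rows)
    if L in pivots:
        # a 0 = 1 row: the alternating-chain sum conditions fail
        raise TuningInfeasibleError(
            "structurally infeasible profile: the alternating level chains "
            "impose sum conditions this (sizes, t) pair violates"
        )
    free = tuple(j for j in range(L) if j not in pivots)
    base = [Fraction(0)] * L
    coeffs = [[Fraction(0)] * len(free) for _ in range(L)]
    for m, j in enumerate(free):
        coeffs[j][m] = Fraction(1)
    for rrow, c in zip(red, pivots):
        base[c] = rrow[L]
        for m, j in enumerate(free):
            coeffs[c][m] = -rrow[j]

    # feasibility: every p_i in [0, 1]; families arising from the cyclic
    # system are decoupled (each p_i depends on at most one free weight)
    for i in range(L):
        dep = [m for m in range(len(free)) if coeffs[i][m] != 0]
        if len(dep) > 1:
            raise NotImplementedError(
                "coupled feasibility region (a p depends on several free "
                "parameters); not produced by cyclic temperature systems"
            )
        if not dep and not 0 <= base[i] <= 1:
            raise TuningInfeasibleError(
                f"p_{i} is forced to {base[i]}, outside [0, 1]"
            )
    feasible: dict[int, tuple[Fraction, Fraction]] = {}
    for m, j in enumerate(free):
        lo, hi = Fraction(0), Fraction(1)
        lo_src, hi_src = f"p_{j} >= 0", f"p_{j} <= 1"
        for i in range(L):
            a = coeffs[i][m]
            if a == 0:
                continue
            b0 = (0 - base[i]) / a
            b1 = (1 - base[i]) / a
            lo_i, hi_i = min(b0, b1), max(b0, b1)
            if lo_i > lo:
                lo, lo_src = lo_i, f"p_{i} in [0, 1]"
            if hi_i < hi:
                hi, hi_src = hi_i, f"p_{i} in [0, 1]"
        if lo > hi:
            raise TuningInfeasibleError(
                f"empty feasibility interval for free weight p_{j}: "
                f"{lo_src} requires p_{j} >= {lo} but {hi_src} requires "
                f"p_{j} <= {hi}"
            )
        feasible[j] = (lo, hi)

    return TuningSolution(
        sizes=sizes,
        t=t,
        free=free,
        base=tuple(base),
        coeffs=tuple(tuple(row) for row in coeffs),
        feasible=feasible,
    )


def isothermal_tuning(sizes: Sequence[int]) -> TuningSolution:
    """Weights giving the flat temperature profile t = 1 (doubly stochastic W).

    Any concrete member of the returned family is fixation-equivalent to
    the complete graph (Moran probability), by the isothermal theorem.
    """
    sizes = tuple(int(x) for x in sizes)
    return tune_profile(sizes, tuple(Fraction(1) for _ in sizes))
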