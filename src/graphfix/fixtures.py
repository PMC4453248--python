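"""Seeded random graph fixtures, exact by construction.

Used by the property-test suites (notably the isothermal-theorem suite:
every doubly stochastic weight matrix fixes at the Moran probability) and
available from the CLI for ad-hoc experiments.  Matrices are built from
random integers and exact Fraction division, so row (and, for the doubly
stochastic kind, column) sums are exactly 1.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .graphs import WeightedDigraph

__all__ = ["fixture_graph"]

FIXTURE_CAP = 10


def _derangement(rng: np.random.Generator, N: int) -> np.ndarray:
    while True:
        perm = rng.permutation(N)
        if not np.any(perm == np.arange(N)):
            return perm


def fixture_graph(kind: str, N: int, seed: int) -> WeightedDigraph:
    """A seeded random row- or doubly stochastic graph with zero diagonal.

    ``kind="row_stochastic"``: positive random integer rows, each divided
    by its exact sum.  ``kind="doubly_stochastic"``: a convex combination
    of ``2 N`` random derangement permutation matrices with exact rational
    weights (a Birkhoff-style construction), so both marginals are exactly
    1.  Deterministic for a given seed.
    """
    if N < 2 or N > FIXTURE_CAP:
        raise ValueError(f"fixture graphs support 2 <= N <= {FIXTURE_CAP}")
    rng = np.random.default_rng(seed)
    if kind == "row_stochastic":
        raw = rng.integers(1, 1000, size=(N, N))
        rows = []
        for i in range(N):
            vals = [Fraction(int(raw[i, j])) for j in range(N)]
            vals[i] = Fraction(0)
            total = sum(vals)
            rows.append([v / total for v in vals])
    elif kind == "doubly_stochastic":
        k = 2 * N
        weights_raw = [int(x) for x in rng.integers(1, 1000, size=k)]
        total = sum(weights_raw)
        coeffs = [Fraction(w, total) for w in weights_raw]
        rows = [[Fraction(0)] * N for _ in range(N)]
        for c in coeffs:
            perm = _derangement(rng, N)
            for i in range(N):
                rows[i][int(perm[i])] += c
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return WeightedDigraph(
        rows, family="generic", params={"fixture": kind, "seed": seed}
    )
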