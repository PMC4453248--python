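"""Desk-scale reproduction runs: crossing tables, patterns and equality lines.

Each function returns a list of plain dict rows (one per computed entry)
and can be serialised to CSV via :func:`rows_to_csv`.  These are the
machine-readable counterparts of the fixation-pattern and crossing tables
the graph families exhibit.
"""

from __future__ import annotations

import csv
from typing import Sequence

from .fixation import (
    bipartite_equality_q,
    bipartite_rho,
    bisect_root,
    flow_level_crossing,
    flow_moran_crossing,
    moran_probability,
)
from .graphs import single_link
from .metrics import communicability, saddle_point_search

__all__ = [
    "flow_crossings",
    "t1_patterns",
    "classify_pattern",
    "bipartite_lines",
    "singlelink_saddle",
    "rows_to_csv",
]


def rows_to_csv(rows: list[dict], path) -> None:
    if not rows:
        raise ValueError("nothing to write")
    keys = list(rows[0])
    with open(path, "w", newline="") as fh:
        out = csv.DictWriter(fh, fieldnames=keys)
        out.writeheader()
        out.writerows(rows)


def flow_crossings(tol: float = 1e-5) -> list[dict]:
    """Enhancement windows of the (1,2,3) funnel and cascade.

    For both one-directional extremes of the (1,2,3) dual circular flow
    the average single-vertex fixation exceeds the Moran value only on a
    finite fitness window (1, r*); the rows report r*.
    """
    rows = []
    for name, p in (("funnel", 1), ("cascade", 0)):
        r_star = flow_moran_crossing((1, 2, 3), p, bracket=(1.01, 20.0), tol=tol)
        rows.append(
            {
                "flow": "(1,2,3)",
                "case": name,
                "p": p,
                "r_star": round(r_star, 6),
                "backend": "float-lumped",
            }
        )
    # the level-crossing fitnesses of the same flow
    rows.append(
        {
            "flow": "(1,2,3)",
            "case": "x2=x8 at p=0.25",
            "p": 0.25,
            "r_star": round(flow_level_crossing((1, 2, 3), 0.25, 1, 2, tol=tol), 6),
            "backend": "float-lumped",
        }
    )
    rows.append(
        {
            "flow": "(1,2,3)",
            "case": "x2=x1 at p=0.9",
            "p": 0.9,
            "r_star": round(flow_level_crossing((1, 2, 3), 0.9, 1, 0, tol=tol), 6),
            "backend": "float-lumped",
        }
    )
    return rows


_R_PROBES = [1.05, 1.2, 1.5, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0, 55.0, 144.0, 377.0, 987.0]


def classify_pattern(
    s: int, n: int, p, q, r_below: float = 0.5, tol: float = 1e-5
) -> dict:
    """Classify the sign pattern of rho - rho_Moran over fitness.

    Patterns (the A-D scheme): A = suppressed below r = 1,
    enhanced above; D = the mirror image; B and C have one extra crossing
    r_max above 1 (B: suppressed, enhanced, suppressed; C: enhanced,
    suppressed, enhanced).
    """
    N = s + n

    def diff(r: float) -> float:
        return bipartite_rho(s, n, p, q, r) - float(moran_probability(N, r))

    below = diff(r_below)
    signs = [(r, diff(r)) for r in _R_PROBES]
    flips = [
        (signs[i][0], signs[i + 1][0])
        for i in range(len(signs) - 1)
        if (signs[i][1] > 0) != (signs[i + 1][1] > 0)
    ]
    r_max = None
    if flips:
        r_max = bisect_root(diff, flips[0][0], flips[0][1], tol=tol)
    if below < 0:
        pattern = "A" if r_max is None else "B"
    else:
        pattern = "D" if r_max is None else "C"
    return {
        "s": s,
        "n": n,
        "p": float(p),
        "q": float(q),
        "pattern": pattern,
        "r_max": None if r_max is None else round(r_max, 4),
        "backend": "float",
    }


def t1_patterns(
    q=0,
    p_values: Sequence[float] = (0.25, 0.5, 0.55, 0.6, 0.75, 0.875, 1.0),
    tol: float = 1e-5,
) -> list[dict]:
    """Fixation patterns of the (2, 5) partial bipartite graph along one q row."""
    return [classify_pattern(2, 5, p, q, tol=tol) for p in p_values]


def bipartite_lines(
    cases=((3, 4), (2, 5)),
    r_values=(1.25, 1.5, 2.0),
    p_values=(0.0, 0.2, 0.4, 0.6, 0.8),
) -> list[dict]:
    """Solver-determined single-mutant equality lines q*(p) for two block sizes.

    The conductance-balance prediction is q = (1 + 3p)/4 for (3,4) and
    q = (3 + 2p)/5 for (2,5); rows carry both the solver value and the
    prediction.
    """
    rows = []
    for s, n in cases:
        for r in r_values:
            for p in p_values:
                q_solver = bipartite_equality_q(s, n, p, r)
                # conductance balance: 1 - p = (n/s)(1 - q)
                q_pred = 1 - (s / n) * (1 - p)
                rows.append(
                    {
                        "s": s,
                        "n": n,
                        "r": r,
                        "p": p,
                        "q_solver": round(q_solver, 9),
                        "q_conductance_balance": round(q_pred, 9),
                        "abs_error": round(abs(q_solver - q_pred), 12),
                        "backend": "float",
                    }
                )
    return rows


def singlelink_saddle() -> list[dict]:
    """Stationary point of the (3,4) single-link average centrality surface."""
    rows = []
    for mode in ("series6", "exact"):

        def avg(x, mode=mode):
            return communicability(
                single_link(3, 4, float(x[0]), float(x[1])), mode=mode
            ).average

        res = saddle_point_search(avg, [(0.02, 0.98), (0.02, 0.98)], grid=5)
        for r in res:
            rows.append(
                {
                    "mode": mode,
                    "p": round(r.point[0], 6),
                    "q": round(r.point[1], 6),
                    "kind": r.kind,
                    "grad_norm": float(r.grad_norm),
                }
            )
    return rows
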