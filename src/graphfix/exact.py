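"""Small exact linear-algebra routines over the rationals.

Dense Gaussian elimination on :class:`fractions.Fraction` entries.  Meant
for the modest system sizes this package works with (at most a few hundred
unknowns); no attempt at asymptotic cleverness.
"""

from __future__ import annotations

from fractions import Fraction

__all__ = ["solve_exact", "rref", "SingularSystemError"]


class SingularSystemError(ValueError):
    """Raised when an exact linear system has no unique solution."""


def solve_exact(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Solve ``A x = b`` exactly.  Raises SingularSystemError if singular."""
    n = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            raise SingularSystemError(f"singular system (no pivot in column {col})")
        if piv != col:
            M[col], M[piv] = M[piv], M[col]
        inv = 1 / M[col][col]
        M[col] = [x * inv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [xr - f * xc for xr, xc in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def rref(
    M: list[list[Fraction]],
) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form; returns (RREF matrix, pivot columns).

    Pivots are chosen left to right, so trailing columns are left free
    whenever the system is rank-deficient.
    """
    M = [row[:] for row in M]
    rows = len(M)
    cols = len(M[0]) if rows else 0
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        if r >= rows:
            break
        piv = next((i for i in range(r, rows) if M[i][c] != 0), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        inv = 1 / M[r][c]
        M[r] = [x * inv for x in M[r]]
        for i in range(rows):
            if i != r and M[i][c] != 0:
                f = M[i][c]
                M[i] = [xi - f * xr for xi, xr in zip(M[i], M[r])]
        pivots.append(c)
        r += 1
    return M, pivots
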