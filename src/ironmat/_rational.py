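"""Exact rational linear algebra on small matrices.

Elementary-mode enumeration hinges on support minimality, which is brittle
under floating-point rank decisions; everything here runs on
:class:`fractions.Fraction` so that ``S v = 0`` holds exactly.  Matrices are
tiny (tens of rows/columns), so plain Gaussian elimination is adequate.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

Matrix = list[list[Fraction]]


def as_fraction(x, tol: float = 1e-9) -> Fraction:
    """Convert ``x`` to an exact Fraction.

    Floats are rationalized to the simplest fraction within ``tol`` relative
    error (``limit_denominator`` on the scaled value), so e.g. 0.5 -> 1/2 and
    1.63 -> 163/100.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, float):
        if x == 0.0:
            return Fraction(0)
        exact = Fraction(x)
        # search for the simplest fraction within relative tol
        for digits in range(0, 18):
            cand = exact.limit_denominator(10**digits)
            if cand == 0:
                continue
            if abs(cand - exact) <= abs(exact) * Fraction(tol).limit_denominator(10**12):
                return cand
        return exact
    raise TypeError(f"cannot rationalize {type(x).__name__}")


def rref(mat: Matrix) -> tuple[Matrix, list[int]]:
    """Reduced row-echelon form; returns (rref matrix, pivot column indices)."""
    m = [row[:] for row in mat]
    nrows = len(m)
    ncols = len(m[0]) if nrows else 0
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        pivot = next((i for i in range(r, nrows) if m[i][c] != 0), None)
        if pivot is None:
            continue
        m[r], m[pivot] = m[pivot], m[r]
        pv = m[r][c]
        m[r] = [x / pv for x in m[r]]
        for i in range(nrows):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == nrows:
            break
    return m, pivots


def rank(mat: Matrix) -> int:
    if not mat or not mat[0]:
        return 0
    _, pivots = rref(mat)
    return len(pivots)


def nullspace(mat: Matrix, ncols: int | None = None) -> list[list[Fraction]]:
    """Basis of the right kernel of ``mat`` (rows = equations)."""
    if not mat:
        n = ncols or 0
        return [[Fraction(i == j) for i in range(n)] for j in range(n)]
    n = len(mat[0])
    red, pivots = rref(mat)
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -red[r][fc]
        basis.append(v)
    return basis


def solve_homogeneous_ray(mat: Matrix) -> list[Fraction] | None:
    """If the kernel of ``mat`` is one-dimensional, return a generator, else None."""
    basis = nullspace(mat)
    if len(basis) != 1:
        return None
    return basis[0]


def dot(row: Sequence[Fraction], vec: Sequence[Fraction]) -> Fraction:
    return sum((a * b for a, b in zip(row, vec)), Fraction(0))
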