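"""Quadrature rules on reference simplices.

Uses the Grundmann-Moller construction, which provides rules of arbitrary
odd degree in any dimension.  Some weights are negative; the rules are
nevertheless exact for the stated polynomial degree, which is all assembly
of affine-mapped P1/P2 forms requires.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from math import factorial

import numpy as np

__all__ = ["simplex_rule"]


def _compositions(total: int, parts: int):
    """All tuples of `parts` nonnegative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


@lru_cache(maxsize=None)
def _grundmann_moller(dim: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Grundmann-Moller rule of degree 2s+1 on the unit reference simplex.

    Returns points (n, dim) in reference coordinates and weights summing to
    the reference simplex volume 1/dim!.
    """
    d = 2 * s + 1
    n = dim
    pts = []
    wts = []
    for i in range(s + 1):
        coeff = (
            (-1) ** i
            * 2.0 ** (-2 * s)
            * float(d + n - 2 * i) ** d
            / (factorial(i) * factorial(d + n - i))
        )
        denom = float(d + n - 2 * i)
        for beta in _compositions(s - i, n + 1):
            bary = (2.0 * np.asarray(beta, dtype=float) + 1.0) / denom
            pts.append(bary[1:])  # drop lambda_0; ref coords are (l1..ln)
            wts.append(coeff)
    points = np.asarray(pts)
    weights = np.asarray(wts)
    # The classical normalization integrates over the unit simplex measure
    # 1/n!; the construction above already produces weights with that sum.
    target = 1.0 / factorial(n)
    weights *= target / weights.sum()
    return points, weights


@lru_cache(maxsize=None)
def simplex_rule(dim: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature rule exact for polynomials of the given degree.

    Parameters
    ----------
    dim : int
        Simplex dimension (1, 2 or 3).
    degree : int
        Requested polynomial exactness.

    Returns
    -------
    points : (n, dim) ndarray
        Reference coordinates on the simplex {x_i >= 0, sum x_i <= 1}.
    weights : (n,) ndarray
        Weights summing to 1/dim!.
    """
    if dim == 1:
        npts = max(1, (degree + 2) // 2)
        x, w = np.polynomial.legendre.leggauss(npts)
        return (0.5 * (x + 1.0))[:, None], 0.5 * w
    s = max(0, (degree - 1 + 1) // 2)  # 2s+1 >= degree
    return _grundmann_moller(dim, s)
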