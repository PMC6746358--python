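"""Exact rational linear solves for the Fraction-valued pipeline.

scipy's sparse solvers only handle machine floats, so the exact-rational
mode (small ``N``) uses plain Gaussian elimination over ``Fraction``
entries stored in dense object arrays.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def solve_fraction(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``A x = b`` exactly; ``A`` is an (n, n) object array of Fractions,
    ``b`` an (n,) or (n, k) object array."""
    n = A.shape[0]
    b2 = b.reshape(n, -1)
    M = np.empty((n, n + b2.shape[1]), dtype=object)
    M[:, :n] = A
    M[:, n:] = b2
    M = M.copy()
    for col in range(n):
        piv = next((i for i in range(col, n) if M[i, col] != 0), None)
        if piv is None:
            raise np.linalg.LinAlgError("singular rational system")
        if piv != col:
            M[[col, piv]] = M[[piv, col]]
        inv = Fraction(1, 1) / M[col, col]
        M[col, col:] = M[col, col:] * inv
        for i in range(n):
            if i != col and M[i, col] != 0:
                M[i, col:] = M[i, col:] - M[i, col] * M[col, col:]
    x = M[:, n:]
    return x.reshape(b.shape) if b.ndim == 1 else x
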