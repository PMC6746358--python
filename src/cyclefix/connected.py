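"""Fixation of a single connected mutant group: the one-dimensional chain.

With one connected group of ``w`` mutants on the cycle, the Death-birth
process is a birth-death chain on ``w = 0 .. N`` with absorbing ends.  Its
fixation probabilities admit the classical closed form

    pi_w = (1 + sum_{j=1}^{w-1} prod_{k=1}^{j} gamma_k)
           / (1 + sum_{j=1}^{N-1} prod_{k=1}^{j} gamma_k),

where ``gamma_w = P_{w,w-1} / P_{w,w+1}`` is the down/up rate ratio:
``(r+1)/(2r)`` at ``w=1``, ``1/r`` in the interior, ``2/(r+1)`` at
``w=N-1`` (the boundary cases reflect the deterministic replacement of a
lone mutant / lone wild-type).

Conditional fixation times are handled through ``theta_w = pi_w * tau_w``,
which satisfies a tridiagonal difference equation with theta_0 = theta_N =
0; both the explicit telescoped-sum solution and the direct linear solve
are implemented and must agree.  Times are counted in elementary rounds
(one death draw each), including rounds that do not change the state.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.linalg import solve_banded

from .jets import Jet
from .states import ModelParams
from .transitions import final_chain_rates


def gamma(w: int, params: ModelParams):
    """Down/up transition ratio ``gamma_w`` of the single-group chain."""
    down, up = final_chain_rates(w, params)
    return down / up


def _gamma_jets(params: ModelParams) -> list[Jet]:
    """Jets of gamma_1 .. gamma_{N-1} in r."""
    N = params.N
    r = Jet.variable(Fraction(params.r) if params.exact else float(params.r))
    first = (r + 1) / (r * 2)
    interior = r.reciprocal()
    last = 2 * (r + 1).reciprocal()
    out = []
    for w in range(1, N):
        out.append(first if w == 1 else last if w == N - 1 else interior)
    return out


def _pi_jets(params: ModelParams) -> list[Jet]:
    """Jets of pi_0 .. pi_N via cumulative products/sums of the gamma jets."""
    one = Fraction(1) if params.exact else 1.0
    gam = _gamma_jets(params)
    prefix = [Jet.constant(one)]  # prefix[w] = 1 + sum_{j<=w-1} prod gamma
    G = Jet.constant(one)
    for g in gam:
        G = G * g
        prefix.append(prefix[-1] + G)
    D_inv = prefix[-1].reciprocal()
    pis = [Jet.constant(0 * one)]
    pis.extend(prefix[w - 1] * D_inv for w in range(1, params.N + 1))
    return pis


def fixprob_final(w: int, params: ModelParams):
    """Fixation probability ``pi_w`` of a connected group of size ``w``."""
    if not 0 <= w <= params.N:
        raise ValueError(f"w={w} outside [0, {params.N}]")
    if w == 0:
        return Fraction(0) if params.exact else 0.0
    if w == params.N:
        return Fraction(1) if params.exact else 1.0
    return _pi_jets(params)[w].f


def fixprob_final_derivs(w: int, params: ModelParams, order: int = 1):
    """d^order/dr^order of ``pi_w`` at ``params.r`` (order 1 or 2), exact
    differentiation of the closed form via Taylor-mode propagation."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not 0 <= w <= params.N:
        raise ValueError(f"w={w} outside [0, {params.N}]")
    if w in (0, params.N):
        return Fraction(0) if params.exact else 0.0
    jet = _pi_jets(params)[w]
    return jet.d1 if order == 1 else jet.d2


def pi_vector(params: ModelParams) -> np.ndarray:
    """All fixation probabilities pi_0 .. pi_N as a vector."""
    vals = [j.f for j in _pi_jets(params)]
    return np.array(vals, dtype=object if params.exact else float)


def pi_deriv_vector(params: ModelParams, order: int) -> np.ndarray:
    jets = _pi_jets(params)
    vals = [j.d1 if order == 1 else j.d2 for j in jets]
    return np.array(vals, dtype=object if params.exact else float)


def theta_vector(params: ModelParams) -> np.ndarray:
    """theta_w = pi_w * tau^A_w for w = 0..N from the tridiagonal solve.

    theta satisfies  down_w theta_{w-1} - (down_w + up_w) theta_w
    + up_w theta_{w+1} = -pi_w  with theta_0 = theta_N = 0.
    """
    N = params.N
    pis = pi_vector(params)
    downs = []
    ups = []
    for w in range(1, N):
        d, u = final_chain_rates(w, params)
        downs.append(d)
        ups.append(u)
    n = N - 1
    if params.exact:
        # Thomas sweep on the exact tridiagonal system
        diag = [-(downs[i] + ups[i]) for i in range(n)]
        rhs = [-pis[w] for w in range(1, N)]
        for i in range(1, n):
            m = downs[i] / diag[i - 1]
            diag[i] = diag[i] - m * ups[i - 1]
            rhs[i] = rhs[i] - m * rhs[i - 1]
        sol = [Fraction(0)] * n
        sol[-1] = rhs[-1] / diag[-1]
        for i in range(n - 2, -1, -1):
            sol[i] = (rhs[i] - ups[i] * sol[i + 1]) / diag[i]
        theta = np.empty(N + 1, dtype=object)
        theta[0] = Fraction(0)
        theta[N] = Fraction(0)
        theta[1:N] = sol
        return theta
    ab = np.zeros((3, n))
    ab[1, :] = -(np.asarray(downs) + np.asarray(ups))
    ab[0, 1:] = ups[:-1]  # superdiagonal
    ab[2, :-1] = downs[1:]  # subdiagonal
    rhs = -pis[1:N]
    theta = np.zeros(N + 1)
    theta[1:N] = solve_banded((1, 1), ab, rhs)
    return theta


def _tau1_explicit(params: ModelParams):
    """tau^A_1 = sum_{k=1}^{N-1} sum_{l=1}^{k} (pi_l / P_{l,l+1})
    prod_{m=l+1}^{k} gamma_m  (telescoped solution of the theta equation)."""
    N = params.N
    pis = pi_vector(params)
    gam = [gamma(w, params) for w in range(1, N)]  # gam[w-1] = gamma_w
    ups = [final_chain_rates(w, params)[1] for w in range(1, N)]
    total = Fraction(0) if params.exact else 0.0
    for k in range(1, N):
        term = pis[k] / ups[k - 1]  # l = k contribution
        acc = term
        prod = 1
        for l in range(k - 1, 0, -1):
            prod = prod * gam[l]  # gamma_{l+1} * ... * gamma_k
            acc = acc + pis[l] / ups[l - 1] * prod
        total = total + acc
    return total


def cond_time_final(w: int, params: ModelParams, method: str = "solve"):
    """Mean number of rounds to all-mutant absorption from ``F_w``,
    conditioned on that absorption.

    ``method='solve'`` uses the tridiagonal theta solve; ``method='sum'``
    uses the explicit telescoped sums.  Both count every elementary round,
    including self-loops.
    """
    N = params.N
    if w == 0:
        raise ValueError("conditional fixation time undefined from w=0 (fixation impossible)")
    if not 1 <= w <= N:
        raise ValueError(f"w={w} outside [1, {N}]")
    if w == N:
        return Fraction(0) if params.exact else 0.0
    if method == "solve":
        theta = theta_vector(params)
        return theta[w] / fixprob_final(w, params)
    if method != "sum":
        raise ValueError(f"unknown method {method!r}")
    pis = pi_vector(params)
    gam = [gamma(v, params) for v in range(1, N)]
    ups = [final_chain_rates(v, params)[1] for v in range(1, N)]
    u0 = pis[1] * _tau1_explicit(params)  # u_0 = theta_1
    # u_k = u_0 prod_{m<=k} gamma_m - sum_{l=1}^{k} (pi_l/up_l) prod_{m=l+1}^{k} gamma_m
    theta_w = u0
    u = u0
    sum_part = Fraction(0) if params.exact else 0.0
    for k in range(1, w):
        sum_part = sum_part * gam[k - 1] + pis[k] / ups[k - 1]
        u = u0
        for m in range(k):
            u = u * gam[m]
        u = u - sum_part
        theta_w = theta_w + u
    return theta_w / pis[w]
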