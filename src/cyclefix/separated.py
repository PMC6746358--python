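"""Fixation probability and conditional fixation time for separated mutants.

With the transition matrix in block form ``P = [[Q1, Q2], [0, Q3]]`` the
fixation probabilities satisfy

    Psi_F = pi                (the connected-chain closed form)
    (I - Q1) Psi_S = Q2 pi,

where invertibility of ``I - Q1`` follows from the transience of the
two-group states.  Derivatives in ``r`` follow by differentiating the
linear system (``Q2`` carries no ``r`` dependence):

    Psi_S'  = (I - Q1)^{-1} (Q1' Psi_S + Q2 pi')
    Psi_S'' = (I - Q1)^{-1} (2 Q1' Psi_S' + Q1'' Psi_S + Q2 pi'')

and the fixation-conditioned times from the theta trick
(``theta = Psi o T``):

    (I - Q1) (Psi_S o T_S) = Q1 Psi_S + Q2 pi + Q2 theta_F.

All solves are sparse LU factorisations of ``I - Q1`` (the explicit inverse
is never formed); in exact-rational mode they are dense Fraction solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._linalg import solve_fraction
from .connected import pi_deriv_vector, pi_vector, theta_vector
from .states import FinalState, ModelParams, State, StateSpace, TripletState, enumerate_states
from .transitions import TransitionBlocks, build_blocks


class _FactorisedSystem:
    """Reusable solver for (I - Q1) x = b in either arithmetic."""

    def __init__(self, Q1, exact: bool):
        self.exact = exact
        if exact:
            n = Q1.shape[0]
            I = np.empty((n, n), dtype=object)
            I[:] = Fraction(0)
            for i in range(n):
                I[i, i] = Fraction(1)
            self.A = I - Q1
        else:
            n = Q1.shape[0]
            A = (sp.identity(n, format="csc") - Q1).tocsc()
            self.lu = spla.splu(A)
            self.A = A

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.exact:
            return solve_fraction(self.A, b)
        x = self.lu.solve(b)
        # one step of iterative refinement keeps 8-decimal accuracy at N ~ 100
        x += self.lu.solve(b - self.A @ x)
        return x


@dataclass
class FixationProfile:
    """Per-state fixation probabilities Psi (middle block then final block),
    with optional first/second r-derivative vectors."""

    space: StateSpace
    params: ModelParams
    psi: np.ndarray
    dpsi: Optional[np.ndarray] = None
    d2psi: Optional[np.ndarray] = None

    def value(self, state: State, order: int = 0):
        vec = (self.psi, self.dpsi, self.d2psi)[order]
        if vec is None:
            raise ValueError(f"derivative order {order} was not computed")
        return vec[self.space.index(state)]


@dataclass
class TimeProfile:
    """Fixation-conditioned mean absorption times (in elementary rounds).

    ``tau[F_0]`` is NaN: fixation never happens from the all-wild-type
    state, so the conditional expectation is undefined.
    """

    space: StateSpace
    params: ModelParams
    tau: np.ndarray

    def value(self, state: State):
        return self.tau[self.space.index(state)]


def _full_vector(space: StateSpace, mid: np.ndarray, fin: np.ndarray) -> np.ndarray:
    if mid.dtype == object or fin.dtype == object:
        out = np.empty(len(space), dtype=object)
    else:
        out = np.empty(len(space))
    out[: space.n_middle] = mid
    out[space.n_middle :] = fin
    return out


def fixprob_all(
    space: StateSpace,
    params: ModelParams,
    blocks: Optional[TransitionBlocks] = None,
) -> FixationProfile:
    """Fixation probability from every state at ``params.r``."""
    blocks = blocks or build_blocks(space, params)
    pi = pi_vector(params)
    rhs = blocks.Q2.dot(pi) if params.exact else blocks.Q2 @ pi
    psi_S = _FactorisedSystem(blocks.Q1, params.exact).solve(rhs)
    return FixationProfile(space, params, _full_vector(space, psi_S, pi))


def fixprob_derivs(
    space: StateSpace,
    params: ModelParams,
    order: int = 2,
    blocks: Optional[TransitionBlocks] = None,
) -> FixationProfile:
    """Fixation probabilities with first (and second) derivatives in ``r``."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    blocks = blocks or build_blocks(space, params, deriv_order=order)
    if blocks.dQ1 is None or (order == 2 and blocks.d2Q1 is None):
        raise ValueError("blocks were built without the required derivative order")
    exact = params.exact
    dot = (lambda M, v: M.dot(v)) if exact else (lambda M, v: M @ v)
    pi = pi_vector(params)
    dpi = pi_deriv_vector(params, 1)
    system = _FactorisedSystem(blocks.Q1, exact)
    psi_S = system.solve(dot(blocks.Q2, pi))
    dpsi_S = system.solve(dot(blocks.dQ1, psi_S) + dot(blocks.Q2, dpi))
    profile = FixationProfile(
        space,
        params,
        _full_vector(space, psi_S, pi),
        dpsi=_full_vector(space, dpsi_S, dpi),
    )
    if order == 2:
        d2pi = pi_deriv_vector(params, 2)
        d2psi_S = system.solve(
            2 * dot(blocks.dQ1, dpsi_S) + dot(blocks.d2Q1, psi_S) + dot(blocks.Q2, d2pi)
        )
        profile.d2psi = _full_vector(space, d2psi_S, d2pi)
    return profile


def _initial_state(N: int, d: int) -> State:
    """Canonical state of two single mutants at gap ``d`` (reflected if
    ``d`` exceeds the opposite gap)."""
    if not 0 <= d <= N - 2:
        raise ValueError(f"distance d={d} outside [0, {N - 2}]")
    dd = min(d, N - 2 - d)
    return FinalState(2) if dd == 0 else TripletState(dd, 1, 1)


def fixprob(N: int, d: int, r: Union[float, Fraction]) -> Union[float, Fraction]:
    """Fixation probability of two single mutants at distance ``d`` on a
    cycle of size ``N`` at relative fitness ``r``."""
    params = ModelParams(N, r)
    state = _initial_state(N, d)
    if isinstance(state, FinalState):
        from .connected import fixprob_final

        return fixprob_final(2, params)
    space = enumerate_states(N)
    return fixprob_all(space, params).value(state)


def taylor_neutral(N: int, d: int, order: int = 2, exact: Optional[bool] = None):
    """Coefficients ``(c0, c1, c2)`` of ``Psi ~ c0 + c1 (r-1) + c2 (r-1)^2``
    around neutrality for two mutants at distance ``d``.

    ``exact=None`` selects exact rationals automatically for ``N <= 15``.
    """
    if order > 2:
        raise ValueError("only expansion up to second order is supported")
    if exact is None:
        exact = N <= 15
    params = ModelParams(N, Fraction(1) if exact else 1.0)
    state = _initial_state(N, d)
    if isinstance(state, FinalState):
        from .connected import fixprob_final, fixprob_final_derivs

        c0 = fixprob_final(2, params)
        c1 = fixprob_final_derivs(2, params, 1)
        c2 = fixprob_final_derivs(2, params, 2)
    else:
        space = enumerate_states(N)
        prof = fixprob_derivs(space, params, order=2)
        c0 = prof.value(state, 0)
        c1 = prof.value(state, 1)
        c2 = prof.value(state, 2)
    half = Fraction(1, 2) if exact else 0.5
    return (c0, c1, c2 * half)[: order + 1]


def cond_time_all(
    space: StateSpace,
    params: ModelParams,
    blocks: Optional[TransitionBlocks] = None,
) -> TimeProfile:
    """Fixation-conditioned mean times from every state, in rounds."""
    blocks = blocks or build_blocks(space, params)
    exact = params.exact
    dot = (lambda M, v: M.dot(v)) if exact else (lambda M, v: M @ v)
    pi = pi_vector(params)
    theta_F = theta_vector(params)
    system = _FactorisedSystem(blocks.Q1, exact)
    psi_S = system.solve(dot(blocks.Q2, pi))
    theta_S = system.solve(dot(blocks.Q1, psi_S) + dot(blocks.Q2, pi) + dot(blocks.Q2, theta_F))
    tau_S = theta_S / psi_S
    if exact:
        tau_F = np.empty(params.N + 1, dtype=object)
        tau_F[0] = None  # conditional time undefined from F_0
        for w in range(1, params.N + 1):
            tau_F[w] = theta_F[w] / pi[w]
    else:
        tau_F = np.full(params.N + 1, np.nan)
        tau_F[1:] = theta_F[1:] / pi[1:]
    return TimeProfile(space, params, _full_vector(space, tau_S, tau_F))
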