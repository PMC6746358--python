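"""Transition blocks: probability conservation, structure, derivatives."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import bruteforce_lumped_blocks
from cyclefix.states import FinalState, ModelParams, TripletState, enumerate_states
from cyclefix.transitions import border_events, build_blocks, final_chain_rates


def full_matrix(blocks):
    """Dense [Q1 Q2; 0 Q3] in state-space order."""
    Q1 = blocks.Q1.toarray() if hasattr(blocks.Q1, "toarray") else blocks.Q1
    Q2 = blocks.Q2.toarray() if hasattr(blocks.Q2, "toarray") else blocks.Q2
    Q3 = blocks.Q3.toarray() if hasattr(blocks.Q3, "toarray") else blocks.Q3
    nm = Q1.shape[0]
    nf = Q3.shape[0]
    P = np.zeros((nm + nf, nm + nf))
    P[:nm, :nm] = Q1
    P[:nm, nm:] = Q2
    P[nm:, nm:] = Q3
    return P


@pytest.mark.parametrize("N", [6, 9, 12])
@pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
def test_lumped_bruteforce_equals_blocks(N, r):
    """Lumping the explicit-position chain reproduces [Q1 Q2; 0 Q3]."""
    P_brute, space = bruteforce_lumped_blocks(N, r)
    blocks = build_blocks(enumerate_states(N), ModelParams(N, r))
    np.testing.assert_allclose(full_matrix(blocks), P_brute, atol=1e-14)


@pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
def test_row_sums_one(r):
    blocks = build_blocks(enumerate_states(10), ModelParams(10, r))
    rows = blocks.Q1.sum(axis=1).A1 + blocks.Q2.sum(axis=1).A1
    np.testing.assert_allclose(rows, 1.0, atol=1e-15)
    np.testing.assert_allclose(blocks.Q3.sum(axis=1).A1, 1.0, atol=1e-15)


def test_q2_independent_of_r():
    space = enumerate_states(9)
    q2_a = build_blocks(space, ModelParams(9, 0.5)).Q2.toarray()
    q2_b = build_blocks(space, ModelParams(9, 2.0)).Q2.toarray()
    np.testing.assert_array_equal(q2_a, q2_b)


def test_border_events_n6_examples():
    """Hand-checked hexagon transitions out of S(1,1,1) and S(2,1,1)."""
    params = ModelParams(6, Fraction(3, 2))
    ev = dict(border_events(TripletState(1, 1, 1), params))
    # either lone mutant dies, both neighbours wild-type -> F_1
    assert ev[FinalState(1)] == Fraction(2, 6)
    # the single gap wild-type dies between two mutants -> F_3
    assert ev[FinalState(3)] == Fraction(1, 6)
    r = params.r
    ev2 = dict(border_events(TripletState(2, 1, 1), params))
    # all four wild-types are gap-end borders; each mutant win gives (1,1,2)
    assert ev2[TripletState(1, 1, 2)] == 4 * Fraction(1, 6) * r / (1 + r)
    assert ev2[FinalState(1)] == Fraction(2, 6)
    assert sum(ev2.values()) == 1


def test_border_events_rejects_noncanonical():
    with pytest.raises(ValueError):
        border_events(TripletState(3, 1, 1), ModelParams(6, 1.0))


def test_neutral_weights_are_half():
    """At r=1 every mixed competition resolves 50/50, so every off-diagonal
    middle-state entry is a multiple of 1/(2N) and sure events are 1/N."""
    params = ModelParams(8, Fraction(1))
    for state in enumerate_states(8).middle:
        for tgt, p in border_events(state, params):
            if tgt != state:
                assert p % Fraction(1, 16) == 0


@pytest.mark.parametrize(
    "w, N, r, expected",
    [
        (1, 6, 2.0, 3 / 4),  # lone mutant: (1+r)/(2r)
        (3, 6, 1.0, 1.0),  # interior neutral
        (5, 6, 3.0, 1 / 2),  # lone wild-type: 2/(1+r)
    ],
)
def test_final_chain_ratios(w, N, r, expected):
    down, up = final_chain_rates(w, ModelParams(N, r))
    assert down / up == pytest.approx(expected, rel=1e-15)


def test_final_chain_rates_range():
    with pytest.raises(ValueError):
        final_chain_rates(0, ModelParams(6, 1.0))
    with pytest.raises(ValueError):
        final_chain_rates(6, ModelParams(6, 1.0))


@pytest.mark.parametrize("r", [0.25, 0.5, 1.0, 2.0, 4.0])
def test_middle_states_transient(r):
    """Spectral radius of Q1 below one: two-group states are always left."""
    blocks = build_blocks(enumerate_states(12), ModelParams(12, r))
    eigs = np.linalg.eigvals(blocks.Q1.toarray())
    assert np.abs(eigs).max() < 1.0


def test_q1_row_nonzeros_bounded():
    """At most 8 moves plus the diagonal per middle-state row."""
    blocks = build_blocks(enumerate_states(30), ModelParams(30, 1.3))
    nnz_per_row = np.diff(blocks.Q1.tocsr().indptr) + np.diff(blocks.Q2.tocsr().indptr)
    assert nnz_per_row.max() <= 9


@pytest.mark.parametrize("r0", [0.7, 1.0, 1.6])
def test_derivative_blocks_match_finite_differences(r0):
    """dQ1/dr and d2Q1/dr2 agree with central differences of Q1(r)."""
    space = enumerate_states(10)
    blocks = build_blocks(space, ModelParams(10, r0), deriv_order=2)
    h = 1e-5
    Qp = build_blocks(space, ModelParams(10, r0 + h)).Q1.toarray()
    Qm = build_blocks(space, ModelParams(10, r0 - h)).Q1.toarray()
    Q0 = blocks.Q1.toarray()
    np.testing.assert_allclose(blocks.dQ1.toarray(), (Qp - Qm) / (2 * h), atol=1e-9)
    np.testing.assert_allclose(blocks.d2Q1.toarray(), (Qp - 2 * Q0 + Qm) / h**2, atol=1e-5)


def test_exact_blocks_are_fractions():
    blocks = build_blocks(enumerate_states(6), ModelParams(6, Fraction(2)), deriv_order=1)
    assert blocks.Q1.dtype == object
    assert all(isinstance(v, Fraction) for v in blocks.Q1.ravel())
    assert blocks.Q1.sum(axis=1)[0] + blocks.Q2.sum(axis=1)[0] == 1
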