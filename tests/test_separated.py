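"""Block solves for separated mutants: probabilities, derivatives, times."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import bruteforce_absorption, two_mutant_config
from cyclefix.connected import fixprob_final, fixprob_final_derivs
from cyclefix.separated import (
    cond_time_all,
    fixprob,
    fixprob_all,
    fixprob_derivs,
    taylor_neutral,
)
from cyclefix.states import FinalState, ModelParams, TripletState, enumerate_states


def psi_s1_rational(r: Fraction) -> Fraction:
    """Reference closed form of Psi at (1,1,1), N=6."""
    num = r**2 * (28 + 167 * r + 475 * r**2 + 920 * r**3 + 1036 * r**4 + 585 * r**5 + 117 * r**6)
    den = (3 + 2 * r + 2 * r**2 + 2 * r**3 + 3 * r**4) * (
        45 + 210 * r + 322 * r**2 + 210 * r**3 + 45 * r**4
    )
    return num / den


def psi_s2_rational(r: Fraction) -> Fraction:
    """Reference closed form of Psi at (2,1,1), N=6."""
    num = r**2 * (39 + 179 * r + 456 * r**2 + 896 * r**3 + 1041 * r**4 + 597 * r**5 + 120 * r**6)
    den = (3 + 2 * r + 2 * r**2 + 2 * r**3 + 3 * r**4) * (
        45 + 210 * r + 322 * r**2 + 210 * r**3 + 45 * r**4
    )
    return num / den


def test_exact_closed_forms_n6(space6):
    """Exact-rational block solve reproduces the printed N=6 closed forms."""
    for r in [Fraction(2), Fraction(1, 2), Fraction(7, 4)]:
        prof = fixprob_all(space6, ModelParams(6, r))
        assert prof.value(TripletState(1, 1, 1)) == psi_s1_rational(r)
        assert prof.value(TripletState(2, 1, 1)) == psi_s2_rational(r)
    assert fixprob_all(space6, ModelParams(6, Fraction(2))).value(
        TripletState(2, 1, 1)
    ) == Fraction(211316, 328087)


@pytest.mark.parametrize("N", [6, 25])
def test_neutral_psi_proportional_to_mutant_count(N):
    """At r=1 the fixation probability of any state is w/N."""
    space = enumerate_states(N)
    prof = fixprob_all(space, ModelParams(N, 1.0))
    for i, s in enumerate(space):
        w = s.w if isinstance(s, TripletState) else s.w
        assert prof.psi[i] == pytest.approx(w / N, abs=1e-12)


@pytest.mark.parametrize("N", [6, 25])
def test_psi_monotone_in_r(N):
    space = enumerate_states(N)
    grid = [0.25, 0.5, 1.0, 2.0, 4.0]
    profiles = [fixprob_all(space, ModelParams(N, r)).psi for r in grid]
    for a, b in zip(profiles, profiles[1:]):
        mid = space.n_middle
        assert np.all(b[:mid] - a[:mid] > 0)


def test_fixprob_wrapper_delegation_and_reflection():
    assert fixprob(6, 0, 1.7) == fixprob_final(2, ModelParams(6, 1.7))
    assert fixprob(25, 13, 1.5) == fixprob(25, 10, 1.5)  # min-gap reflection
    assert fixprob(6, 2, 1.0) == pytest.approx(1 / 3, abs=1e-12)
    with pytest.raises(ValueError):
        fixprob(6, 5, 1.0)


def test_taylor_neutral_exact_coefficients(space6):
    """Second-order expansion around r=1 for N=6, bit-exact rationals."""
    assert taylor_neutral(6, 0) == (Fraction(2, 6), Fraction(7, 12), Fraction(-40, 288))
    assert taylor_neutral(6, 1) == (Fraction(2, 6), Fraction(6, 12), Fraction(-49, 288))
    assert taylor_neutral(6, 2) == (Fraction(2, 6), Fraction(6, 12), Fraction(-46, 288))


def test_taylor_c2_is_half_second_derivative():
    prof = fixprob_derivs(enumerate_states(8), ModelParams(8, Fraction(1)), order=2)
    c0, c1, c2 = taylor_neutral(8, 2)
    st = TripletState(2, 1, 1)
    assert c2 == prof.value(st, 2) / 2
    assert (c0, c1) == (prof.value(st, 0), prof.value(st, 1))


@pytest.mark.parametrize("N", [6, 25])
def test_derivatives_match_finite_differences(N):
    """Block-derivative formulas vs central differences of the solve at r=1."""
    space = enumerate_states(N)
    prof = fixprob_derivs(space, ModelParams(N, 1.0), order=2)
    h = 1e-4
    psi_p = fixprob_all(space, ModelParams(N, 1.0 + h)).psi
    psi_m = fixprob_all(space, ModelParams(N, 1.0 - h)).psi
    psi_0 = prof.psi
    mid = space.n_middle
    np.testing.assert_allclose(
        prof.dpsi[:mid], (psi_p - psi_m)[:mid] / (2 * h), rtol=1e-5, atol=1e-8
    )
    np.testing.assert_allclose(
        prof.d2psi[:mid], (psi_p - 2 * psi_0 + psi_m)[:mid] / h**2, rtol=1e-4, atol=1e-6
    )


def test_first_derivative_gap_formula():
    """dPsi/dr at r=1: connected pair exceeds any separated pair by 1/(2N).

    Exact rationals for small N, floating solves for larger populations.
    """
    for N in (6, 10):
        space = enumerate_states(N)
        prof = fixprob_derivs(space, ModelParams(N, Fraction(1)), order=1)
        d_conn = fixprob_final_derivs(2, ModelParams(N, Fraction(1)), 1)
        for d in range(1, (N - 2) // 2 + 1):
            gap = d_conn - prof.value(TripletState(d, 1, 1), 1)
            assert gap == Fraction(1, 2 * N)
    for N in (20, 41):
        space = enumerate_states(N)
        prof = fixprob_derivs(space, ModelParams(N, 1.0), order=1)
        d_conn = fixprob_final_derivs(2, ModelParams(N, 1.0), 1)
        for d in range(1, (N - 2) // 2 + 1):
            gap = d_conn - prof.value(TripletState(d, 1, 1), 1)
            assert gap == pytest.approx(1 / (2 * N), abs=1e-10)


def test_second_derivative_increases_with_distance():
    for N in (6, 25):
        space = enumerate_states(N)
        prof = fixprob_derivs(space, ModelParams(N, 1.0), order=2)
        vals = [prof.value(TripletState(d, 1, 1), 2) for d in range(1, (N - 2) // 2 + 1)]
        assert np.all(np.diff(vals) > 0)


def test_block_solution_vs_dense_full_chain():
    """Absorption probabilities of the dense [Q1 Q2; 0 Q3] chain at N=20."""
    from cyclefix.transitions import build_blocks

    N, r = 20, 1.4
    space = enumerate_states(N)
    blocks = build_blocks(space, ModelParams(N, r))
    nm = space.n_middle
    P = np.zeros((len(space), len(space)))
    P[:nm, :nm] = blocks.Q1.toarray()
    P[:nm, nm:] = blocks.Q2.toarray()
    P[nm:, nm:] = blocks.Q3.toarray()
    # transient = everything except F_0 and F_N
    fix_col = space.index(FinalState(N))
    lose_col = space.index(FinalState(0))
    keep = [i for i in range(len(space)) if i not in (fix_col, lose_col)]
    A = np.eye(len(keep)) - P[np.ix_(keep, keep)]
    b = P[keep, fix_col]
    psi_dense = np.linalg.solve(A, b)
    prof = fixprob_all(space, ModelParams(N, r))
    np.testing.assert_allclose(psi_dense, prof.psi[keep], rtol=1e-10)


def test_cond_times_exact_values_and_ordering(space6):
    """N=6 neutral conditional times: 32 > 766/26 > 739/26 rounds as the
    initial distance grows (more dispersed mutants fixate faster)."""
    times = cond_time_all(space6, ModelParams(6, Fraction(1)))
    t_f2 = times.value(FinalState(2))
    t_s1 = times.value(TripletState(1, 1, 1))
    t_s2 = times.value(TripletState(2, 1, 1))
    assert t_f2 == 32
    assert t_s1 == Fraction(766, 26)
    assert t_s2 == Fraction(739, 26)
    assert t_s2 < t_s1 < t_f2


@pytest.mark.parametrize("N", [6, 9, 12])
@pytest.mark.parametrize("r", [0.8, 1.0, 1.5])
def test_times_match_bruteforce_configuration_chain(N, r):
    """Conditioned times on the unlumped 2^N chain equal the block solution."""
    oracle = bruteforce_absorption(N, r)
    space = enumerate_states(N)
    params = ModelParams(N, r)
    prof = fixprob_all(space, params)
    times = cond_time_all(space, params)
    for d in range(0, (N - 2) // 2 + 1):
        cfg = two_mutant_config(N, d)
        psi_o, theta_o = oracle[cfg]
        st = FinalState(2) if d == 0 else TripletState(d, 1, 1)
        assert prof.value(st) == pytest.approx(psi_o, abs=1e-12)
        assert times.value(st) == pytest.approx(theta_o / psi_o, rel=1e-10)


def test_time_profile_boundaries():
    times = cond_time_all(enumerate_states(10), ModelParams(10, 1.3))
    assert times.value(FinalState(10)) == 0.0
    assert np.isnan(times.value(FinalState(0)))
    mid = times.tau[: enumerate_states(10).n_middle]
    assert np.all(mid > 0) and np.all(np.isfinite(mid))
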