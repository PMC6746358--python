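"""Shared fixtures and the brute-force full-configuration oracle.

The oracle builds the Death-birth transition matrix over explicit 0/1
occupancy tuples (positions not lumped), restricted to configurations with
at most two mutant groups — the set is closed under Death-birth updating
because only border individuals can change type, so groups never split.
Lumping these configurations by their canonical state must reproduce the
block matrices, and absorption probabilities / conditioned times computed
on the unlumped chain must match the block solutions.  Everything here is
independent of the package's transition-assembly code path.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from cyclefix.states import config_to_state


def db_config_transitions(config: tuple, r) -> dict:
    """One-step DB transition distribution out of one explicit configuration."""
    N = len(config)
    w = sum(config)
    if w == 0 or w == N:
        return {config: 1 if isinstance(r, Fraction) else 1.0}
    one = Fraction(1) if isinstance(r, Fraction) else 1.0
    p_mut = r / (1 + r)
    p_wt = one / (1 + r)
    out: dict = {}
    for pos in range(N):
        s = config[pos - 1] + config[(pos + 1) % N]
        if s == 2:
            outcomes = [(1, one)]
        elif s == 0:
            outcomes = [(0, one)]
        else:
            outcomes = [(1, p_mut), (0, p_wt)]
        for new, prob in outcomes:
            c2 = config[:pos] + (new,) + config[pos + 1 :]
            out[c2] = out.get(c2, 0) + prob * one / N
    return out


def two_group_configs(N: int) -> list[tuple]:
    """All occupancy tuples with at most two mutant groups (absorbing incl.)."""
    keep = []
    for c in product((0, 1), repeat=N):
        try:
            config_to_state(c)
        except ValueError:
            continue
        keep.append(c)
    return keep


def bruteforce_lumped_blocks(N: int, r):
    """Lump the explicit-configuration chain onto canonical states.

    Returns (space-ordered dense matrix P, state list) after verifying that
    every configuration in a lumpability class produces the same lumped row.
    """
    from cyclefix.states import enumerate_states

    space = enumerate_states(N)
    configs = two_group_configs(N)
    n = len(space)
    exact = isinstance(r, Fraction)
    P = np.zeros((n, n)) if not exact else np.full((n, n), Fraction(0), dtype=object)
    seen_rows: dict[int, dict] = {}
    for c in configs:
        i = space.index(config_to_state(c))
        row: dict[int, object] = {}
        for c2, p in db_config_transitions(c, r).items():
            j = space.index(config_to_state(c2))
            row[j] = row.get(j, 0) + p
        if i in seen_rows:
            prev = seen_rows[i]
            assert set(prev) == set(row)
            for j in row:
                diff = prev[j] - row[j]
                assert diff == 0 if exact else abs(diff) < 1e-14, (
                    f"lumpability violated at state {space.state(i)!r}"
                )
        else:
            seen_rows[i] = row
            for j, p in row.items():
                P[i, j] = p
    return P, space


def bruteforce_absorption(N: int, r):
    """Fixation probability and conditioned theta for every explicit config.

    Solves psi = P psi and theta = P theta + psi directly on the unlumped
    chain.  Returns dicts config -> (psi, theta).
    """
    configs = two_group_configs(N)
    full = tuple([1] * N)
    trans = [c for c in configs if 0 < sum(c) < N]
    ti = {c: k for k, c in enumerate(trans)}
    m = len(trans)
    A = np.eye(m)
    b = np.zeros(m)
    for c in trans:
        k = ti[c]
        for c2, p in db_config_transitions(c, float(r)).items():
            if c2 == full:
                b[k] += p
            elif c2 in ti:
                A[k, ti[c2]] -= p
    psi = np.linalg.solve(A, b)
    theta = np.linalg.solve(A, psi)
    out = {full: (1.0, 0.0), tuple([0] * N): (0.0, 0.0)}
    for c in trans:
        out[c] = (psi[ti[c]], theta[ti[c]])
    return out


def two_mutant_config(N: int, d: int) -> tuple:
    """Occupancy tuple with two single mutants separated by gap d."""
    c = [0] * N
    c[0] = 1
    c[(d + 1) % N] = 1
    return tuple(c)


@pytest.fixture(scope="session")
def space6():
    from cyclefix.states import enumerate_states

    return enumerate_states(6)


@pytest.fixture(scope="session")
def space25():
    from cyclefix.states import enumerate_states

    return enumerate_states(25)
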