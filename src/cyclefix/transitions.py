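"""One-step transition probabilities of the Death-birth process on a cycle.

Each elementary round a uniformly chosen individual dies (probability
``1/N``) and its two neighbours compete to fill the site: a mutant
neighbour carries weight ``r``, a wild-type neighbour weight ``1``, so
against a mixed pair the offspring is mutant with probability
``r/(1+r)``.  Only individuals on a group border can change the state, and
a two-group state has at most 8 such individuals, so each row of the
transition matrix has at most 8 off-diagonal entries before canonical
targets are merged.

The matrix over the ordered state space has the block form::

    P = [ Q1  Q2 ]      Q1: middle -> middle      Q2: middle -> final
        [ 0   Q3 ]      Q3: final  -> final (tridiagonal, absorbing ends)

``Q2`` collects group-merging and group-extinction events, all of which
happen with probability ``1/N`` regardless of ``r``; hence ``Q2`` carries
no ``r`` dependence and its derivative vanishes.  Derivatives of ``Q1`` and
``Q3`` in ``r`` are assembled entrywise from the closed forms of the
competition weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .jets import Jet
from .states import (
    FinalState,
    ModelParams,
    State,
    StateSpace,
    TripletState,
    canonicalize,
)

# event kinds: the replacement weight attached to a border death
_SURE = "sure"  # deterministic replacement, probability 1/N
_MUT = "mut"  # mutant wins a mixed competition, (1/N) * r/(1+r)
_WT = "wt"  # wild-type wins a mixed competition, (1/N) * 1/(1+r)


def _raw_events(state: TripletState, N: int) -> list[tuple[State, str]]:
    """Death events at the 8 (or fewer) border individuals, uncanonicalized.

    Cyclic arrangement: group A (size a), gap X (size x), group B (size b),
    gap Y (size y).  Only state-changing outcomes are listed; the
    complementary outcome of each mixed competition leaves the state
    unchanged and ends up in the diagonal.
    """
    x, a, b = state.x, state.a, state.b
    y = N - x - a - b
    ev: list[tuple[State, str]] = []
    # mutant deaths at group ends (replaced by wild-type)
    if a == 1:
        ev.append((FinalState(b), _SURE))  # lone mutant, both neighbours wild-type
    else:
        ev.append((canonicalize(x + 1, a - 1, y, b, N), _WT))
        ev.append((canonicalize(x, a - 1, y + 1, b, N), _WT))
    if b == 1:
        ev.append((FinalState(a), _SURE))
    else:
        ev.append((canonicalize(x + 1, a, y, b - 1, N), _WT))
        ev.append((canonicalize(x, a, y + 1, b - 1, N), _WT))
    # wild-type deaths at gap ends (replaced by mutant)
    if x == 1:
        ev.append((FinalState(a + b + 1), _SURE))  # gap closes, groups merge
    else:
        ev.append((canonicalize(x - 1, a + 1, y, b, N), _MUT))
        ev.append((canonicalize(x - 1, a, y, b + 1, N), _MUT))
    if y == 1:
        ev.append((FinalState(a + b + 1), _SURE))
    else:
        ev.append((canonicalize(x, a + 1, y - 1, b, N), _MUT))
        ev.append((canonicalize(x, a, y - 1, b + 1, N), _MUT))
    return ev


def _weight_jets(params: ModelParams) -> dict[str, Jet]:
    """Probability jets (value, d/dr, d2/dr2) for the three event kinds."""
    if params.exact:
        invN = Fraction(1, params.N)
        r = Jet.variable(Fraction(params.r))
    else:
        invN = 1.0 / params.N
        r = Jet.variable(float(params.r))
    one_plus = r + 1
    return {
        _SURE: Jet.constant(invN),
        _MUT: (r / one_plus) * invN,
        _WT: one_plus.reciprocal() * invN,
    }


def border_events(state: TripletState, params: ModelParams) -> list[tuple[State, object]]:
    """Aggregated one-step transitions out of a middle state.

    Returns ``(target, probability)`` pairs at ``params.r``, with events
    that canonicalize to the same target summed and the residual mass
    reported as a self-loop ``(state, p)`` entry.
    """
    state.validate(params.N)
    w = _weight_jets(params)
    acc: dict[State, object] = {}
    for target, kind in _raw_events(state, params.N):
        acc[target] = acc.get(target, 0) + w[kind].f
    total = sum(acc.values())
    acc[state] = acc.get(state, 0) + (1 - total)
    return sorted(acc.items(), key=lambda kv: repr(kv[0]))


def final_chain_rates(w: int, params: ModelParams):
    """Down/up one-step probabilities ``(P_{w,w-1}, P_{w,w+1})`` of the
    single-group chain.

    A connected group of size ``2 <= w <= N-2`` has two mutant and two
    wild-type border individuals; a lone mutant (``w=1``) or lone wild-type
    (``w=N-1``) is its own pair of borders and is replaced deterministically.
    """
    N = params.N
    if not 1 <= w <= N - 1:
        raise ValueError(f"w={w} outside [1, {N - 1}]")
    jets = _weight_jets(params)
    down = jets[_SURE].f if w == 1 else 2 * jets[_WT].f
    up = jets[_SURE].f if w == N - 1 else 2 * jets[_MUT].f
    return down, up


@dataclass
class TransitionBlocks:
    """Q1/Q2/Q3 blocks (and optional r-derivatives) over a state space."""

    space: StateSpace
    params: ModelParams
    Q1: object
    Q2: object
    Q3: object
    dQ1: Optional[object] = None
    dQ3: Optional[object] = None
    d2Q1: Optional[object] = None
    d2Q3: Optional[object] = None


def build_blocks(space: StateSpace, params: ModelParams, deriv_order: int = 0) -> TransitionBlocks:
    """Assemble the sparse transition blocks and their ``r``-derivatives.

    ``deriv_order`` 0, 1 or 2 controls which derivative blocks are built.
    ``dQ2`` is identically zero and therefore never materialised.  In exact
    mode (rational ``r``) dense object arrays of Fractions are returned
    instead of scipy sparse matrices.
    """
    if space.N != params.N:
        raise ValueError("state space and params disagree on N")
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1 or 2")
    N = space.N
    nm, nf = space.n_middle, space.n_final
    jets = _weight_jets(params)
    one = Fraction(1) if params.exact else 1.0

    # accumulate per-row jets over canonical targets
    rows1: list[dict[int, Jet]] = []
    rows2: list[dict[int, Jet]] = []
    for i, s in enumerate(space.middle):
        acc: dict[State, Jet] = {}
        for target, kind in _raw_events(s, N):
            j = jets[kind]
            acc[target] = acc[target] + j if target in acc else j
        loop = Jet.constant(one)
        for j in acc.values():
            loop = loop - j
        acc[s] = acc.get(s, Jet.constant(0)) + loop
        r1: dict[int, Jet] = {}
        r2: dict[int, Jet] = {}
        for target, j in acc.items():
            if isinstance(target, TripletState):
                r1[space.middle_index(target)] = j
            else:
                r2[target.w] = j
        rows1.append(r1)
        rows2.append(r2)

    # final-state chain rows (tridiagonal, absorbing at 0 and N)
    rows3: list[dict[int, Jet]] = []
    for w in range(N + 1):
        if w == 0 or w == N:
            rows3.append({w: Jet.constant(one)})
            continue
        down = jets[_SURE] if w == 1 else jets[_WT] * 2
        up = jets[_SURE] if w == N - 1 else jets[_MUT] * 2
        rows3.append({w - 1: down, w + 1: up, w: Jet.constant(one) - down - up})

    def assemble(rows, ncols, part):
        if params.exact:
            M = np.empty((len(rows), ncols), dtype=object)
            M[:] = Fraction(0)
            for i, row in enumerate(rows):
                for jcol, jet in row.items():
                    M[i, jcol] = part(jet)
            return M
        data, ri, ci = [], [], []
        for i, row in enumerate(rows):
            for jcol, jet in row.items():
                ri.append(i)
                ci.append(jcol)
                data.append(part(jet))
        return sp.csr_matrix((data, (ri, ci)), shape=(len(rows), ncols))

    blocks = TransitionBlocks(
        space=space,
        params=params,
        Q1=assemble(rows1, nm, lambda j: j.f),
        Q2=assemble(rows2, nf, lambda j: j.f),
        Q3=assemble(rows3, nf, lambda j: j.f),
    )
    if deriv_order >= 1:
        blocks.dQ1 = assemble(rows1, nm, lambda j: j.d1)
        blocks.dQ3 = assemble(rows3, nf, lambda j: j.d1)
    if deriv_order >= 2:
        blocks.d2Q1 = assemble(rows1, nm, lambda j: j.d2)
        blocks.d2Q3 = assemble(rows3, nf, lambda j: j.d2)
    return blocks
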