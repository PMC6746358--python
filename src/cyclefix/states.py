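"""State space of the Death-birth process on a cycle with at most two mutant groups.

A configuration of mutants on a cycle of ``N`` individuals is reduced, up to
rotation and reflection, to either

* a :class:`FinalState` ``F_w`` — a single connected mutant group of size
  ``w`` (``w = 0`` and ``w = N`` are the absorbing all-wild-type and
  all-mutant states), or
* a :class:`TripletState` ``S_{x,a,b}`` — two separated mutant groups of
  sizes ``a <= b`` whose minimal wild-type gap is ``x`` (the other gap is
  ``N - x - a - b >= x``).

Under Death-birth updating on a cycle a mutant group can never split, so
configurations with more than two groups are unreachable from the initial
conditions considered here and are deliberately not represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterator, Union


@dataclass(frozen=True)
class ModelParams:
    """Population size ``N`` and relative mutant fitness ``r``.

    ``r`` is the fitness of a mutant divided by that of a wild-type
    individual: in a local competition for an empty site a mutant neighbour
    wins with probability ``r / (1 + r)``.  Passing ``r`` as a
    :class:`fractions.Fraction` (or int) switches all downstream linear
    algebra to exact rational arithmetic.
    """

    N: int
    r: Union[float, Fraction]

    def __post_init__(self) -> None:
        if not isinstance(self.N, int) or self.N < 3:
            raise ValueError(f"population size N must be an integer >= 3, got {self.N!r}")
        if self.r <= 0:
            raise ValueError(f"relative fitness r must be positive, got {self.r!r}")

    @property
    def exact(self) -> bool:
        """True when ``r`` is rational and computations should be exact."""
        return isinstance(self.r, Rational)


@dataclass(frozen=True, order=True)
class TripletState:
    """Two separated mutant groups: minimal gap ``x``, group sizes ``a <= b``."""

    x: int
    a: int
    b: int

    def validate(self, N: int) -> None:
        x, a, b = self.x, self.a, self.b
        other = N - x - a - b
        if not (1 <= a <= b and 1 <= x <= other):
            raise ValueError(f"{self} is not canonical for N={N}")

    @property
    def w(self) -> int:
        """Total number of mutants."""
        return self.a + self.b

    def other_gap(self, N: int) -> int:
        return N - self.x - self.a - self.b

    def __repr__(self) -> str:  # S_{x,a,b} in the field's notation
        return f"S({self.x},{self.a},{self.b})"


@dataclass(frozen=True, order=True)
class FinalState:
    """A single connected mutant group of size ``w`` (0 and N absorbing)."""

    w: int

    def __repr__(self) -> str:
        return f"F({self.w})"


State = Union[TripletState, FinalState]


def canonicalize(gap1: int, groupA: int, gap2: int, groupB: int, N: int) -> State:
    """Reduce a raw cycle geometry to its canonical state.

    The arguments describe the cyclic arrangement
    ``groupA, gap1, groupB, gap2`` (sizes of the two mutant groups and the
    two wild-type gaps, read around the cycle).  If either group is empty or
    either gap is empty the configuration has at most one connected mutant
    group and a :class:`FinalState` is returned; otherwise the unique
    canonical triplet (minimal gap, smaller group, larger group).
    """
    sizes = (gap1, groupA, gap2, groupB)
    if any(s < 0 for s in sizes):
        raise ValueError(f"negative segment size in {sizes}")
    if gap1 + groupA + gap2 + groupB != N:
        raise ValueError(f"segment sizes {sizes} do not sum to N={N}")
    if groupA == 0 or groupB == 0:
        return FinalState(groupA + groupB)
    if gap1 == 0 or gap2 == 0:
        return FinalState(groupA + groupB)
    return TripletState(min(gap1, gap2), min(groupA, groupB), max(groupA, groupB))


def middle_state_count(N: int) -> int:
    """Closed-form number of two-group states: sum_w floor(w/2)*floor((N-w)/2)."""
    return sum((w // 2) * ((N - w) // 2) for w in range(N + 1))


def _iter_middle_states(N: int) -> Iterator[TripletState]:
    for a in range(1, N):
        for b in range(a, N):
            for x in range(1, N):
                if 1 <= N - x - a - b and x <= N - x - a - b:
                    yield TripletState(x, a, b)


class StateSpace:
    """Ordered enumeration of all states for a given ``N`` with index maps.

    Middle states come first, sorted by ``(a + b, x, a)``, followed by the
    final states ``F_0 ... F_N``.  The ordering is deterministic so indices
    are stable across runs.
    """

    def __init__(self, N: int):
        if N < 3:
            raise ValueError(f"N must be >= 3, got {N}")
        self.N = N
        self.middle: list[TripletState] = sorted(
            _iter_middle_states(N), key=lambda s: (s.w, s.x, s.a)
        )
        self.final: list[FinalState] = [FinalState(w) for w in range(N + 1)]
        self.states: list[State] = [*self.middle, *self.final]
        self._index: dict[State, int] = {s: i for i, s in enumerate(self.states)}
        assert len(self.middle) == middle_state_count(N)

    @property
    def n_middle(self) -> int:
        return len(self.middle)

    @property
    def n_final(self) -> int:
        return self.N + 1

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[State]:
        return iter(self.states)

    def index(self, state: State) -> int:
        """Integer index of ``state`` in the global ordering."""
        try:
            return self._index[state]
        except KeyError:
            raise KeyError(f"{state!r} is not a state of the N={self.N} space") from None

    def middle_index(self, state: TripletState) -> int:
        """Index of a middle state within the middle block."""
        i = self.index(state)
        if i >= self.n_middle:
            raise KeyError(f"{state!r} is not a middle state")
        return i

    def state(self, i: int) -> State:
        """Inverse of :meth:`index`."""
        if not 0 <= i < len(self.states):
            raise IndexError(f"state index {i} out of range for N={self.N}")
        return self.states[i]


def enumerate_states(N: int) -> StateSpace:
    """Build the full ordered state space for a cycle of size ``N``."""
    return StateSpace(N)


def config_to_state(occupancy, N: int | None = None) -> State:
    """Canonical state of an explicit 0/1 mutant occupancy around the cycle.

    Raises if the configuration has more than two mutant groups (such
    configurations cannot arise under Death-birth updating from at most two
    groups).
    """
    occ = [int(bool(v)) for v in occupancy]
    n = len(occ)
    if N is not None and N != n:
        raise ValueError("occupancy length does not match N")
    w = sum(occ)
    if w == 0 or w == n:
        return FinalState(w)
    # runs of mutants around the cycle: count boundaries 0->1
    starts = [i for i in range(n) if occ[i] and not occ[i - 1]]
    if len(starts) == 1:
        return FinalState(w)
    if len(starts) > 2:
        raise ValueError(f"configuration has {len(starts)} mutant groups; at most 2 supported")
    s1, s2 = starts
    len1 = next(k for k in range(1, n) if not occ[(s1 + k) % n])
    len2 = next(k for k in range(1, n) if not occ[(s2 + k) % n])
    gap12 = (s2 - (s1 + len1)) % n
    gap21 = (s1 - (s2 + len2)) % n
    return canonicalize(gap12, len1, gap21, len2, n)
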