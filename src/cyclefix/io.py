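"""Tabular views of the analytic results (pandas DataFrames, CSV/JSON)."""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Optional, Sequence

import pandas as pd

from .connected import fixprob_final, fixprob_final_derivs
from .separated import cond_time_all, fixprob_all, fixprob_derivs
from .states import FinalState, ModelParams, StateSpace, TripletState, enumerate_states
from .transitions import build_blocks

#: exact-rational mode is restricted to small populations, where Fraction
#: denominators stay manageable
EXACT_N_MAX = 15


def state_table(space: StateSpace) -> pd.DataFrame:
    """One row per state: index, kind, and its (x, a, b) or w coordinates."""
    rows = []
    for i, s in enumerate(space):
        if isinstance(s, TripletState):
            rows.append(dict(index=i, kind="middle", x=s.x, a=s.a, b=s.b, w=s.w))
        else:
            rows.append(dict(index=i, kind="final", x=None, a=None, b=None, w=s.w))
    return pd.DataFrame(rows)


def _d_values(N: int, d: Optional[Sequence[int]]) -> list[int]:
    return list(d) if d is not None else list(range(0, (N - 2) // 2 + 1))


def fixprob_table(N: int, d: Sequence[int], r_values: Iterable[float]) -> pd.DataFrame:
    """Fixation probability of two mutants for each (d, r) combination."""
    rows = []
    space = enumerate_states(N)
    for r in r_values:
        params = ModelParams(N, float(r))
        profile = fixprob_all(space, params)
        for dd in _d_values(N, d):
            eff = min(dd, N - 2 - dd)
            state = FinalState(2) if eff == 0 else TripletState(eff, 1, 1)
            psi = fixprob_final(2, params) if eff == 0 else profile.value(state)
            rows.append(dict(N=N, d=dd, r=float(r), Psi=float(psi)))
    return pd.DataFrame(rows)


def derivative_table(N: int, d: Optional[Sequence[int]] = None, exact: bool = False) -> pd.DataFrame:
    """Fixation probability and its first two ``r``-derivatives at ``r = 1``
    for two mutants at each distance ``d`` (the per-``N`` derivative table).

    With ``exact=True`` (``N <= EXACT_N_MAX``) entries are Fractions.
    """
    if exact and N > EXACT_N_MAX:
        raise ValueError(f"exact-rational mode supports N <= {EXACT_N_MAX}")
    params = ModelParams(N, Fraction(1) if exact else 1.0)
    space = enumerate_states(N)
    profile = fixprob_derivs(space, params, order=2)
    rows = []
    for dd in _d_values(N, d):
        eff = min(dd, N - 2 - dd)
        if eff == 0:
            vals = (
                fixprob_final(2, params),
                fixprob_final_derivs(2, params, 1),
                fixprob_final_derivs(2, params, 2),
            )
        else:
            st = TripletState(eff, 1, 1)
            vals = (profile.value(st, 0), profile.value(st, 1), profile.value(st, 2))
        if not exact:
            vals = tuple(float(v) for v in vals)
        rows.append(dict(N=N, d=dd, Psi=vals[0], dPsi=vals[1], d2Psi=vals[2]))
    return pd.DataFrame(rows)


def fixtime_table(N: int, r: float, exact: bool = False) -> pd.DataFrame:
    """Fixation probability and conditional fixation time for every state."""
    if exact and N > EXACT_N_MAX:
        raise ValueError(f"exact-rational mode supports N <= {EXACT_N_MAX}")
    params = ModelParams(N, Fraction(r) if exact else float(r))
    space = enumerate_states(N)
    blocks = build_blocks(space, params)
    profile = fixprob_all(space, params, blocks)
    times = cond_time_all(space, params, blocks)
    rows = []
    for i, s in enumerate(space):
        rows.append(
            dict(
                N=N,
                r=r if exact else float(r),
                state=repr(s),
                Psi=profile.psi[i],
                T_A=times.tau[i],
            )
        )
    return pd.DataFrame(rows)


def transition_table(N: int, r: float) -> pd.DataFrame:
    """Sparse listing of the full one-step matrix: from, to, probability."""
    params = ModelParams(N, float(r))
    space = enumerate_states(N)
    blocks = build_blocks(space, params)
    rows = []
    nm = space.n_middle
    for name, M, roff, coff in (
        ("Q1", blocks.Q1, 0, 0),
        ("Q2", blocks.Q2, 0, nm),
        ("Q3", blocks.Q3, nm, nm),
    ):
        coo = M.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            rows.append(
                dict(
                    block=name,
                    from_index=int(i + roff),
                    to_index=int(j + coff),
                    from_state=repr(space.state(i + roff)),
                    to_state=repr(space.state(j + coff)),
                    probability=float(v),
                )
            )
    return pd.DataFrame(rows).sort_values(["from_index", "to_index"]).reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str, fmt: str = "csv", decimals: int = 8) -> None:
    """Write a result table as CSV or JSON records with fixed precision."""
    if fmt == "csv":
        df.to_csv(path, index=False, float_format=f"%.{decimals}f")
    elif fmt == "json":
        df.to_json(path, orient="records", double_precision=min(decimals, 15), indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
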