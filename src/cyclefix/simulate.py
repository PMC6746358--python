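"""Monte Carlo simulation of the Death-birth (and Birth-death) process.

The simulator works on explicit 0/1 occupancy arrays over the cycle
positions — no lumping into gap/group coordinates — so it is an
independent check of the analytic Markov-chain machinery.  Rounds are
counted exactly as in the analytic time unit: one death draw per round,
including rounds in which the state does not change.

``run_db`` / ``run_bd`` are scalar reference implementations; ``estimate``
advances a whole batch of replicates in lock-step with vectorised numpy
operations, compacting absorbed runs out of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np


@dataclass
class SimEstimate:
    """Aggregated fixation statistics from independent replicates."""

    N: int
    d: Optional[int]
    r: float
    process: str
    n_runs: int
    n_fixed: int
    fixprob_hat: float
    fixprob_se: float
    mean_cond_time: float
    cond_time_se: float
    seed: Optional[int]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check_positions(N: int, positions: Iterable[int]) -> np.ndarray:
    occ = np.zeros(N, dtype=np.uint8)
    pos = [p % N for p in positions]
    occ[pos] = 1
    return occ


def run_db(N: int, initial_mutant_positions: Iterable[int], r: float, rng: np.random.Generator):
    """Single Death-birth trajectory; returns ``(fixed, rounds)``.

    Each round: a uniform individual dies; its two neighbours compete to
    refill the site with offspring, the mutant side weighted ``r`` against
    ``1``.  Runs until extinction or fixation of the mutant lineage.
    """
    occ = _check_positions(N, initial_mutant_positions)
    count = int(occ.sum())
    if count == 0 or count == N:
        return count == N, 0
    p_mut = r / (1.0 + r)
    rounds = 0
    while 0 < count < N:
        rounds += 1
        i = int(rng.integers(N))
        s = occ[i - 1] + occ[(i + 1) % N]
        if s == 2:
            new = 1
        elif s == 0:
            new = 0
        else:
            new = 1 if rng.random() < p_mut else 0
        count += new - int(occ[i])
        occ[i] = new
    return count == N, rounds


def run_bd(N: int, initial_mutant_positions: Iterable[int], r: float, rng: np.random.Generator):
    """Single Birth-death trajectory; returns ``(fixed, rounds)``.

    Each round: a parent is drawn fitness-proportionally from the whole
    population, and its offspring replaces a uniformly chosen neighbour.
    """
    occ = _check_positions(N, initial_mutant_positions)
    count = int(occ.sum())
    if count == 0 or count == N:
        return count == N, 0
    rounds = 0
    while 0 < count < N:
        rounds += 1
        fitness = np.where(occ == 1, r, 1.0)
        cum = np.cumsum(fitness)
        parent = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        child = (parent + (1 if rng.random() < 0.5 else -1)) % N
        new = occ[parent]
        count += int(new) - int(occ[child])
        occ[child] = new
    return count == N, rounds


def _initial_occupancy(N: int, d: int, n: int) -> np.ndarray:
    """Batch of two-mutant configurations at distance ``d``."""
    if not 0 <= d <= N - 2:
        raise ValueError(f"d={d} outside [0, {N - 2}]")
    occ = np.zeros((n, N), dtype=np.uint8)
    occ[:, 0] = 1
    occ[:, d + 1] = 1
    return occ


def _batch_db(occ: np.ndarray, r: float, rng: np.random.Generator):
    n, N = occ.shape
    p_mut = r / (1.0 + r)
    counts = occ.sum(axis=1).astype(np.int64)
    alive = np.arange(n)
    rounds = np.zeros(n, dtype=np.int64)
    fixed = np.zeros(n, dtype=bool)
    t = 0
    while alive.size:
        t += 1
        m = alive.size
        die = rng.integers(0, N, size=m)
        rows = np.arange(m)
        left = occ[rows, (die - 1) % N]
        right = occ[rows, (die + 1) % N]
        s = left + right
        new = np.where(s == 2, 1, 0).astype(np.uint8)
        mixed = s == 1
        if mixed.any():
            new[mixed] = (rng.random(int(mixed.sum())) < p_mut).astype(np.uint8)
        old = occ[rows, die]
        occ[rows, die] = new
        counts += new.astype(np.int64) - old.astype(np.int64)
        done = (counts == 0) | (counts == N)
        if done.any():
            idx = alive[done]
            rounds[idx] = t
            fixed[idx] = counts[done] == N
            keep = ~done
            occ = occ[keep]
            counts = counts[keep]
            alive = alive[keep]
    return fixed, rounds


def _batch_bd(occ: np.ndarray, r: float, rng: np.random.Generator):
    n, N = occ.shape
    counts = occ.sum(axis=1).astype(np.int64)
    alive = np.arange(n)
    rounds = np.zeros(n, dtype=np.int64)
    fixed = np.zeros(n, dtype=bool)
    t = 0
    while alive.size:
        t += 1
        m = alive.size
        fitness = np.where(occ == 1, r, 1.0)
        cum = np.cumsum(fitness, axis=1)
        u = rng.random(m) * cum[:, -1]
        parent = (u[:, None] < cum).argmax(axis=1)
        step = np.where(rng.random(m) < 0.5, 1, -1)
        child = (parent + step) % N
        rows = np.arange(m)
        new = occ[rows, parent]
        old = occ[rows, child]
        occ[rows, child] = new
        counts += new.astype(np.int64) - old.astype(np.int64)
        done = (counts == 0) | (counts == N)
        if done.any():
            idx = alive[done]
            rounds[idx] = t
            fixed[idx] = counts[done] == N
            keep = ~done
            occ = occ[keep]
            counts = counts[keep]
            alive = alive[keep]
    return fixed, rounds


def estimate(
    N: int,
    d: int,
    r: float,
    n_iter: int,
    seed: Optional[int] = None,
    process: str = "db",
) -> SimEstimate:
    """Fixation probability and fixation-conditioned mean time from
    ``n_iter`` independent replicates of the two-mutant initial condition.

    Standard errors: binomial for the fixation fraction, sample standard
    error over the fixed replicates for the conditional time.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if process not in ("db", "bd"):
        raise ValueError(f"process must be 'db' or 'bd', got {process!r}")
    rng = np.random.default_rng(seed)
    occ = _initial_occupancy(N, d, n_iter)
    fixed, rounds = (_batch_db if process == "db" else _batch_bd)(occ, float(r), rng)
    n_fixed = int(fixed.sum())
    phat = n_fixed / n_iter
    se = float(np.sqrt(phat * (1 - phat) / n_iter))
    if n_fixed > 0:
        ct = rounds[fixed].astype(float)
        mean_ct = float(ct.mean())
        ct_se = float(ct.std(ddof=1) / np.sqrt(n_fixed)) if n_fixed > 1 else float("nan")
    else:
        mean_ct = float("nan")
        ct_se = float("nan")
    return SimEstimate(
        N=N,
        d=d,
        r=float(r),
        process=process,
        n_runs=n_iter,
        n_fixed=n_fixed,
        fixprob_hat=phat,
        fixprob_se=se,
        mean_cond_time=mean_ct,
        cond_time_se=ct_se,
        seed=seed,
    )


def moran_well_mixed_fixprob(N: int, w: int, r: float) -> float:
    """Well-mixed Moran fixation probability of ``w`` mutants,
    ``(1 - r^-w) / (1 - r^-N)``; by the isothermal theorem this is also the
    Birth-death fixation probability on any regular graph such as the cycle."""
    if r == 1.0:
        return w / N
    return (1.0 - r**-w) / (1.0 - r**-N)
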