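# Methods

## Model and assumptions

`N ≥ 3` individuals occupy the nodes of a cycle; each has exactly two
neighbours.  Two types exist: mutants of constant fitness `r > 0` and
wild-types of fitness 1 (fitness is frequency-independent — no game payoffs).
The update rule is Death-birth (DB): each elementary *round* one individual
is chosen uniformly (probability `1/N`) to die, and its two neighbours
compete to place an identical offspring in the vacancy, success probability
proportional to fitness.  Against a mixed neighbour pair the offspring is a
mutant with probability `r/(1+r)`; two same-type neighbours replace the
deceased deterministically.  The convention throughout is that `r` is the
*mutant's* relative fitness: `r > 1` means mutants are advantaged.  (Some
verbal descriptions of this model family define the ratio the other way
round; every formula, table and result here uses the mutant-relative
convention consistently.)

An optional Birth-death (BD) mode exists only in the simulator: a parent is
drawn fitness-proportionally from the whole population and its offspring
replaces a uniformly chosen neighbour.  On a regular graph such as the
cycle, BD fixation probabilities equal the well-mixed Moran values
(isothermal theorem), which the simulator uses as its closed-form check.

## State space

Starting from at most two mutant groups, DB updating can merge, grow,
shrink or extinguish groups but never split one (only border individuals
change type, and a border flip keeps each group connected).  Configurations
are therefore classified, up to rotation and reflection, as

- **middle states** `S_{x,a,b}`: two groups of sizes `a ≤ b`, minimal gap
  `x`, other gap `N − x − a − b ≥ x ≥ 1`;
- **final states** `F_w`: one connected group of `w` mutants, `w = 0 … N`,
  with `F_0` and `F_N` absorbing.

Middle states are ordered by `(a+b, x, a)`, then `F_0 … F_N`; the ordering
is deterministic so indices are reproducible.  The total count is
`Σ_w ⌊w/2⌋·⌊(N−w)/2⌋ + N + 1`, which grows as `N³/24` (40 526 states at
`N = 100`).  Since every row of the transition matrix has at most 9
nonzeros, sparse storage keeps memory and solve cost modest at this size.

## Transition matrix

Transitions are generated from first-principles border enumeration rather
than from a lookup table: a middle state has at most 8 border individuals
(up to four group ends, up to four gap ends), each contributing one death
event whose outcome geometry is canonicalized and accumulated.  Events that
land on the same canonical state are summed — e.g. from `S_{2,1,1}` at
`N = 6` all four wild-types are gap ends and all four mutant-win outcomes
canonicalize to `S_{1,1,2}`, total probability `4·(1/N)·r/(1+r)`.  The
residual mass is an explicit diagonal self-loop, so the time unit counts
every round including those that change nothing.  Lumpability of the
explicit-position chain onto these classes is verified, not assumed: the
test suite builds the full configuration chain for `N ≤ 12`, checks that
all configurations in a class yield identical lumped rows, and compares
the lumped matrix entrywise with the assembled blocks.

Group-merging and group-extinction events always involve an individual
whose two neighbours share a type, so every middle→final probability is
exactly `1/N`: the `Q2` block carries no `r` dependence and its derivative
vanishes.  `Q1` and `Q3` entries are constants times `1`, `r/(1+r)` or
`1/(1+r)`; their first and second `r`-derivatives are accumulated from the
closed-form derivatives of those weights via a small second-order
Taylor-mode (jet) arithmetic that works identically for floats and exact
rationals.

## Fixation probabilities, derivatives, times

The single-group chain is one-dimensional with ratios
`γ_1 = (r+1)/(2r)`, `γ_w = 1/r` (interior), `γ_{N−1} = 2/(r+1)`; `π_w`
follows from the standard partial-product formula, differentiated
analytically through the jets (no numerical differentiation).  For the
block system:

- `Ψ_F = π`; `Ψ_S` solves `(I − Q1)Ψ_S = Q2 π`.  Invertibility follows
  from transience of the middle states (spectral radius of `Q1` < 1,
  asserted in tests).
- `Ψ_S' = (I−Q1)^{-1}(Q1' Ψ_S + Q2 π')` and
  `Ψ_S'' = (I−Q1)^{-1}(2 Q1' Ψ_S' + Q1'' Ψ_S + Q2 π'')` — obtained by
  differentiating the linear system; each derivative order is one more
  sparse solve against the same factorisation.
- Times use `θ = Ψ ∘ T^A` (with `θ = 0` at both absorbing states, the
  natural convention since fixation from `F_0` is impossible):
  `(I − Q1)θ_S = Q1 Ψ_S + Q2 π + Q2 θ_F`, then `T^A_S = θ_S ⊘ Ψ_S`.  On
  the final chain, θ satisfies a tridiagonal system solved directly; an
  independent explicit telescoped-sum solution is also implemented and the
  two must agree (bit-exactly in rational mode).

The explicit inverse `(I−Q1)^{-1}` is never formed: the float path uses a
sparse LU factorisation (`scipy.sparse.linalg.splu`) with one step of
iterative refinement, which keeps the `N = 100` second derivatives accurate
to ~1e-9 relative.  The exact path (rational `r`, guarded to `N ≤ 15`
where Fraction growth is harmless) uses dense Gaussian elimination over
`fractions.Fraction`, and a Thomas sweep for the tridiagonal θ system, so
small-`N` results are bit-exact rational numbers.

## Simulator

The Monte Carlo engine stores explicit 0/1 occupancy over positions — no
triplet lumping — and counts every round.  `run_db`/`run_bd` are scalar
reference implementations; `estimate` advances all replicates of one
parameter set in lock-step with vectorised numpy draws, removing absorbed
runs from the batch, which makes 10⁴-replicate grids run in seconds.  One
seeded `numpy` Generator drives each `estimate` call, so results are
reproducible; the batch path is validated against both the scalar path and
the analytic values.  Reported uncertainties are the binomial standard
error for the fixation fraction and the sample standard error over fixed
runs for the conditional time.

What the simulator does *not* emulate: mutation, demographic change,
fitness noise, or graphs other than the cycle.  Agreement between simulator
and analytics therefore validates the Markov-chain machinery on this model,
not the model's fidelity to any particular biological population.

## Problem sizes and tolerances

- Analytic surfaces are exercised at `N = 6, 25, 100` (the published
  table) and `6 ≤ N ≤ 60` for the closed-form first-derivative identities
  `(2N−5)/2N` and `(2N−6)/2N` (tolerance 1e-9).
- Brute-force equivalence (full configuration chain, lumping, absorption
  and conditioned times to 1e-10) runs at `N ∈ {6, 9, 12}`.
- Simulation agreement uses 10⁴ replicates per cell on the grid
  `r ∈ {0.5, 1, 1.5, 2} × d ∈ {0, 1, 2} × N ∈ {6, 25}`, at the 3-standard-
  error level, with fixed seeds.  At `(N=25, r=0.5)` the analytic fixation
  probability is ~1e-7, so no fixations are expected in 10⁴ runs; there the
  binomial band is evaluated at the analytic value and the conditional-time
  comparison (whose estimator does not exist without fixations) is skipped.
- Printed-precision comparisons: 3–4-decimal table cells to ±1 in the last
  digit, 8-decimal cells to 1e-6 relative.

## Numerical and design choices

- **Derivatives analytically, never by finite differences** in the product
  pipeline; central finite differences appear only as independent test
  oracles (steps 1e-4 … 1e-5).
- **Float range**: interior ratios `1/r` make the partial products scale
  like `r^±(N−3)`; in float this is safe for `|log r|·N ≲ 700` (far beyond
  `N = 100` at the `r` values of interest).  The telescoped-sum time
  formula additionally *cancels* terms of that magnitude, so it is only
  used in float at moderate `N`; the tridiagonal solve is the default.
- **Degenerate inputs**: `d` larger than the opposite gap is reflected to
  `min(d, N−2−d)` rather than rejected; `d = 0` delegates to the connected
  chain; conditional times from `F_0` are reported as undefined (NaN)
  rather than extrapolated.
- **Ties** (`a = b`, equal gaps) are single canonical states; multiplicity
  is handled by event aggregation, which the brute-force lumping check
  confirms.

## Known limitations

- At most two mutant groups: sufficient for every initial condition
  treated here (groups cannot split under DB on a cycle), but general
  `k`-group initial conditions are out of scope.
- Exact-rational mode is limited to `N ≤ 15`; beyond that the float path
  with iterative refinement is used and verified to ~1e-9 relative.
- No closed-form symbolic `Ψ(r)` for general `N` is attempted; the
  derivative identities at neutrality are verified numerically over
  `6 ≤ N ≤ 60`, not proved.
- The BD mode exists for the well-mixed contrast only; no analytic BD
  chain is built.
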