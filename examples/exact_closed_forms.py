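"""Exact rational arithmetic: closed forms without floating-point error.

Passing r as a fractions.Fraction switches the whole pipeline (transition
blocks, linear solves, derivative propagation) to exact rationals, so
small-N results are bit-exact rational functions of r evaluated at r.
"""

from fractions import Fraction

from cyclefix import ModelParams, TripletState, enumerate_states, fixprob_final, taylor_neutral
from cyclefix.separated import fixprob_all

p = ModelParams(6, Fraction(2))
print("N=6, r=2, exact mode")
print("  pi_2 (connected pair)      =", fixprob_final(2, p))
space = enumerate_states(6)
prof = fixprob_all(space, p)
print("  Psi at S(1,1,1) (d=1)      =", prof.value(TripletState(1, 1, 1)))
print("  Psi at S(2,1,1) (d=2)      =", prof.value(TripletState(2, 1, 1)))

print()
print("Taylor expansion of Psi around r = 1 (c0 + c1 (r-1) + c2 (r-1)^2):")
for d in (0, 1, 2):
    c0, c1, c2 = taylor_neutral(6, d)
    print(f"  d={d}:  c0={c0}  c1={c1}  c2={c2}")
print()
print("The shared c0 = 1/3 is the neutral frequency; the connected pair has")
print("the larger linear response c1, while c2 ranks the separated distances.")
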