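"""Second-order Taylor-mode arithmetic.

A :class:`Jet` carries a value together with its first and second derivative
with respect to the selection parameter ``r``, and propagates them through
sums, products and quotients.  It works with floats and with
:class:`fractions.Fraction` components alike, so the same derivative code
serves both the floating and the exact-rational pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Jet:
    f: object  # value
    d1: object = 0  # first derivative
    d2: object = 0  # second derivative

    @staticmethod
    def variable(value):
        """The jet of the independent variable itself (d/dr r = 1)."""
        return Jet(value, 1, 0)

    @staticmethod
    def constant(value):
        return Jet(value, 0, 0)

    def _coerce(self, other) -> "Jet":
        return other if isinstance(other, Jet) else Jet(other, 0, 0)

    def __add__(self, other):
        o = self._coerce(other)
        return Jet(self.f + o.f, self.d1 + o.d1, self.d2 + o.d2)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.f, -self.d1, -self.d2)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Jet(
            self.f * o.f,
            self.d1 * o.f + self.f * o.d1,
            self.d2 * o.f + 2 * self.d1 * o.d1 + self.f * o.d2,
        )

    __rmul__ = __mul__

    def reciprocal(self) -> "Jet":
        g, g1, g2 = self.f, self.d1, self.d2
        inv = 1 / g
        return Jet(inv, -g1 * inv * inv, (2 * g1 * g1 - g * g2) * inv * inv * inv)

    def __truediv__(self, other):
        return self * self._coerce(other).reciprocal()

    def __rtruediv__(self, other):
        return self._coerce(other) * self.reciprocal()
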