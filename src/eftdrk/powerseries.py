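"""Truncated power series with exact rational coefficients.

Used to manipulate the frequency-dependent update coefficients of fitted
two-derivative Runge-Kutta methods symbolically in the fitting parameter
``nu = omega * h``.  A :class:`PowerSeries` of truncation order ``K`` knows
its coefficients for powers ``0..K``; higher powers are *unknown*, not zero,
and arithmetic propagates that uncertainty (the order of a sum or product is
the minimum of the operands' orders).  All coefficients are
:class:`fractions.Fraction`, so algebraic identities among tabulated method
coefficients are checked exactly rather than in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, (int, Rational)):
        return Fraction(x)
    raise TypeError(f"expected an exact rational, got {type(x).__name__}")


@dataclass(frozen=True)
class PowerSeries:
    """A polynomial ``sum_k a_k nu^k`` known exactly up to power ``truncation_order``."""

    coeffs: dict[int, Fraction] = field(default_factory=dict)
    truncation_order: int = 0

    def __post_init__(self):
        clean = {
            int(k): _as_fraction(v)
            for k, v in self.coeffs.items()
            if k <= self.truncation_order and v != 0
        }
        if any(k < 0 for k in clean):
            raise ValueError("negative powers are not supported")
        object.__setattr__(self, "coeffs", clean)

    @classmethod
    def constant(cls, value, truncation_order: int) -> "PowerSeries":
        return cls({0: _as_fraction(value)}, truncation_order)

    def coefficient(self, power: int) -> Fraction:
        """Exact coefficient of ``nu**power``; error beyond the valid order."""
        if power > self.truncation_order:
            raise ValueError(
                f"power {power} exceeds truncation order {self.truncation_order}"
            )
        return self.coeffs.get(power, Fraction(0))

    def __add__(self, other) -> "PowerSeries":
        if isinstance(other, (int, Fraction, Rational)):
            other = PowerSeries.constant(other, self.truncation_order)
        order = min(self.truncation_order, other.truncation_order)
        coeffs: dict[int, Fraction] = {}
        for k in range(order + 1):
            coeffs[k] = self.coeffs.get(k, Fraction(0)) + other.coeffs.get(k, Fraction(0))
        return PowerSeries(coeffs, order)

    __radd__ = __add__

    def __neg__(self) -> "PowerSeries":
        return PowerSeries({k: -v for k, v in self.coeffs.items()}, self.truncation_order)

    def __sub__(self, other) -> "PowerSeries":
        if isinstance(other, (int, Fraction, Rational)):
            other = PowerSeries.constant(other, self.truncation_order)
        return self + (-other)

    def __rsub__(self, other) -> "PowerSeries":
        return (-self) + other

    def __mul__(self, other) -> "PowerSeries":
        if isinstance(other, (int, Fraction, Rational)):
            scale = _as_fraction(other)
            return PowerSeries(
                {k: scale * v for k, v in self.coeffs.items()}, self.truncation_order
            )
        order = min(self.truncation_order, other.truncation_order)
        coeffs: dict[int, Fraction] = {}
        for i, a in self.coeffs.items():
            for j, b in other.coeffs.items():
                k = i + j
                if k <= order:
                    coeffs[k] = coeffs.get(k, Fraction(0)) + a * b
        return PowerSeries(coeffs, order)

    __rmul__ = __mul__

    def equals_up_to_valid_order(self, other: "PowerSeries") -> bool:
        order = min(self.truncation_order, other.truncation_order)
        return all(self.coefficient(k) == other.coefficient(k) for k in range(order + 1))

    def evaluate(self, nu: float) -> float:
        """Horner evaluation at a float ``nu`` (the only place exactness is dropped)."""
        acc = 0.0
        for k in range(self.truncation_order, -1, -1):
            acc = acc * nu + float(self.coeffs.get(k, Fraction(0)))
        return acc

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        terms = " + ".join(f"({v})*nu^{k}" for k, v in sorted(self.coeffs.items()))
        return f"PowerSeries({terms or '0'} + O(nu^{self.truncation_order + 1}))"


def series_arith(op: str, x: PowerSeries, y) -> PowerSeries:
    """Functional front end for series arithmetic: op in {add, mul, scale}."""
    if op == "add":
        return x + y
    if op == "mul":
        return x * y
    if op == "scale":
        return x * _as_fraction(y)
    raise ValueError(f"unknown op {op!r}")
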