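"""Order-condition and exponential-fitting verification.

Two independent kinds of evidence certify a fitted TDRK method here:

* **Algebraic order.**  The sixth-order conditions couple the fixed tableau
  ``(c, A)`` with the nu-dependent update weights.  Each condition has the form
  ``b(nu) . phi = 1/gamma + O(nu^p)`` (plus ``eta = 1 + O(nu^7)`` and
  ``beta = 1 + O(nu^6)``).  They are checked *coefficientwise* on the exact
  rational Taylor series of the weights -- no floating-point sampling -- so a
  single wrong digit in a tabulated coefficient is detected.

* **Exponential fitting.**  The one-step defect operator

  ``L[y](t) = y(t+h) - eta y(t) - h beta y'(t) - h^2 sum_i b_i y''(t + c_i h)``

  must annihilate every member of a method's reference set (e.g.
  ``exp(+-i w t)`` and ``t exp(+-i w t)`` for method "a").  The residual is
  evaluated with exact analytic derivatives of the reference function.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .powerseries import PowerSeries
from .tableaux import CoefficientSeries, TDRKTableau, fitted_weights

__all__ = [
    "ConditionResult",
    "check_order_conditions",
    "check_tableau_row_sums",
    "fitting_residual",
    "REFERENCE_SETS",
]

F = Fraction


@dataclass(frozen=True)
class ConditionResult:
    name: str
    passed: bool
    checkable: bool
    first_offending_power: int | None
    detail: str = ""


def _dot(b: tuple[PowerSeries, ...], phi: list[Fraction]) -> PowerSeries:
    acc = PowerSeries.constant(0, min(s.truncation_order for s in b))
    for bi, pi in zip(b, phi):
        acc = acc + bi * pi
    return acc


def _tableau_vectors(tab: TDRKTableau) -> dict[str, list[Fraction]]:
    c = list(tab.c_exact)
    A = tab.A_exact
    s = tab.s

    def amul(v):
        return [sum((A[i][j] * v[j] for j in range(s)), F(0)) for i in range(s)]

    def had(u, v):
        return [ui * vi for ui, vi in zip(u, v)]

    e = [F(1)] * s
    Ae = amul(e)
    Ac = amul(c)
    c2 = had(c, c)
    return {
        "e": e,
        "c": c,
        "c2": c2,
        "c3": had(c2, c),
        "c4": had(c2, c2),
        "Ae": Ae,
        "Ac": Ac,
        "Ac2": amul(c2),
        "c.Ac": had(c, Ac),
        "c.Ae": had(c, Ae),
        "c2.Ae": had(c2, Ae),
        "Ae.Ae": had(Ae, Ae),
        "A2e": amul(Ae),
    }


# (vector key, right-hand side, required O(nu^p))  --  reduced list, valid
# when the row-sum assumption A e = c^2/2 holds
_REDUCED_CONDITIONS = [
    ("e", F(1, 2), 5),
    ("c", F(1, 6), 4),
    ("c2", F(1, 12), 3),
    ("c3", F(1, 20), 2),
    ("Ac", F(1, 120), 2),
    ("c4", F(1, 30), 1),
    ("c.Ac", F(1, 180), 1),
    ("Ac2", F(1, 360), 1),
]

# extra conditions of the full order-6 list, redundant under A e = c^2/2
_EXTRA_CONDITIONS = [
    ("Ae", F(1, 24), 3),
    ("c.Ae", F(1, 40), 2),
    ("c2.Ae", F(1, 60), 1),
    ("Ae.Ae", F(1, 120), 1),
    ("A2e", F(1, 720), 1),
]


def _check_series_condition(
    name: str, lhs: PowerSeries, rhs: Fraction, o_power: int
) -> ConditionResult:
    if lhs.truncation_order < o_power - 1:
        return ConditionResult(
            name, False, False, None,
            f"series truncation {lhs.truncation_order} < required power {o_power - 1}",
        )
    for k in range(o_power):
        want = rhs if k == 0 else F(0)
        got = lhs.coefficient(k)
        if got != want:
            return ConditionResult(
                name, False, True, k, f"coefficient of nu^{k} is {got}, expected {want}"
            )
    return ConditionResult(name, True, True, None)


def check_order_conditions(
    cs: CoefficientSeries, tableau: TDRKTableau, full_list: bool = False
) -> list[ConditionResult]:
    """Verify the sixth-order conditions for one method's coefficient series.

    The default checks the ten-condition reduced list (valid because the
    tableau satisfies ``A e = c^2/2``, which is asserted separately by
    :func:`check_tableau_row_sums`); ``full_list=True`` additionally checks
    the five conditions that the row-sum assumption makes redundant.
    """
    vecs = _tableau_vectors(tableau)
    results = [
        _check_series_condition("eta = 1 + O(nu^7)", cs.eta, F(1), 7),
        _check_series_condition("beta = 1 + O(nu^6)", cs.beta, F(1), 6),
    ]
    conditions = list(_REDUCED_CONDITIONS)
    if full_list:
        conditions += _EXTRA_CONDITIONS
    for key, rhs, p in conditions:
        lhs = _dot(cs.b, vecs[key])
        results.append(
            _check_series_condition(f"b.{key} = {rhs} + O(nu^{p})", lhs, rhs, p)
        )
    return results


def check_tableau_row_sums(tableau: TDRKTableau) -> bool:
    """Exact-rational check of the simplifying row-sum assumption A e = c^2/2."""
    return all(
        sum(row, F(0)) == ci**2 / 2
        for row, ci in zip(tableau.A_exact, tableau.c_exact)
    )


# ---------------------------------------------------------------------------
# Exponential-fitting residual of the one-step defect operator
# ---------------------------------------------------------------------------

def _ref_function(ref_id: str, omega: float):
    """Return (y, y', y'') as callables of t, complex-valued, exact analytics."""
    w = omega
    table = {
        "one": (lambda t: 1.0 + 0j, lambda t: 0j, lambda t: 0j),
        "t": (lambda t: t + 0j, lambda t: 1.0 + 0j, lambda t: 0j),
        "t_sq": (lambda t: t * t + 0j, lambda t: 2.0 * t + 0j, lambda t: 2.0 + 0j),
        "t_cubed": (
            lambda t: t**3 + 0j,
            lambda t: 3.0 * t * t + 0j,
            lambda t: 6.0 * t + 0j,
        ),
        "exp_iwt": (
            lambda t: np.exp(1j * w * t),
            lambda t: 1j * w * np.exp(1j * w * t),
            lambda t: -(w**2) * np.exp(1j * w * t),
        ),
        "t_exp_iwt": (
            lambda t: t * np.exp(1j * w * t),
            lambda t: (1 + 1j * w * t) * np.exp(1j * w * t),
            lambda t: (2j * w - w**2 * t) * np.exp(1j * w * t),
        ),
        "exp_2iwt": (
            lambda t: np.exp(2j * w * t),
            lambda t: 2j * w * np.exp(2j * w * t),
            lambda t: -4 * w**2 * np.exp(2j * w * t),
        ),
        "t_exp_2iwt": (
            lambda t: t * np.exp(2j * w * t),
            lambda t: (1 + 2j * w * t) * np.exp(2j * w * t),
            lambda t: (4j * w - 4 * w**2 * t) * np.exp(2j * w * t),
        ),
    }
    if ref_id not in table:
        raise ValueError(f"unknown reference function {ref_id!r}")
    return table[ref_id]


#: reference sets annihilated (up to weight-source accuracy) by each method
REFERENCE_SETS = {
    "a": ("exp_iwt", "t_exp_iwt"),
    "b": ("one", "t", "t_sq", "t_cubed", "exp_iwt", "exp_2iwt"),
    "c": ("one", "t", "t_sq", "t_cubed", "t_exp_2iwt"),
}


def fitting_residual(
    method_id: str,
    nu: float,
    ref_function: str,
    t: float,
    h: float,
    tableau: TDRKTableau | None = None,
) -> complex:
    """Defect ``L[y](t)`` of one method's update applied to a reference function.

    ``nu = omega * h`` fixes the frequency ``omega = nu / h`` at which the
    reference function oscillates.  For members of the method's reference set
    the residual vanishes to the accuracy of the weight source (machine
    precision for the exact solve; the series truncation bound otherwise).
    """
    if tableau is None:
        from .tableaux import limit_tableau

        tableau = limit_tableau()
    omega = nu / h
    y, dy, d2y = _ref_function(ref_function, omega)
    w = fitted_weights(method_id, nu)
    stage_sum = sum(
        bi * d2y(t + float(ci) * h) for bi, ci in zip(w.b, tableau.c_exact)
    )
    return complex(y(t + h) - w.eta * y(t) - h * w.beta * dy(t) - h * h * stage_sum)
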