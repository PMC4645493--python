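"""Stage structure and frequency-dependent update weights of the EFTDRK family.

The integrators in this package are four-stage explicit two-derivative
Runge-Kutta (TDRK) schemes.  The stage abscissae ``c`` and stage matrix ``A``
are fixed rational constants shared by the whole family; what varies between
methods is the *update*: the scalar weights ``eta(nu)`` and ``beta(nu)`` and the
vector ``b(nu)`` are functions of ``nu = omega * h``, the product of a fitting
frequency and the step size.  At ``nu = 0`` every variant collapses to the same
constant-coefficient sixth-order prototype (the "limit method").

Three exponentially fitted variants are provided:

* method ``a`` -- fitted to ``{exp(+-i w t), t exp(+-i w t)}``; its weights are
  obtained either by solving the 6x6 trigonometric fitting system exactly or,
  for small ``|nu|``, from tabulated Taylor series (the exact solve suffers
  catastrophic cancellation as ``nu -> 0``).
* methods ``b`` and ``c`` -- fitted to reference sets mixing low-degree
  polynomials with ``exp(i w t)``/``exp(2 i w t)`` terms; they are evaluated
  from their tabulated truncated Taylor series.

All tabulated coefficients are stored as exact rationals and converted to
floating point only at evaluation time, so transcription faults are caught by
the exact order-condition checker in :mod:`eftdrk.series_checks`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import cached_property

import numpy as np

from .powerseries import PowerSeries

__all__ = [
    "TDRKTableau",
    "FittedWeights",
    "CoefficientSeries",
    "limit_tableau",
    "weights_a",
    "weights_series",
    "fitted_weights",
    "coefficient_series",
    "SERIES_SWITCH",
    "SERIES_VALIDITY_RADIUS",
]

F = Fraction

#: below this |nu| the exact trigonometric solve for method "a" loses digits
#: to cancellation and the Taylor series is used instead
SERIES_SWITCH = 0.05

#: |nu| beyond which the truncated series' tail is no longer negligible
#: (coefficients decay fast enough that truncation error is ~1e-12 inside)
SERIES_VALIDITY_RADIUS = 1.5


@dataclass(frozen=True)
class TDRKTableau:
    """Fixed stage structure ``(c, A)`` plus the prototype (nu=0) update weights."""

    c_exact: tuple[Fraction, ...]
    A_exact: tuple[tuple[Fraction, ...], ...]
    b_limit_exact: tuple[Fraction, ...]
    eta_limit: Fraction = F(1)
    beta_limit: Fraction = F(1)

    def __post_init__(self):
        s = len(self.c_exact)
        if len(self.A_exact) != s or any(len(row) != s for row in self.A_exact):
            raise ValueError("A must be s x s")
        for i in range(s):
            if any(self.A_exact[i][j] != 0 for j in range(i, s)):
                raise ValueError("A must be strictly lower triangular (explicit method)")
            # row-sum simplifying assumption: A e = c^2 / 2
            if sum(self.A_exact[i], F(0)) != self.c_exact[i] ** 2 / 2:
                raise ValueError(f"row {i} of A violates the row-sum condition c_i^2/2")
        b, c = self.b_limit_exact, self.c_exact
        checks = {
            "b.e = 1/2": (sum(b, F(0)), F(1, 2)),
            "b.c = 1/6": (sum(bi * ci for bi, ci in zip(b, c)), F(1, 6)),
            "b.c^2 = 1/12": (sum(bi * ci**2 for bi, ci in zip(b, c)), F(1, 12)),
        }
        for name, (lhs, rhs) in checks.items():
            if lhs != rhs:
                raise ValueError(f"limit weights violate {name}: got {lhs}")

    @property
    def s(self) -> int:
        return len(self.c_exact)

    @cached_property
    def c(self) -> np.ndarray:
        return np.array([float(x) for x in self.c_exact])

    @cached_property
    def A(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.A_exact])

    @cached_property
    def b_limit(self) -> np.ndarray:
        return np.array([float(x) for x in self.b_limit_exact])


@dataclass(frozen=True)
class FittedWeights:
    """Update coefficients of one method at one value of ``nu = omega * h``."""

    nu: float
    eta: float
    beta: float
    b: np.ndarray
    method_id: str  # one of {"a", "b", "c", "prototype"}
    source: str  # "exact_solve" or "series"

    def as_dict(self) -> dict:
        return {
            "method": self.method_id,
            "nu": self.nu,
            "eta": self.eta,
            "beta": self.beta,
            "b": list(map(float, self.b)),
            "source": self.source,
        }


@dataclass(frozen=True)
class CoefficientSeries:
    """Truncated Taylor expansions in nu of one method's update coefficients."""

    method_id: str
    eta: PowerSeries
    beta: PowerSeries
    b: tuple[PowerSeries, PowerSeries, PowerSeries, PowerSeries]


def limit_tableau() -> TDRKTableau:
    """The shared four-stage tableau with prototype weights.

    ``c = (0, 1/4, 2/3, 1)``; each row of ``A`` sums to ``c_i^2/2`` and the
    limit weights satisfy the quadrature conditions of algebraic order six.
    The constructor re-validates those identities in exact arithmetic.
    """
    c = (F(0), F(1, 4), F(2, 3), F(1))
    A = (
        (F(0), F(0), F(0), F(0)),
        (F(1, 32), F(0), F(0), F(0)),
        (F(-2, 81), F(20, 81), F(0), F(0)),
        (F(5, 4), F(-6, 5), F(9, 20), F(0)),
    )
    b = (F(3, 40), F(64, 225), F(27, 200), F(1, 180))
    return TDRKTableau(c, A, b)


# ---------------------------------------------------------------------------
# Tabulated Taylor series of the update coefficients (exact rationals).
# Only even powers of nu occur; the highest tabulated power is the series'
# truncation order.
# ---------------------------------------------------------------------------

_SERIES_TABLE: dict[str, dict[str, dict[int, Fraction]]] = {
    "a": {
        "eta": {0: F(1), 8: F(23, 348364800), 10: F(-2087, 222953472000)},
        "beta": {
            0: F(1),
            6: F(1, 1209600),
            8: F(1637, 20901888000),
            10: F(-3444061, 3973030871040000),
        },
        "b1": {
            0: F(3, 40),
            2: F(1, 11200),
            4: F(-4601, 870912000),
            6: F(-36863647, 165542952960000),
            8: F(248988432157, 86770994223513600000),
        },
        "b2": {
            0: F(64, 225),
            2: F(-1, 5250),
            4: F(5407, 816480000),
            6: F(52884329, 155196518400000),
            8: F(-391939117499, 81347807084544000000),
        },
        "b3": {
            0: F(27, 200),
            2: F(9, 56000),
            4: F(17, 17920000),
            6: F(-9073027, 91968307200000),
            8: F(35868256579, 16068702633984000000),
        },
        "b4": {
            0: F(1, 180),
            2: F(-1, 16800),
            4: F(-427, 186624000),
            6: F(-4822283, 248314429440000),
            8: F(-36912938527, 130156491335270400000),
        },
    },
    "b": {
        "eta": {0: F(1), 8: F(299, 136080000), 10: F(-16561, 108864000000)},
        "beta": {
            0: F(1),
            6: F(1, 189000),
            8: F(12749, 8164800000),
            10: F(9829099, 277136640000000),
        },
        "b1": {
            0: F(3, 40),
            2: F(1, 4000),
            4: F(-159449, 5443200000),
            6: F(-328547263, 117573120000000),
            8: F(-168770118283, 3386105856000000000),
        },
        "b2": {
            0: F(64, 225),
            2: F(-1, 1875),
            4: F(155713, 5103000000),
            6: F(398361581, 110224800000000),
            8: F(1477535874781, 34919216640000000000),
        },
        "b3": {
            0: F(27, 200),
            2: F(9, 20000),
            4: F(2153, 112000000),
            6: F(16429997, 65318400000000),
            8: F(374690334049, 6897623040000000000),
        },
        "b4": {
            0: F(1, 180),
            2: F(-1, 6000),
            4: F(-166921, 8164800000),
            6: F(-188918627, 176359680000000),
            8: F(-2614342153777, 55870746624000000000),
        },
    },
    "c": {
        "eta": {0: F(1), 8: F(23, 1360800), 10: F(-2087, 217728000)},
        "beta": {
            0: F(1),
            6: F(1, 18900),
            8: F(1637, 81648000),
            10: F(-3444061, 3879912960000),
        },
        "b1": {
            0: F(3, 40),
            2: F(1, 2800),
            4: F(-4601, 54432000),
            6: F(-36863647, 2586608640000),
            8: F(248988432157, 338949196185600000),
        },
        "b2": {
            0: F(64, 225),
            2: F(-2, 2625),
            4: F(5407, 51030000),
            6: F(52884329, 2424945600000),
            8: F(-391939117499, 317764871424000000),
        },
        "b3": {
            0: F(27, 200),
            2: F(9, 14000),
            4: F(17, 1120000),
            6: F(-9073027, 1437004800000),
            8: F(35868256579, 62768369664000000),
        },
        "b4": {
            0: F(1, 180),
            2: F(-1, 4200),
            4: F(-427, 11664000),
            6: F(-4822283, 3879912960000),
            8: F(-36912938527, 508423794278400000),
        },
    },
}


def coefficient_series(method_id: str) -> CoefficientSeries:
    """The tabulated truncated Taylor series of one method's coefficients."""
    if method_id not in _SERIES_TABLE:
        raise ValueError(f"unknown method {method_id!r}; expected one of a, b, c")
    tab = _SERIES_TABLE[method_id]

    def mk(name: str) -> PowerSeries:
        coeffs = tab[name]
        return PowerSeries(coeffs, truncation_order=max(coeffs))

    return CoefficientSeries(
        method_id=method_id,
        eta=mk("eta"),
        beta=mk("beta"),
        b=(mk("b1"), mk("b2"), mk("b3"), mk("b4")),
    )


def weights_series(method_id: str, nu: float) -> FittedWeights:
    """Evaluate the truncated Taylor series of a method's weights at ``nu``.

    The series are even in ``nu``, so the result is invariant under
    ``nu -> -nu``.  Beyond the documented validity radius a warning is issued
    but the value is still returned (the truncation error is the caller's
    problem there).
    """
    cs = coefficient_series(method_id)
    if abs(nu) > SERIES_VALIDITY_RADIUS:
        warnings.warn(
            f"|nu|={abs(nu):.3g} exceeds the series validity radius "
            f"{SERIES_VALIDITY_RADIUS}; truncation error may be significant",
            stacklevel=2,
        )
    return FittedWeights(
        nu=nu,
        eta=cs.eta.evaluate(nu),
        beta=cs.beta.evaluate(nu),
        b=np.array([s.evaluate(nu) for s in cs.b]),
        method_id=method_id,
        source="series",
    )


# condition-number cutoff above which the exact fitting solve is distrusted
_COND_CUTOFF = 1e12


def _fitting_matrix_a(nu, c: np.ndarray, dtype=float):
    """Linear system (rows x unknowns (eta, beta, b1..b4)) for method "a".

    Rows 1-4 require the one-step defect operator to annihilate
    ``exp(+-i w t)`` and ``t exp(+-i w t)``; rows 5-6 are the algebraic
    quadrature conditions ``b.e = 1/2`` and ``b.c = 1/6``.
    """
    nu = dtype(nu)
    c = c.astype(dtype)
    s2, s3, s4 = np.sin(c[1:] * nu)
    k2, k3, k4 = np.cos(c[1:] * nu)
    c2, c3, c4 = c[1:]
    M = np.array(
        [
            [0.0, -1.0 / nu, 0.0, s2, s3, s4],
            [-1.0 / nu**2, 0.0, 1.0, k2, k3, k4],
            [
                0.0,
                -1.0,
                0.0,
                nu**2 * c2 * k2 + 2 * nu * s2,
                nu**2 * c3 * k3 + 2 * nu * s3,
                nu**2 * c4 * k4 + 2 * nu * s4,
            ],
            [
                0.0,
                0.0,
                2 * nu,
                2 * nu * k2 - nu**2 * c2 * s2,
                2 * nu * k3 - nu**2 * c3 * s3,
                2 * nu * k4 - nu**2 * c4 * s4,
            ],
            [0.0, 0.0, 1.0, 1.0, 1.0, 1.0],
            [0.0, 0.0, 0.0, c2, c3, c4],
        ]
    )
    rhs = np.array(
        [
            -np.sin(nu) / nu**2,
            -np.cos(nu) / nu**2,
            -np.cos(nu),
            np.sin(nu),
            dtype(0.5),
            dtype(1) / dtype(6),
        ]
    )
    return M.astype(dtype), rhs.astype(dtype)


def _lu_solve(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    # partial-pivoting Gaussian elimination; used for extended-precision
    # dtypes that LAPACK does not accept (the system is only 6x6)
    n = len(rhs)
    M = M.copy()
    x = rhs.copy()
    for k in range(n):
        p = k + int(np.argmax(np.abs(M[k:, k])))
        if M[p, k] == 0:
            raise np.linalg.LinAlgError("singular fitting matrix")
        if p != k:
            M[[k, p]] = M[[p, k]]
            x[[k, p]] = x[[p, k]]
        for i in range(k + 1, n):
            m = M[i, k] / M[k, k]
            M[i, k:] -= m * M[k, k:]
            x[i] -= m * x[k]
    for k in range(n - 1, -1, -1):
        x[k] = (x[k] - M[k, k + 1 :] @ x[k + 1 :]) / M[k, k]
    return x


def weights_a(nu: float) -> FittedWeights:
    """Weights of method "a" at ``nu``: exact trigonometric solve when safe.

    For ``|nu| >= SERIES_SWITCH`` the 6x6 fitting system is solved directly
    and the residual of all six equations at the solution is below 1e-12.
    For smaller ``|nu|`` (including 0) the Taylor series is evaluated instead.
    A near-singular fitting matrix also falls back to the series, flagged via
    ``source``.
    """
    if not np.isfinite(nu):
        raise ValueError("nu must be finite")
    if abs(nu) < SERIES_SWITCH:
        return weights_series("a", nu)
    tab = limit_tableau()
    if np.linalg.cond(_fitting_matrix_a(nu, tab.c)[0]) > _COND_CUTOFF:
        warnings.warn(
            f"fitting system near-singular at nu={nu:.6g}; using series", stacklevel=2
        )
        return weights_series("a", nu)
    # extended precision absorbs the (eta - cos nu)/nu^2-type cancellation
    # that erodes the double-precision solve for moderate |nu|
    M, rhs = _fitting_matrix_a(nu, tab.c, dtype=np.longdouble)
    x = _lu_solve(M, rhs).astype(float)
    return FittedWeights(
        nu=nu,
        eta=float(x[0]),
        beta=float(x[1]),
        b=x[2:].copy(),
        method_id="a",
        source="exact_solve",
    )


def fitted_weights(method_id: str, nu: float) -> FittedWeights:
    """Dispatch: prototype weights, exact solve (method a) or series (b, c)."""
    if method_id == "prototype" or nu == 0.0:
        tab = limit_tableau()
        return FittedWeights(
            nu=0.0,
            eta=1.0,
            beta=1.0,
            b=tab.b_limit,
            method_id=method_id,
            source="series",
        )
    if method_id == "a":
        return weights_a(nu)
    if method_id in ("b", "c"):
        return weights_series(method_id, nu)
    raise ValueError(f"unknown method {method_id!r}")
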