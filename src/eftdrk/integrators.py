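"""Fixed-step time stepping for two-derivative Runge-Kutta methods.

A TDRK step advances ``y' = f(y)`` using one evaluation of ``f`` and one
evaluation per stage of the second-derivative field ``g = f' f``:

    Y_i   = y_n + c_i h f(y_n) + h^2 sum_j a_ij g(Y_j)
    y_n+1 = eta(nu) y_n + h beta(nu) f(y_n) + h^2 sum_i b_i(nu) g(Y_i)

With the four-stage tableau used throughout this package each step costs
exactly 1 f-evaluation and 4 g-evaluations (Y_1 = y_n since c_1 = 0, and
g(Y_1) is evaluated once).  The fitting parameter ``nu = omega h`` is fixed
for a whole run: the weights are computed once, not per step.

A classical seven-stage sixth-order explicit Runge-Kutta scheme (Butcher's
1964 method) is included as a same-order single-derivative baseline; it costs
7 f-evaluations per step.  Function-evaluation counts are recorded exactly on
every trajectory so that accuracy can be compared at equal computational
effort.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .models import ODESystem
from .tableaux import FittedWeights, TDRKTableau, fitted_weights, limit_tableau

__all__ = [
    "Trajectory",
    "StepFailure",
    "tdrk_step",
    "rk6_step",
    "rk6_baseline_tableau",
    "integrate_fixed",
    "METHOD_IDS",
    "write_trajectory",
]

F = Fraction

#: method ids accepted by :func:`integrate_fixed`
METHOD_IDS = ("prototype", "efa", "efb", "efc", "rk6")

# integrate_fixed method id -> weights method id
_WEIGHTS_FOR = {"prototype": "prototype", "efa": "a", "efb": "b", "efc": "c"}


class StepFailure(RuntimeError):
    """A stage or update produced a non-finite state."""

    def __init__(self, message: str, stage: int | None = None, time: float | None = None):
        super().__init__(message)
        self.stage = stage
        self.time = time


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid solution with exact function-evaluation accounting."""

    times: np.ndarray
    states: np.ndarray  # shape (n_steps + 1, dim)
    method_id: str
    h: float
    omega: float
    n_f: int
    n_g: int


def tdrk_step(
    system: ODESystem,
    y: np.ndarray,
    h: float,
    tableau: TDRKTableau,
    weights: FittedWeights,
) -> np.ndarray:
    """One explicit TDRK step; raises :class:`StepFailure` naming the first
    non-finite stage."""
    c = tableau.c
    A = tableau.A
    f0 = system.f(y)
    gs = []
    for i in range(tableau.s):
        Yi = y + c[i] * h * f0
        for j in range(i):
            if A[i, j] != 0.0:
                Yi = Yi + (h * h * A[i, j]) * gs[j]
        if not np.all(np.isfinite(Yi)):
            raise StepFailure(f"non-finite stage {i + 1}", stage=i + 1)
        gs.append(system.g(Yi))
    y_new = weights.eta * y + (h * weights.beta) * f0
    for bi, gi in zip(weights.b, gs):
        y_new = y_new + (h * h * bi) * gi
    if not np.all(np.isfinite(y_new)):
        raise StepFailure("non-finite update", stage=tableau.s + 1)
    return y_new


def rk6_baseline_tableau() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Butcher's seven-stage explicit Runge-Kutta method of order six (1964).

    Returned as ``(c, A, b)`` float arrays.  This is a standard literature
    tableau used purely as a same-order single-derivative baseline; it is not
    part of the fitted family and no headline result depends on it.
    """
    c = np.array([0, F(1, 3), F(2, 3), F(1, 3), F(1, 2), F(1, 2), F(1)], dtype=float)
    A = np.zeros((7, 7))
    rows = [
        [],
        [F(1, 3)],
        [0, F(2, 3)],
        [F(1, 12), F(1, 3), F(-1, 12)],
        [F(-1, 16), F(9, 8), F(-3, 16), F(-3, 8)],
        [0, F(9, 8), F(-3, 8), F(-3, 4), F(1, 2)],
        [F(9, 44), F(-9, 11), F(63, 44), F(18, 11), 0, F(-16, 11)],
    ]
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            A[i, j] = float(v)
    b = np.array(
        [F(11, 120), 0, F(27, 40), F(27, 40), F(-4, 15), F(-4, 15), F(11, 120)],
        dtype=float,
    )
    return c, A, b


def rk6_step(system: ODESystem, y: np.ndarray, h: float) -> np.ndarray:
    """One step of the order-six RK baseline (7 f-evaluations)."""
    c, A, b = _RK6
    ks = []
    for i in range(7):
        Yi = y
        for j in range(i):
            if A[i, j] != 0.0:
                Yi = Yi + (h * A[i, j]) * ks[j]
        ks.append(system.f(Yi))
    y_new = y
    for bi, ki in zip(b, ks):
        if bi != 0.0:
            y_new = y_new + (h * bi) * ki
    if not np.all(np.isfinite(y_new)):
        raise StepFailure("non-finite update")
    return y_new


_RK6 = rk6_baseline_tableau()


def _n_steps(t0: float, t_end: float, h: float) -> int:
    span = t_end - t0
    n = round(span / h)
    if abs(n * h - span) > 1e-9 * h:
        raise ValueError(
            f"(t_end - t0) = {span} is not an integer multiple of h = {h}"
        )
    return n


def integrate_fixed(
    system: ODESystem,
    y0: np.ndarray,
    t0: float,
    t_end: float,
    h: float,
    method: str = "prototype",
    omega: float = 0.0,
) -> Trajectory:
    """Integrate on a uniform grid with a fixed fitting frequency.

    ``omega`` is ignored for the prototype and the RK baseline.  ``nu`` is
    computed once (``omega * h``) and the fitted weights are solved once for
    the whole run.  The interval must be an integer number of steps.
    """
    if method not in METHOD_IDS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_IDS}")
    if h <= 0:
        raise ValueError("h must be positive")
    if t_end < t0:
        raise ValueError("t_end must be >= t0")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    y0 = np.asarray(y0, dtype=float)
    n = _n_steps(t0, t_end, h)
    times = t0 + h * np.arange(n + 1)
    states = np.empty((n + 1, system.dim))
    states[0] = y0
    if n == 0:
        return Trajectory(times, states, method, h, omega, 0, 0)

    y = y0
    if method == "rk6":
        for k in range(n):
            try:
                y = rk6_step(system, y, h)
            except StepFailure as err:
                raise StepFailure(str(err), time=float(times[k])) from None
            states[k + 1] = y
        return Trajectory(times, states, method, h, omega, n_f=7 * n, n_g=0)

    tableau = limit_tableau()
    weights = fitted_weights(_WEIGHTS_FOR[method], 0.0 if method == "prototype" else omega * h)

    # the four-stage structure is unrolled with the tableau entries bound as
    # plain floats: this loop is the package's hot path (reference
    # trajectories run to ~10^6 steps)
    f, g = system.f, system.g
    h2 = h * h
    c2h, c3h, c4h = (float(ci) * h for ci in tableau.c_exact[1:])
    (a21,), (a31, a32), (a41, a42, a43) = (
        [h2 * float(a) for a in row[:i]] for i, row in enumerate(tableau.A_exact[1:], 1)
    )
    eta, hbeta = float(weights.eta), h * float(weights.beta)
    b1, b2, b3, b4 = (h2 * float(bi) for bi in weights.b)
    for k in range(n):
        f0 = f(y)
        g1 = g(y)
        g2 = g(y + c2h * f0 + a21 * g1)
        g3 = g(y + c3h * f0 + a31 * g1 + a32 * g2)
        g4 = g(y + c4h * f0 + a41 * g1 + a42 * g2 + a43 * g3)
        y = eta * y + hbeta * f0 + b1 * g1 + b2 * g2 + b3 * g3 + b4 * g4
        if not np.isfinite(y.sum()):
            # re-run the failed step through the checked stepper to name
            # the offending stage
            try:
                tdrk_step(system, states[k], h, tableau, weights)
            except StepFailure as err:
                raise StepFailure(str(err), stage=err.stage, time=float(times[k])) from None
            raise StepFailure("non-finite update", time=float(times[k]))
        states[k + 1] = y
    return Trajectory(times, states, method, h, omega, n_f=n, n_g=4 * n)


def write_trajectory(traj: Trajectory, system: ODESystem, csv_path) -> None:
    """CSV with header ``time,<state names>`` plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    csv_path = Path(csv_path)
    names = system.state_names or tuple(f"y{i+1}" for i in range(system.dim))
    df = pd.DataFrame(traj.states, columns=list(names))
    df.insert(0, "time", traj.times)
    df.to_csv(csv_path, index=False)
    sidecar = {
        "model": system.name,
        "method": traj.method_id,
        "h": traj.h,
        "omega": traj.omega,
        "n_f": traj.n_f,
        "n_g": traj.n_g,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
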