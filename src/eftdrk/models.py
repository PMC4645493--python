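"""Benchmark oscillatory gene-regulatory ODE models.

Two classic limit-cycle systems are provided, each exposing the vector field
``f``, its analytic Jacobian ``J = f'`` and the second-derivative field
``g(y) = J(y) f(y)`` needed by two-derivative Runge-Kutta integrators:

* **Two-gene cross-regulation** (dimension 4, state ``(m1, m2, p1, p2)``):
  gene 1's transcription is activated by protein 2 through a Hill function,
  gene 2's is inhibited by protein 1; mRNAs are translated to proteins and
  both species degrade linearly.  With the default parameters the unique
  positive steady state is unstable with a complex eigenvalue pair of
  positive real part, and trajectories settle onto a limit cycle.

* **Goldbeter PER circadian oscillator** (dimension 5, state
  ``(M, P0, P1, P2, PN)``): cytosolic *per* mRNA ``M`` drives synthesis of
  PER protein, which is reversibly phosphorylated (``P0 -> P1 -> P2``,
  Michaelis-Menten kinetics), degraded, and shuttled into the nucleus as
  ``PN``, where it represses transcription of its own mRNA through a Hill
  term.  Units are uM for concentrations and hours for time; the default
  parameters give sustained circadian oscillations with a period near 23.7 h.

``g`` is always computed as ``J(y) @ f(y)`` from the analytic Jacobian; the
closed forms of ``g`` serve only as cross-checks in the test suite.
A general builder for N-gene transcription/translation networks with
user-supplied regulation functions is also included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ODESystem",
    "TwoGeneParams",
    "PERParams",
    "NGeneSpec",
    "hill",
    "two_gene_system",
    "per_circadian_system",
    "n_gene_system",
    "get_model",
    "MODEL_REGISTRY",
]


@dataclass(frozen=True)
class ODESystem:
    """An autonomous ODE ``y' = f(y)`` with analytic Jacobian and ``g = J f``."""

    dim: int
    f: Callable[[np.ndarray], np.ndarray]
    jac: Callable[[np.ndarray], np.ndarray]
    g: Callable[[np.ndarray], np.ndarray]
    name: str = ""
    state_names: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)


def hill(kind: str, p: float, theta: float, n: float) -> float:
    """Sigmoidal regulation: ``p^n/(p^n + theta^n)`` (activation) or its
    complement ``theta^n/(p^n + theta^n)`` (inhibition).

    At ``p = 0`` activation returns 0 and inhibition 1 (the ``p -> 0+``
    limits), avoiding the indeterminate ``0^n/0`` form.
    """
    if p < 0:
        raise ValueError("concentration must be nonnegative")
    if theta <= 0 or n <= 0:
        raise ValueError("threshold and Hill coefficient must be positive")
    if p == 0.0:
        act = 0.0
    else:
        pn = p**n
        act = pn / (pn + theta**n)
    if kind == "activation":
        return act
    if kind == "inhibition":
        return 1.0 - act
    raise ValueError(f"unknown kind {kind!r}")


def _check_positive(obj, names: Sequence[str]):
    for name in names:
        if getattr(obj, name) <= 0:
            raise ValueError(f"parameter {name} must be strictly positive")


@dataclass(frozen=True)
class TwoGeneParams:
    """Parameters of the two-gene cross-regulation model (all > 0).

    Defaults are the standard oscillatory operating point: Hill coefficients
    3, asymmetric maximal transcription rates, unit degradation/translation
    rates and a shared threshold of 0.21.
    """

    n1: float = 3.0
    n2: float = 3.0
    lambda1: float = 1.15
    lambda2: float = 2.35
    gamma1: float = 1.0
    gamma2: float = 1.0
    kappa1: float = 1.0
    kappa2: float = 1.0
    mu1: float = 1.0
    mu2: float = 1.0
    theta1: float = 0.21
    theta2: float = 0.21

    def __post_init__(self):
        _check_positive(self, [f.name for f in self.__dataclass_fields__.values()])


def two_gene_system(params: TwoGeneParams | None = None) -> ODESystem:
    """Two-gene system: activation of gene 1 by P2, inhibition of gene 2 by P1."""
    p = params or TwoGeneParams()
    n1, n2 = p.n1, p.n2
    th1n = p.theta1**n1
    th2n = p.theta2**n2
    l1, l2 = p.lambda1, p.lambda2
    g1, g2 = p.gamma1, p.gamma2
    k1, k2 = p.kappa1, p.kappa2
    m1d, m2d = p.mu1, p.mu2

    # f and g are hand-inlined in scalar arithmetic: they sit in the
    # integrator's innermost loop (millions of calls for reference
    # trajectories), where building 4x4 ndarrays dominates the cost

    def f(y: np.ndarray) -> np.ndarray:
        m1, m2, p1, p2 = y.tolist() if isinstance(y, np.ndarray) else y
        p1n = p1**n1
        p2n = p2**n2
        return np.array(
            [
                l1 * p2n / (p2n + th2n) - g1 * m1,
                l2 * th1n / (p1n + th1n) - g2 * m2,
                k1 * m1 - m1d * p1,
                k2 * m2 - m2d * p2,
            ]
        )

    def jac(y: np.ndarray) -> np.ndarray:
        _, _, p1, p2 = y
        dH_act = l1 * n2 * th2n * p2 ** (n2 - 1) / (th2n + p2**n2) ** 2
        dH_inh = -l2 * n1 * th1n * p1 ** (n1 - 1) / (th1n + p1**n1) ** 2
        return np.array(
            [
                [-g1, 0.0, 0.0, dH_act],
                [0.0, -g2, dH_inh, 0.0],
                [k1, 0.0, -m1d, 0.0],
                [0.0, k2, 0.0, -m2d],
            ]
        )

    def g(y: np.ndarray) -> np.ndarray:
        # J(y) @ f(y), expanded over the Jacobian's sparsity pattern
        m1, m2, p1, p2 = y.tolist() if isinstance(y, np.ndarray) else y
        p1n = p1**n1
        p2n = p2**n2
        d1 = p1n + th1n
        d2 = p2n + th2n
        f0 = l1 * p2n / d2 - g1 * m1
        f1 = l2 * th1n / d1 - g2 * m2
        f2 = k1 * m1 - m1d * p1
        f3 = k2 * m2 - m2d * p2
        dH_act = l1 * n2 * th2n * p2 ** (n2 - 1) / (d2 * d2)
        dH_inh = -l2 * n1 * th1n * p1 ** (n1 - 1) / (d1 * d1)
        return np.array(
            [
                -g1 * f0 + dH_act * f3,
                -g2 * f1 + dH_inh * f2,
                k1 * f0 - m1d * f2,
                k2 * f1 - m2d * f3,
            ]
        )

    return ODESystem(
        dim=4,
        f=f,
        jac=jac,
        g=g,
        name="two_gene",
        state_names=("m1", "m2", "p1", "p2"),
        params={k: getattr(p, k) for k in p.__dataclass_fields__},
    )


@dataclass(frozen=True)
class PERParams:
    """Parameters of the five-variable PER circadian model.

    Rates ``vs, vm, vd, V1..V4`` in uM/h; first-order constants ``ks, k1, k2``
    in 1/h; Michaelis/threshold constants ``KI, Kd, Km1, K1..K4`` in uM;
    Hill coefficient ``n`` dimensionless.  Defaults are the standard
    circadian-oscillation parameter set.
    """

    vs: float = 0.76
    vm: float = 0.65
    ks: float = 0.38
    vd: float = 0.95
    k1: float = 1.9
    k2: float = 1.3
    KI: float = 1.0
    Kd: float = 0.2
    Km1: float = 0.5
    K1: float = 2.0
    K2: float = 2.0
    K3: float = 2.0
    K4: float = 2.0
    n: float = 4.0
    V1: float = 3.2
    V2: float = 1.58
    V3: float = 5.0
    V4: float = 2.5

    def __post_init__(self):
        _check_positive(self, [f.name for f in self.__dataclass_fields__.values()])


def per_circadian_system(params: PERParams | None = None) -> ODESystem:
    """Goldbeter's five-variable model of PER protein circadian oscillation."""
    q = params or PERParams()
    KIn = q.KI**q.n
    n = q.n

    vs, vm, ks, vd, k1, k2 = q.vs, q.vm, q.ks, q.vd, q.k1, q.k2
    Kd, Km1, K1, K2, K3, K4 = q.Kd, q.Km1, q.K1, q.K2, q.K3, q.K4
    V1, V2, V3, V4 = q.V1, q.V2, q.V3, q.V4

    def f(y: np.ndarray) -> np.ndarray:
        M, P0, P1, P2, PN = y.tolist() if isinstance(y, np.ndarray) else y
        PNn = PN**n
        v_transcribe = vs * KIn / (KIn + PNn)
        v_mrna_deg = vm * M / (Km1 + M)
        V1P0 = V1 * P0 / (K1 + P0)
        V2P1 = V2 * P1 / (K2 + P1)
        V3P1 = V3 * P1 / (K3 + P1)
        V4P2 = V4 * P2 / (K4 + P2)
        v_deg = vd * P2 / (Kd + P2)
        return np.array(
            [
                v_transcribe - v_mrna_deg,
                ks * M - V1P0 + V2P1,
                V1P0 - V2P1 - V3P1 + V4P2,
                V3P1 - V4P2 - k1 * P2 + k2 * PN - v_deg,
                k1 * P2 - k2 * PN,
            ]
        )

    def jac(y: np.ndarray) -> np.ndarray:
        M, P0, P1, P2, PN = y
        # Michaelis-Menten terms differentiate to K V / (K + x)^2
        dV1 = q.V1 * q.K1 / (q.K1 + P0) ** 2
        dV2 = q.V2 * q.K2 / (q.K2 + P1) ** 2
        dV3 = q.V3 * q.K3 / (q.K3 + P1) ** 2
        dV4 = q.V4 * q.K4 / (q.K4 + P2) ** 2
        dvd = q.vd * q.Kd / (q.Kd + P2) ** 2
        dvm = q.vm * q.Km1 / (q.Km1 + M) ** 2
        dhill = -q.vs * KIn * n * PN ** (n - 1) / (KIn + PN**n) ** 2
        return np.array(
            [
                [-dvm, 0.0, 0.0, 0.0, dhill],
                [q.ks, -dV1, dV2, 0.0, 0.0],
                [0.0, dV1, -dV2 - dV3, dV4, 0.0],
                [0.0, 0.0, dV3, -dV4 - q.k1 - dvd, q.k2],
                [0.0, 0.0, 0.0, q.k1, -q.k2],
            ]
        )

    def g(y: np.ndarray) -> np.ndarray:
        # J(y) @ f(y), expanded over the Jacobian's sparsity pattern
        M, P0, P1, P2, PN = y.tolist() if isinstance(y, np.ndarray) else y
        PNn = PN**n
        dKI = KIn + PNn
        dM = Km1 + M
        d0 = K1 + P0
        d1 = K2 + P1
        d1b = K3 + P1
        d2 = K4 + P2
        d2b = Kd + P2
        V1P0 = V1 * P0 / d0
        V2P1 = V2 * P1 / d1
        V3P1 = V3 * P1 / d1b
        V4P2 = V4 * P2 / d2
        f0 = vs * KIn / dKI - vm * M / dM
        f1 = ks * M - V1P0 + V2P1
        f2 = V1P0 - V2P1 - V3P1 + V4P2
        f3 = V3P1 - V4P2 - k1 * P2 + k2 * PN - vd * P2 / d2b
        f4 = k1 * P2 - k2 * PN
        dV1 = V1 * K1 / (d0 * d0)
        dV2 = V2 * K2 / (d1 * d1)
        dV3 = V3 * K3 / (d1b * d1b)
        dV4 = V4 * K4 / (d2 * d2)
        dvd = vd * Kd / (d2b * d2b)
        dvm = vm * Km1 / (dM * dM)
        dhill = -vs * KIn * n * PN ** (n - 1) / (dKI * dKI)
        return np.array(
            [
                -dvm * f0 + dhill * f4,
                ks * f0 - dV1 * f1 + dV2 * f2,
                dV1 * f1 + (-dV2 - dV3) * f2 + dV4 * f3,
                dV3 * f2 + (-dV4 - k1 - dvd) * f3 + k2 * f4,
                k1 * f3 - k2 * f4,
            ]
        )

    return ODESystem(
        dim=5,
        f=f,
        jac=jac,
        g=g,
        name="per",
        state_names=("M", "P0", "P1", "P2", "PN"),
        params={k: getattr(q, k) for k in q.__dataclass_fields__},
    )


@dataclass(frozen=True)
class NGeneSpec:
    """General N-gene transcription/translation network.

    ``regulation(p)`` maps the length-N protein vector to the N transcription
    rates; ``regulation_jac(p)`` returns the N x N matrix of its partial
    derivatives.  ``gamma``/``mu`` are mRNA/protein degradation rates and
    ``kappa`` the translation rates.  State ordering is
    ``(m_1..m_N, p_1..p_N)``.
    """

    N: int
    regulation: Callable[[np.ndarray], np.ndarray]
    regulation_jac: Callable[[np.ndarray], np.ndarray]
    kappa: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray
    name: str = "n_gene"


def n_gene_system(spec: NGeneSpec) -> ODESystem:
    N = spec.N
    kappa = np.asarray(spec.kappa, dtype=float)
    gamma = np.asarray(spec.gamma, dtype=float)
    mu = np.asarray(spec.mu, dtype=float)
    if not (len(kappa) == len(gamma) == len(mu) == N):
        raise ValueError("kappa, gamma, mu must all have length N")

    def f(y: np.ndarray) -> np.ndarray:
        m, p = y[:N], y[N:]
        R = np.asarray(spec.regulation(p), dtype=float)
        if R.shape != (N,):
            raise ValueError("regulation(p) must return a length-N vector")
        return np.concatenate([R - gamma * m, kappa * m - mu * p])

    def jac(y: np.ndarray) -> np.ndarray:
        p = y[N:]
        dR = np.asarray(spec.regulation_jac(p), dtype=float)
        if dR.shape != (N, N):
            raise ValueError("regulation_jac(p) must return an N x N matrix")
        J = np.zeros((2 * N, 2 * N))
        J[:N, :N] = -np.diag(gamma)
        J[:N, N:] = dR
        J[N:, :N] = np.diag(kappa)
        J[N:, N:] = -np.diag(mu)
        return J

    def g(y: np.ndarray) -> np.ndarray:
        return jac(y) @ f(y)

    names = tuple(f"m{i+1}" for i in range(N)) + tuple(f"p{i+1}" for i in range(N))
    return ODESystem(dim=2 * N, f=f, jac=jac, g=g, name=spec.name, state_names=names)


MODEL_REGISTRY: dict[str, Callable[..., ODESystem]] = {
    "two_gene": lambda **kw: two_gene_system(TwoGeneParams(**kw)),
    "per": lambda **kw: per_circadian_system(PERParams(**kw)),
}


def get_model(name: str, **param_overrides) -> ODESystem:
    """Build a registered model by name with optional parameter overrides."""
    if name not in MODEL_REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        )
    return MODEL_REGISTRY[name](**param_overrides)
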