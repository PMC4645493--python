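"""Vector fields, analytic Jacobians and g = J f for the benchmark models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eftdrk import (
    NGeneSpec,
    PERParams,
    TwoGeneParams,
    find_steady_state,
    get_model,
    hill,
    n_gene_system,
    per_circadian_system,
    two_gene_system,
)

# steady states as published for the default parameter sets (6 decimals)
TWO_GENE_STAR = np.array([0.475099, 0.186810, 0.475099, 0.186810])
PER_STAR = np.array([1.851476, 1.049558, 0.672924, 0.570982, 0.834512])


class TestHill:
    def test_half_maximal_at_threshold(self):
        assert hill("activation", 0.21, 0.21, 3) == pytest.approx(0.5)
        assert hill("inhibition", 0.21, 0.21, 3) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(0, 50),
        theta=st.floats(0.01, 10),
        n=st.floats(0.5, 8),
    )
    def test_activation_and_inhibition_are_complementary(self, p, theta, n):
        total = hill("activation", p, theta, n) + hill("inhibition", p, theta, n)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_inhibition_monotone_decreasing_with_zero_limit(self):
        vals = [hill("inhibition", p, 0.21, 3) for p in (0.0, 0.1, 1.0, 10.0, 1e6)]
        assert vals[0] == 1.0
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-16

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill("activation", -0.1, 0.21, 3)


class TestTwoGene:
    def test_vector_field_vanishes_at_published_steady_state(self, two_gene):
        assert np.max(np.abs(two_gene.f(TWO_GENE_STAR))) < 5e-6

    def test_jacobian_eigenvalues_match_published_linearization(self, two_gene):
        ss = find_steady_state(two_gene, np.full(4, 0.5))
        eigs = np.sort_complex(ss.eigenvalues)
        expected = np.sort_complex(
            np.array(
                [
                    -2.049997 - 1.049997j,
                    -2.049997 + 1.049997j,
                    0.049997 - 1.049997j,
                    0.049997 + 1.049997j,
                ]
            )
        )
        assert np.max(np.abs(eigs.real - expected.real)) < 5e-7
        assert np.max(np.abs(eigs.imag - expected.imag)) < 5e-7

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TwoGeneParams(theta1=0.0)


class TestPER:
    def test_vector_field_vanishes_at_published_steady_state(self, per):
        assert np.max(np.abs(per.f(PER_STAR))) < 5e-6

    def test_jacobian_eigenvalues_match_published_linearization(self, per):
        ss = find_steady_state(per, np.ones(5))
        real = np.sort(ss.eigenvalues[np.abs(ss.eigenvalues.imag) < 1e-12].real)
        assert real == pytest.approx([-4.266573, -1.834793, -0.829294], abs=5e-7)
        pair = ss.eigenvalues[ss.eigenvalues.imag > 1e-12]
        assert pair.real == pytest.approx(0.032824, abs=5e-7)
        assert pair.imag == pytest.approx(0.297276, abs=5e-7)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PERParams(n=-1)


@pytest.mark.parametrize("builder", [two_gene_system, per_circadian_system])
class TestDerivativeOracles:
    """The analytic J and the hand-inlined g against finite differences."""

    def test_jacobian_matches_central_differences(self, builder):
        system = builder()
        rng = np.random.default_rng(42)
        eps = 1e-6
        eye = np.eye(system.dim)
        for y in rng.uniform(0.05, 2.0, size=(50, system.dim)):
            J_fd = np.column_stack(
                [(system.f(y + eps * e) - system.f(y - eps * e)) / (2 * eps) for e in eye]
            )
            assert np.max(np.abs(system.jac(y) - J_fd)) < 1e-7

    def test_g_matches_directional_difference_of_f_along_f(self, builder):
        system = builder()
        rng = np.random.default_rng(43)
        eps = 1e-6
        for y in rng.uniform(0.05, 2.0, size=(50, system.dim)):
            fy = system.f(y)
            g_fd = (system.f(y + eps * fy) - system.f(y - eps * fy)) / (2 * eps)
            assert np.max(np.abs(system.g(y) - g_fd)) < 1e-7

    def test_g_equals_jacobian_times_f(self, builder):
        system = builder()
        rng = np.random.default_rng(44)
        for y in rng.uniform(0.05, 2.0, size=(50, system.dim)):
            assert np.max(np.abs(system.g(y) - system.jac(y) @ system.f(y))) < 1e-13


class TestNGeneBuilder:
    @staticmethod
    def _two_gene_as_spec(p: TwoGeneParams) -> NGeneSpec:
        th1n, th2n = p.theta1**p.n1, p.theta2**p.n2

        def regulation(prot):
            p1, p2 = prot
            return np.array(
                [
                    p.lambda1 * p2**p.n2 / (p2**p.n2 + th2n),
                    p.lambda2 * th1n / (p1**p.n1 + th1n),
                ]
            )

        def regulation_jac(prot):
            p1, p2 = prot
            d12 = p.lambda1 * p.n2 * th2n * p2 ** (p.n2 - 1) / (th2n + p2**p.n2) ** 2
            d21 = -p.lambda2 * p.n1 * th1n * p1 ** (p.n1 - 1) / (th1n + p1**p.n1) ** 2
            return np.array([[0.0, d12], [d21, 0.0]])

        return NGeneSpec(
            N=2,
            regulation=regulation,
            regulation_jac=regulation_jac,
            kappa=[p.kappa1, p.kappa2],
            gamma=[p.gamma1, p.gamma2],
            mu=[p.mu1, p.mu2],
        )

    def test_two_gene_model_is_an_instance_of_the_general_builder(self, two_gene):
        params = TwoGeneParams()
        general = n_gene_system(self._two_gene_as_spec(params))
        rng = np.random.default_rng(7)
        for y in rng.uniform(0.05, 2.0, size=(20, 4)):
            assert np.max(np.abs(general.f(y) - two_gene.f(y))) < 1e-14
            assert np.max(np.abs(general.jac(y) - two_gene.jac(y))) < 1e-14

    def test_single_gene_constant_regulation_steady_state(self):
        # m' = r - m, p' = m - p  ==>  y* = (r, r)
        r = 0.8
        spec = NGeneSpec(
            N=1,
            regulation=lambda p: np.array([r]),
            regulation_jac=lambda p: np.zeros((1, 1)),
            kappa=[1.0],
            gamma=[1.0],
            mu=[1.0],
        )
        system = n_gene_system(spec)
        assert system.dim == 2
        ss = find_steady_state(system, np.array([0.3, 0.3]))
        assert ss.y_star == pytest.approx([r, r], abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            n_gene_system(
                NGeneSpec(
                    N=2,
                    regulation=lambda p: np.zeros(2),
                    regulation_jac=lambda p: np.zeros((2, 2)),
                    kappa=[1.0],
                    gamma=[1.0, 1.0],
                    mu=[1.0, 1.0],
                )
            )


def test_registry_builds_models_with_overrides():
    m = get_model("two_gene", lambda1=2.0)
    assert m.params["lambda1"] == 2.0
    with pytest.raises(KeyError):
        get_model("three_gene")
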