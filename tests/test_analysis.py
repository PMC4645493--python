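"""Steady states, frequencies, global errors and the fitting-frequency sweep."""

import numpy as np
import pytest

from eftdrk import (
    ODESystem,
    best_fitting_frequency,
    convergence_order,
    efficiency_table,
    find_steady_state,
    global_error,
    integrate_fixed,
    limit_cycle_frequency,
    reference_trajectory,
)
from eftdrk.analysis import default_h_ref
from tests.conftest import PER_Y0, TWO_GENE_Y0


class TestFindSteadyState:
    def test_linear_problem_converges_in_one_step(self):
        c = 1.7
        system = ODESystem(
            dim=1,
            f=lambda y: -y + c,
            jac=lambda y: np.array([[-1.0]]),
            g=lambda y: y - c,
            name="relax",
        )
        ss = find_steady_state(system, np.array([0.1]))
        assert ss.y_star[0] == pytest.approx(c, abs=1e-14)
        assert ss.n_iterations == 1

    def test_two_gene_root_is_unique_across_seeded_starts(self, two_gene):
        rng = np.random.default_rng(11)
        roots = [
            find_steady_state(two_gene, guess).y_star
            for guess in rng.uniform(0.05, 2.0, size=(10, 4))
        ]
        spread = np.max(np.abs(np.array(roots) - roots[0]))
        assert spread < 1e-10

    def test_reports_oscillatory_character(self, two_gene, per):
        ss = find_steady_state(two_gene, np.full(4, 0.5))
        assert ss.oscillatory
        assert ss.linear_frequency == pytest.approx(1.049997, abs=5e-7)
        sp = find_steady_state(per, np.ones(5))
        assert sp.oscillatory
        assert sp.linear_frequency == pytest.approx(0.297276, abs=5e-7)

    def test_nonconvergence_raises(self, two_gene):
        with pytest.raises(RuntimeError, match="Newton"):
            find_steady_state(two_gene, np.full(4, 0.5), tol=1e-30, max_iter=3)


class TestLimitCycleFrequency:
    def test_linear_center_recovers_exact_frequency(self):
        w0 = 2.0
        J = np.array([[0.0, w0], [-w0, 0.0]])
        system = ODESystem(
            dim=2,
            f=lambda y: J @ y,
            jac=lambda y: J,
            g=lambda y: J @ (J @ y),
            name="center",
        )
        est = limit_cycle_frequency(
            system, np.array([1.0, 0.0]), burn_in=5.0, window=25.0, h=0.001, component=0
        )
        assert est.omega == pytest.approx(2.0, abs=1e-6)
        assert est.reliable

    def test_no_oscillation_detected_on_relaxing_system(self):
        system = ODESystem(
            dim=1,
            f=lambda y: -y,
            jac=lambda y: np.array([[-1.0]]),
            g=lambda y: y,
            name="decay",
        )
        with pytest.raises(RuntimeError, match="no sustained oscillation"):
            limit_cycle_frequency(
                system, np.array([1.0]), burn_in=1.0, window=5.0, h=0.01, component=0
            )


class TestGlobalError:
    def test_self_comparison_is_exactly_zero(self, two_gene):
        ref = integrate_fixed(two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25)
        r = global_error(
            two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25, "prototype", 0.0, 2, reference=ref
        )
        assert r.ge == 0.0

    def test_prototype_error_is_independent_of_omega(self, two_gene):
        ref = reference_trajectory(two_gene, TWO_GENE_Y0, 0.0, 10.0, default_h_ref(0.25))
        ges = {
            global_error(
                two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25, "prototype", w, 2, reference=ref
            ).ge
            for w in (0.0, 1.0, 3.0)
        }
        assert len(ges) == 1

    def test_norms_endpoint_vs_max(self, two_gene):
        ref = reference_trajectory(two_gene, TWO_GENE_Y0, 0.0, 10.0, default_h_ref(0.25))
        end = global_error(
            two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25, "prototype", 0.0, 2, reference=ref
        )
        mx = global_error(
            two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25, "prototype", 0.0, 2,
            reference=ref, norm="max",
        )
        assert mx.ge >= end.ge > 0.0

    def test_mismatched_reference_grid_rejected(self, two_gene):
        ref = integrate_fixed(two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.4)
        with pytest.raises(ValueError, match="integer multiple"):
            global_error(
                two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25, "prototype", 0.0, 2, reference=ref
            )


class TestSweepAndTables:
    def test_prototype_sweep_profile_is_flat_and_picks_first_point(self, two_gene):
        ref = reference_trajectory(two_gene, TWO_GENE_Y0, 0.0, 10.0, default_h_ref(0.5))
        sw = best_fitting_frequency(
            two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.5, "prototype", 2,
            omega_grid=np.arange(0.0, 0.5, 0.1), reference=ref,
        )
        assert sw.omega_star == 0.0
        assert np.ptp(sw.profile[:, 1]) == 0.0

    def test_fitted_sweep_beats_prototype_on_two_gene(self, two_gene):
        # coarse grid around the known-good region; the fitted method at its
        # best frequency must beat the prototype at the same step
        ref = reference_trajectory(two_gene, TWO_GENE_Y0, 0.0, 50.0, default_h_ref(0.125))
        proto = global_error(
            two_gene, TWO_GENE_Y0, 0.0, 50.0, 0.125, "prototype", 0.0, 2, reference=ref
        )
        sw = best_fitting_frequency(
            two_gene, TWO_GENE_Y0, 0.0, 50.0, 0.125, "efa", 2,
            omega_grid=np.arange(2.8, 3.4, 0.01), reference=ref,
        )
        assert sw.ge_star < proto.ge

    def test_efficiency_table_counts_and_consistency(self, two_gene):
        rows = efficiency_table(
            two_gene, TWO_GENE_Y0, 0.0, 10.0, [0.25], [("prototype", 0.0), ("rk6", 0.0)], 2
        )
        by_method = {r.method: r for r in rows}
        assert by_method["prototype"].evaluations == 40 * 5
        assert by_method["rk6"].evaluations == 40 * 7
        check = global_error(two_gene, TWO_GENE_Y0, 0.0, 10.0, 0.25, "prototype", 0.0, 2)
        assert by_method["prototype"].ge == pytest.approx(check.ge, rel=1e-12)

    def test_convergence_order_on_short_two_gene_window(self, two_gene):
        slope, results = convergence_order(
            two_gene, TWO_GENE_Y0, 0.0, 10.0, [1 / 4, 1 / 8, 1 / 16], 2
        )
        assert 5.0 <= slope <= 7.0
        assert all(r.ge > 0 for r in results)
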