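"""Simulation-in-the-loop inversion: objective, failure region, recovery."""

import numpy as np
import pytest

import rpinverse as rp
from rpinverse.forward import SolverConfig


class SharpSwitchConfig(rp.InverseConfig):
    """Inversion config using a near-Heaviside cone-death switch."""

    def solver_config(self):
        return SolverConfig(n_mesh=self.n_mesh, rel_tol=self.rel_tol,
                            abs_tol=self.abs_tol, save_dt=self.save_dt,
                            switch_sharpness=300.0)


@pytest.fixture(scope="module")
def inv_cfg():
    return rp.InverseConfig(n_mesh=26, scaling=1)


@pytest.fixture(scope="module")
def mesh26(inv_cfg):
    return inv_cfg.solver_config().mesh()


@pytest.fixture(scope="module")
def analytic_1a(params1, mesh26):
    target = rp.make_target("1A", "linear")
    prof = rp.analytic_inverse_profile(target, "phi_r", params1, mesh26,
                                       fixed_value=3e-5, scaling=1)
    return target, prof


class TestObjective:
    def test_empty_evaluation_set_is_zero(self, params1, inv_cfg, analytic_1a):
        target, prof = analytic_1a
        assert rp.objective(prof, target, params1, inv_cfg, "phi_r",
                            eval_nodes=np.array([], dtype=int)) == 0.0

    def test_analytic_inverse_is_near_optimal_mid_periphery(self, params1,
                                                            mesh26, analytic_1a):
        # Self-consistency of the asymptotic inverse with the forward model
        # in the sharp-switch limit, away from the fovea.
        target, prof = analytic_1a
        cfg = SharpSwitchConfig(n_mesh=26, scaling=1)
        nodes = np.flatnonzero((mesh26 >= 0.3) & (mesh26 <= 0.8))
        assert rp.objective(prof, target, params1, cfg, "phi_r",
                            eval_nodes=nodes) < 1.0

    def test_scaled_candidate_is_worse(self, params1, inv_cfg, mesh26, analytic_1a):
        target, prof = analytic_1a
        nodes = np.flatnonzero((mesh26 >= 0.3) & (mesh26 <= 0.8))
        base = rp.objective(prof, target, params1, inv_cfg, "phi_r", eval_nodes=nodes)
        scaled = rp.SpatialProfile((mesh26, prof.values * 1.5))
        worse = rp.objective(scaled, target, params1, inv_cfg, "phi_r", eval_nodes=nodes)
        assert worse > base


class TestFailureRegion:
    def test_confined_to_fovea_for_smooth_target(self, params1, inv_cfg,
                                                 mesh26, analytic_1a):
        target, prof = analytic_1a
        region = rp.find_failure_region(prof, target, params1, inv_cfg, "phi_r")
        assert region.size > 0
        assert np.all(mesh26[region] <= 0.15)

    def test_infinite_tolerance_empty(self, params1, inv_cfg, analytic_1a):
        target, prof = analytic_1a
        region = rp.find_failure_region(prof, target, params1, inv_cfg, "phi_r",
                                        tol=1e9)
        assert region.size == 0

    def test_zero_tolerance_flags_everything(self, params1, inv_cfg, analytic_1a):
        target, prof = analytic_1a
        region = rp.find_failure_region(prof, target, params1, inv_cfg, "phi_r",
                                        tol=1e-14)
        assert region.size == 26

    def test_nonpositive_tolerance_rejected(self, params1, inv_cfg, analytic_1a):
        target, prof = analytic_1a
        with pytest.raises(ValueError):
            rp.find_failure_region(prof, target, params1, inv_cfg, "phi_r", tol=0.0)


class TestNumericalInverse:
    def test_known_profile_recovered(self, recovery):
        # Parameter-recovery oracle: the smooth phi_r that generated the
        # target contour is recovered within 10% at failure-region nodes
        # and equals the analytic inverse elsewhere to within its accuracy.
        truth, target, result = recovery
        truth_vals = truth.on_grid(result.theta)
        rel = np.abs(result.values - truth_vals) / truth_vals
        assert result.region.size > 0
        assert np.max(rel[result.region]) < 0.10

    def test_result_positive_and_converged(self, recovery):
        _, _, result = recovery
        assert np.all(result.values > 0)
        assert result.converged
        assert result.method == "stitched"
        assert result.objective_trace[-1] <= result.objective_trace[0]

    def test_analytic_values_kept_outside_region(self, recovery, params1):
        _, target, result = recovery
        analytic = rp.analytic_inverse_profile(target, "phi_r", params1,
                                               result.theta, fixed_value=3e-5,
                                               scaling=1)
        outside = np.setdiff1d(np.arange(len(result.theta)), result.region)
        np.testing.assert_array_equal(result.values[outside],
                                      analytic.values[outside])

    def test_contour_matches_target_after_stitching(self, recovery):
        # Simulating with the stitched inverse reproduces the target within
        # the failure tolerance at at least 95% of nodes.
        _, target, result = recovery
        t_target = target.on_grid(result.theta)
        ok = np.abs(result.residuals) <= 0.05 * t_target
        assert ok.mean() >= 0.95

    def test_deterministic(self, recovery, params1):
        truth, target, result = recovery
        cfg = rp.InverseConfig(n_mesh=26, scaling=1)
        again = rp.numerical_inverse(target, "phi_r", params1, cfg)
        np.testing.assert_array_equal(result.values, again.values)

    def test_f_crit_inverse_below_analytic_near_fovea(self, params1):
        # The asymptotics overestimate how much TF foveal cones can demand;
        # the simulation-corrected threshold is lower there.
        cfg = rp.InverseConfig(n_mesh=26, scaling=1)
        target = rp.make_target("uniform")
        result = rp.numerical_inverse(target, "f_crit", params1, cfg)
        analytic = rp.analytic_inverse_profile(target, "f_crit", params1,
                                               result.theta, fixed_value=7.33e-2,
                                               scaling=1)
        assert result.region.size > 0
        fovea_nodes = result.region[result.theta[result.region] < 0.1]
        assert fovea_nodes.size > 0
        assert np.all(result.values[fovea_nodes] < analytic.values[fovea_nodes])
        assert np.all(result.values > 0)

    def test_coarse_to_fine_consistency(self, recovery, params1):
        # Inverting the same smooth target at N=26 and N=51 gives profiles
        # agreeing within 15% on a common grid.
        truth, _, res26 = recovery
        cfg51 = rp.InverseConfig(n_mesh=51, scaling=1)
        pars = params1.with_(phi_r=truth, f_crit=3e-5)
        sim = rp.simulate_forward(pars, cfg51.solver_config(), t_end=300.0)
        degen = rp.extract_degeneration_times(sim)
        target51 = rp.SpatialProfile((degen.theta, degen.t_degen))
        res51 = rp.numerical_inverse(target51, "phi_r", params1, cfg51)
        common = np.linspace(0.0, 1.0, 26)
        v26 = res26.profile().on_grid(common)
        v51 = res51.profile().on_grid(common)
        assert np.max(np.abs(v26 - v51) / v51) < 0.15

    def test_unknown_which_rejected(self, params1):
        with pytest.raises(ValueError):
            rp.numerical_inverse(rp.make_target("uniform"), "both", params1,
                                 rp.InverseConfig(n_mesh=26))


def test_pattern_search_minimizes_quadratic():
    from rpinverse.numeric import _coordinate_pattern_search
    fun = lambda x: float((x[0] - 1.0) ** 2 + 2.0 * (x[1] + 0.5) ** 2)
    x, f, trace, n_iter, converged = _coordinate_pattern_search(
        fun, np.zeros(2), initial_step=0.5, min_step=1e-6, max_iter=2000, f_tol=1e-10)
    assert converged
    assert np.allclose(x, [1.0, -0.5], atol=1e-4)
    assert trace == sorted(trace, reverse=True)
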