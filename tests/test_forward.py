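"""Discretization, steady state, and stiff forward integration."""

import numpy as np
import pytest

import rpinverse as rp
from rpinverse.model import StateFields


class TestSmoothedSwitch:
    def test_half_at_threshold(self):
        assert rp.smoothed_switch(1.0, 1.0, 50.0) == pytest.approx(0.5)

    def test_limits(self):
        assert rp.smoothed_switch(10.0, 1.0, 50.0) == pytest.approx(0.0, abs=1e-12)
        assert rp.smoothed_switch(-10.0, 1.0, 50.0) == pytest.approx(1.0, abs=1e-12)

    def test_bounded_and_decreasing_in_f(self):
        f = np.linspace(-2, 2, 201)
        out = rp.smoothed_switch(f, 0.3, 7.0)
        assert np.all((out >= 0) & (out <= 1))
        assert np.all(np.diff(out) <= 0)

    def test_positive_steepness_required(self):
        with pytest.raises(ValueError):
            rp.smoothed_switch(1.0, 1.0, 0.0)


class TestPdeRhs:
    def test_rod_equation_is_exact_pointwise_decay(self, params1):
        mesh = np.linspace(0, 1, 21)
        state = StateFields(mesh, np.ones(21), 2.0 + mesh, np.ones(21))
        _, dprdt, _ = rp.pde_rhs(state, params1)
        np.testing.assert_allclose(dprdt, -7.33e-2 * (2.0 + mesh), rtol=1e-14)

    @pytest.mark.parametrize("n", [51, 201, 801])
    def test_pole_diffusion_limit_quadratic_field(self, n, params1):
        # For f = theta^2 the spherical diffusion operator at the pole is
        # exactly 2 D_f f'' = 4 D_f = 0.948.
        mesh = np.linspace(0, 1, n)
        state = StateFields(mesh, mesh ** 2, np.zeros(n), np.zeros(n))
        dfdt, _, _ = rp.pde_rhs(state, params1)
        assert dfdt[0] == pytest.approx(4 * 0.237, rel=1e-10)

    def test_healthy_steady_state_is_stationary(self, params1, f_init_4001):
        # phi_r = 0 and f_crit far below min f: nothing drives change.
        p = params1.with_(phi_r=0.0, f_crit=3e-5)
        mesh = np.linspace(0, 1, 4001)
        state = StateFields(mesh, f_init_4001.on_grid(mesh),
                            p.rod_profile(mesh), p.cone_profile(mesh))
        dfdt, dprdt, dpcdt = rp.pde_rhs(state, p)
        assert np.max(np.abs(dfdt)) < 1e-6
        assert np.max(np.abs(dprdt)) < 1e-6
        assert np.max(np.abs(dpcdt)) < 1e-6


class TestSteadyState:
    def test_uniform_densities_closed_form(self, params1):
        # Uniform fields kill diffusion; f = alpha / (beta + eta) exactly.
        f = rp.steady_state_tf(1.0, 1.0, params1, n_mesh=101)
        expected = params1.alpha / (params1.beta + params1.eta)
        np.testing.assert_allclose(f.values, expected, rtol=1e-10)

    def test_healthy_profile_magnitudes(self, f_init_4001):
        # Central TF is orders of magnitude below mid-peripheral TF.
        assert f_init_4001(0.0) < 5e-4
        assert 0.1 < f_init_4001(0.5) < 2.0

    def test_min_exceeds_constant_threshold(self, f_init_4001):
        assert f_init_4001.values.min() >= 3e-5

    def test_mesh_convergence(self, params1, f_init_4001):
        f401 = rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                                  params1, n_mesh=401)
        th = np.linspace(0.05, 0.95, 181)
        a, b = f401.on_grid(th), f_init_4001.on_grid(th)
        assert np.max(np.abs(a - b) / b) < 0.01

    def test_matches_long_time_integration_of_tf_equation(self, params1):
        # Oracle: integrate the TF equation alone with frozen densities.
        from scipy.integrate import solve_ivp
        from rpinverse.forward import SolverConfig, _Discretization

        n = 101
        cfg = SolverConfig(n_mesh=n)
        disc = _Discretization(params1, cfg)
        p_r = params1.rod_profile(disc.mesh)
        p_c = params1.cone_profile(disc.mesh)
        L = disc.diffusion_matrix()
        sol = solve_ivp(lambda t, f: disc.f_rhs(f, p_r, p_c, L),
                        (0.0, 2.0), np.full(n, 0.01), method="BDF",
                        rtol=1e-10, atol=1e-14)
        f_direct = rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                                      params1, n_mesh=n)
        rel = np.abs(sol.y[:, -1] - f_direct.values) / f_direct.values
        assert np.max(rel) < 1e-4

    def test_comparative_statics(self, params1):
        base = rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                                  params1, n_mesh=101).values
        up_a = rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                                  params1.with_(alpha=params1.alpha * 1.5),
                                  n_mesh=101).values
        up_b = rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                                  params1.with_(beta=params1.beta * 1.5),
                                  n_mesh=101).values
        up_e = rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                                  params1.with_(eta=params1.eta * 100.0),
                                  n_mesh=101).values
        assert np.all(up_a > base)
        assert np.all(up_b < base)
        assert np.all(up_e < base)


class TestSimulateForward:
    def test_initial_conditions_are_healthy(self, constant_sim_401):
        res = constant_sim_401
        np.testing.assert_allclose(res.p_r[0], res.params.rod_profile(res.mesh), rtol=1e-12)
        np.testing.assert_allclose(res.p_c[0], res.params.cone_profile(res.mesh), rtol=1e-12)
        assert res.times[0] == 0.0
        assert np.all(np.diff(res.times) > 0)

    def test_no_degeneration_without_rod_loss(self, params1):
        # The foveal TF boundary layer (width ~ sqrt(D_f / (beta p_c)))
        # needs the 4001-node mesh; coarser meshes underestimate f(0) and
        # would push it below the 3e-5 threshold.
        p = params1.with_(phi_r=0.0)
        res = rp.simulate_forward(p, rp.SolverConfig(n_mesh=4001, save_dt=10.0), t_end=50.0)
        rel = np.abs(res.p_c[-1] - p.cone_profile(res.mesh)) / p.cone_profile(res.mesh)
        assert np.max(rel) < 1e-6

    def test_rod_field_matches_closed_form(self, constant_sim_401):
        res = constant_sim_401
        for i in [1, len(res.times) // 2, -1]:
            expected = rp.rod_closed_form(res.mesh, res.times[i], 7.33e-2, res.params)
            rel = np.abs(res.p_r[i, 1:] - expected[1:]) / expected[1:]
            assert np.max(rel) < 1e-5

    def test_earliest_degeneration_at_fovea(self, constant_sim_401):
        # Scaling 1, constant phi_r and f_crit: the TF minimum sits at the
        # fovea, so cones fail there first.
        degen = rp.extract_degeneration_times(constant_sim_401)
        assert degen.earliest_theta == 0.0

    def test_fields_nonnegative_and_monotone(self, constant_sim_401):
        res = constant_sim_401
        floor = -10 * res.config.abs_tol
        assert res.p_r.min() >= floor and res.p_c.min() >= floor
        assert np.all(np.diff(res.p_r, axis=0) <= 1e-9)
        assert np.all(np.diff(res.p_c, axis=0) <= 1e-9)

    def test_invalid_t_end_rejected(self, params1):
        with pytest.raises(ValueError):
            rp.simulate_forward(params1, t_end=-1.0)

    def test_tidy_export_shape(self, constant_sim_401, tmp_path):
        frame = constant_sim_401.to_frame()
        assert list(frame.columns) == ["time", "theta", "f", "p_r", "p_c"]
        assert len(frame) == len(constant_sim_401.times) * len(constant_sim_401.mesh)
        sidecar = constant_sim_401.sidecar()
        assert sidecar["config"]["n_mesh"] == 401


def test_solver_config_validation():
    with pytest.raises(ValueError):
        rp.SolverConfig(n_mesh=5)
    with pytest.raises(ValueError):
        rp.SolverConfig(rel_tol=-1.0)
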