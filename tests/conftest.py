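"""Shared fixtures; expensive forward runs are session-scoped and reused."""

import numpy as np
import pytest

import rpinverse as rp


@pytest.fixture(scope="session")
def params1():
    return rp.make_parameters(1)


@pytest.fixture(scope="session")
def params2():
    return rp.make_parameters(2)


@pytest.fixture(scope="session")
def f_init_4001(params1):
    """Healthy steady-state TF profile, Scaling 1, 4001-node mesh."""
    return rp.steady_state_tf(params1.rod_profile, params1.cone_profile,
                              params1, n_mesh=4001)


@pytest.fixture(scope="session")
def constant_sim_401(params1):
    """Forward run with constant phi_r and f_crit = 3e-5 (Scaling 1, N=401)."""
    cfg = rp.SolverConfig(n_mesh=401, save_dt=0.5)
    return rp.simulate_forward(params1, cfg, t_end=170.0)


@pytest.fixture(scope="session")
def protected_fovea_sim_401():
    """Forward run with the fovea-protected piecewise threshold (N=401).

    f_crit = 3e-5 for theta <= 0.13 (foveal cones withstand low TF) and
    0.3 beyond; Scaling 1, constant rod degeneration rate.
    """
    def f_crit(th):
        th = np.asarray(th, float)
        return np.where(th <= 0.13, 3e-5, 0.3)

    params = rp.make_parameters(1, f_crit=f_crit)
    cfg = rp.SolverConfig(n_mesh=401, save_dt=0.1)
    return rp.simulate_forward(params, cfg, t_end=10.0)


@pytest.fixture(scope="session")
def recovery(params1):
    """Parameter-recovery setup: simulate a known smooth phi_r, then invert.

    Returns (truth profile, target built from the simulated contour,
    InverseResult).
    """
    truth = rp.generate_fixture("smooth-phi-r-profile", seed=1)
    cfg = rp.InverseConfig(n_mesh=26, scaling=1)
    pars = params1.with_(phi_r=truth, f_crit=3e-5)
    sim = rp.simulate_forward(pars, cfg.solver_config(), t_end=300.0)
    degen = rp.extract_degeneration_times(sim)
    assert degen.degenerated.all()
    target = rp.SpatialProfile((degen.theta, degen.t_degen), name="recovery_target")
    result = rp.numerical_inverse(target, "phi_r", params1, cfg)
    return truth, target, result
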