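"""Reproducible experiment runner, serialization, and synthetic fixtures.

Each experiment writes plain CSV payloads plus a JSON sidecar holding the
exact parameters and solver settings, sufficient to re-run it.  Scenarios
mirror the study's main computations: forward degeneration contours under
constant parameters, analytic inverse sweeps, and simulation-in-the-loop
inversions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ModelParameters, SpatialProfile, make_parameters
from .forward import SolverConfig, SimulationResult, simulate_forward
from .degeneration import extract_degeneration_times
from .targets import make_target, PATTERNS
from .analytic import analytic_inverse_profile, inverse_to_frame
from .numeric import InverseConfig, numerical_inverse, FIXED_F_CRIT, FIXED_PHI_R

__all__ = ["ExperimentConfig", "run_experiment", "generate_fixture", "SCENARIOS"]

log = logging.getLogger("rpinverse")

SCENARIOS = (
    "forward-contours",        # Scalings 1+2, constant phi_r/f_crit, contour + analytic curves
    "forward-contours-protected-fovea",  # piecewise f_crit: fovea withstands low TF
    "analytic-inverse",        # analytic inverse sweep for one target
    "numerical-inverse",       # stitched analytic+numeric inversion for one target
    "no-degeneration",         # phi_r = 0 control: all-sentinel contour
)


@dataclass
class ExperimentConfig:
    """A named scenario plus every knob needed to reproduce it."""

    scenario: str = "forward-contours"
    scaling: int = 1
    pattern: str = "uniform"
    subpattern: str = ""
    which: str = "phi_r"
    n_mesh: int = 101
    t_end: float = 200.0
    save_dt: float = 0.5
    failure_tol: float = 0.05
    out_dir: str = "results"
    parameter_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_sidecar(out: Path, name: str, config: ExperimentConfig, extra: dict) -> None:
    payload = {"experiment": config.to_dict(), **extra,
               "written_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (out / f"{name}.json").write_text(json.dumps(payload, indent=2, default=str))


def _params_for(config: ExperimentConfig) -> ModelParameters:
    return make_parameters(config.scaling, **config.parameter_overrides)


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute a named scenario and write its artifacts; returns the directory."""
    if config.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {config.scenario!r}; known: {SCENARIOS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("running scenario %s -> %s", config.scenario, out)
    t_start = time.time()

    if config.scenario in ("forward-contours", "forward-contours-protected-fovea",
                           "no-degeneration"):
        _run_forward_scenario(config, out)
    elif config.scenario == "analytic-inverse":
        _run_analytic_inverse(config, out)
    elif config.scenario == "numerical-inverse":
        _run_numerical_inverse(config, out)
    log.info("scenario %s finished in %.1fs", config.scenario, time.time() - t_start)
    return out


def _run_forward_scenario(config: ExperimentConfig, out: Path) -> None:
    from .analytic import t_degen_analytic

    overrides = dict(config.parameter_overrides)
    if config.scenario == "forward-contours-protected-fovea":
        def fcrit(th, _lo=3e-5, _hi=0.3, _edge=0.13):
            th = np.asarray(th, float)
            return np.where(th <= _edge, _lo, _hi)
        overrides["f_crit"] = SpatialProfile(fcrit, name="f_crit_protected_fovea")
    if config.scenario == "no-degeneration":
        overrides["phi_r"] = 0.0

    params = make_parameters(config.scaling, **overrides)
    solver = SolverConfig(n_mesh=config.n_mesh, save_dt=config.save_dt)
    result = simulate_forward(params, solver, t_end=config.t_end)
    degen = extract_degeneration_times(result)
    degen.to_csv(out / "degeneration_profile.csv")
    result.to_csv(out / "simulation.csv")

    if config.scenario != "no-degeneration":
        mesh = result.mesh[1:]
        fc = params.f_crit_profile().on_grid(mesh)
        phi = params.phi_r_profile().on_grid(mesh)
        analytic = t_degen_analytic(mesh, phi, fc, params, scaling=config.scaling)
        np.savetxt(out / "analytic_t_degen.csv",
                   np.column_stack([mesh, analytic]), delimiter=",",
                   header="theta,t_degen_analytic", comments="")
    _write_sidecar(out, "run", config,
                   {"solver": result.sidecar(), "n_degenerated": int(degen.degenerated.sum())})


def _run_analytic_inverse(config: ExperimentConfig, out: Path) -> None:
    params = _params_for(config)
    target = make_target(config.pattern, config.subpattern)
    mesh = SolverConfig(n_mesh=config.n_mesh).mesh()
    fixed = FIXED_F_CRIT if config.which == "phi_r" else FIXED_PHI_R
    prof = analytic_inverse_profile(target, config.which, params, mesh,
                                    fixed_value=fixed, scaling=config.scaling)
    frame = inverse_to_frame(mesh, prof.values, config.which, config.scaling, fixed)
    frame.to_csv(out / "analytic_inverse.csv", index=False)
    _write_sidecar(out, "run", config, {"params": params.to_dict(), "target": target.name})


def _run_numerical_inverse(config: ExperimentConfig, out: Path) -> None:
    params = _params_for(config)
    target = make_target(config.pattern, config.subpattern)
    inv_cfg = InverseConfig(n_mesh=config.n_mesh, scaling=config.scaling,
                            failure_tol=config.failure_tol, save_dt=config.save_dt)
    result = numerical_inverse(target, config.which, params, inv_cfg)
    result.to_csv(out / "numerical_inverse.csv")
    _write_sidecar(out, "run", config, {
        "params": params.to_dict(), "target": target.name,
        "method": result.method, "converged": bool(result.converged),
        "n_iterations": int(result.n_iterations),
        "final_objective": float(result.objective_trace[-1]) if result.objective_trace else None,
        "objective_trace": [float(v) for v in result.objective_trace],
        "failure_region": [int(i) for i in result.region],
    })


# ---------------------------------------------------------------------------
# Synthetic fixtures for tests that must not run the PDE.

def generate_fixture(kind: str, seed: int = 0):
    """Deterministic synthetic inputs with known closed-form structure.

    ``smooth-phi-r-profile`` / ``smooth-fcrit-profile``: positive low-order
    polynomials of ``theta`` around the standard constant values;
    ``synthetic-simulation-for-contour-tests``: a
    :class:`~rpinverse.forward.SimulationResult` whose cone-survival
    fraction is ``exp(-max(0, t - g(theta)))`` for a known ``g``, so the
    99% contour is ``g(theta) + ln(1/0.99)`` exactly.
    """
    rng = np.random.default_rng(seed)
    if kind == "smooth-phi-r-profile":
        base = 7.33e-2
        c1, c2 = rng.uniform(-0.3, 0.3, size=2)
        return SpatialProfile(
            lambda th, b=base, c1=c1, c2=c2: b * (1.0 + c1 * np.asarray(th, float)
                                                  + c2 * np.asarray(th, float) ** 2),
            name=f"smooth_phi_r_seed{seed}")
    if kind == "smooth-fcrit-profile":
        base = 3e-5
        c1, c2 = rng.uniform(-0.4, 0.4, size=2)
        return SpatialProfile(
            lambda th, b=base, c1=c1, c2=c2: b * (1.0 + c1 * np.asarray(th, float)
                                                  + c2 * np.asarray(th, float) ** 2),
            name=f"smooth_fcrit_seed{seed}")
    if kind == "synthetic-simulation-for-contour-tests":
        params = make_parameters(1)
        n, nt = 51, 201
        mesh = np.linspace(0.0, 1.0, n)
        times = np.linspace(0.0, 20.0, nt)
        onset = 2.0 + 10.0 * mesh + 3.0 * rng.random() * mesh ** 2  # g(theta)
        healthy_c = params.cone_profile(mesh)
        healthy_r = params.rod_profile(mesh)
        ratio = np.exp(-np.maximum(0.0, times[:, None] - onset[None, :]))
        p_c = ratio * healthy_c[None, :]
        p_r = np.repeat(healthy_r[None, :], nt, axis=0)
        f = np.ones((nt, n))
        return SimulationResult(mesh=mesh, times=times, f=f, p_r=p_r, p_c=p_c,
                                params=params, config=SolverConfig(n_mesh=n),
                                diagnostics={"success": True, "synthetic": True,
                                             "onset_g": onset.tolist()})
    raise ValueError(f"unknown fixture kind {kind!r}")
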