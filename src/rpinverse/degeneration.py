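"""Cone degeneration-time extraction and quasi-steady-state approximations.

Cone degeneration at a location is "deemed to have initiated" when the
local cone density first falls to 99% of its healthy value; the map
``theta -> t_degen(theta)`` of those first-crossing times is the model's
primary observable, and the quantity the inverse problem targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParameters, as_profile, rod_profile, cone_profile
from .forward import SimulationResult

__all__ = [
    "DegenerationProfile",
    "rod_closed_form",
    "qssa_tf",
    "extract_degeneration_times",
]

#: Default cone-survival fraction defining degeneration onset.
DEGENERATION_FRACTION = 0.99


@dataclass
class DegenerationProfile:
    """First-crossing times of the cone-survival fraction on a mesh.

    ``t_degen`` holds NaN at nodes that never degenerated within the
    simulation horizon; the ``degenerated`` boolean mask is the explicit
    sentinel (never an arbitrary large number).
    """

    theta: np.ndarray
    t_degen: np.ndarray
    degenerated: np.ndarray
    fraction: float = DEGENERATION_FRACTION

    def __post_init__(self):
        valid = self.t_degen[self.degenerated]
        if valid.size and np.any(valid < 0):
            raise ValueError("degeneration times must be non-negative")

    @property
    def earliest_theta(self) -> float:
        """Eccentricity of the earliest degeneration (the contour's origin)."""
        if not self.degenerated.any():
            raise ValueError("no node degenerated within the horizon")
        times = np.where(self.degenerated, self.t_degen, np.inf)
        return float(self.theta[np.argmin(times)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.theta, "t_degen": self.t_degen,
                             "degenerated": self.degenerated})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rod_closed_form(theta, t, phi_r_profile, params: ModelParameters | None = None):
    """Exact rod density ``p_r(theta, t) = p_r_healthy(theta) e^(-phi_r(theta) t)``.

    The rod equation is a pointwise linear decay, so it integrates in
    closed form for any spatial rate profile.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    p = params or ModelParameters()
    th = np.asarray(theta, dtype=float)
    phi = as_profile(phi_r_profile).on_grid(np.atleast_1d(th))
    phi = phi.reshape(th.shape) if th.shape else float(phi[0])
    out = rod_profile(th, p.B3, p.b3) * np.exp(-phi * np.asarray(t, float))
    return float(out) if np.ndim(out) == 0 else out


def qssa_tf(theta, t, params: ModelParameters, scaling: int | None = None):
    """Quasi-steady-state TF concentration in the pre-degeneration regime.

    TF equilibrates much faster than rods decay, so diffusion and time
    derivatives drop at leading order and the TF concentration tracks the
    instantaneous production/consumption balance:

    * Scaling 1: ``alpha p_r(theta, t) / (beta p_c(theta))``
    * Scaling 2: ``alpha p_r(theta, t) / (beta p_c(theta) + eta)``

    with rods from :func:`rod_closed_form` and cones frozen at their
    healthy profile.
    """
    sc = scaling if scaling is not None else params.scaling
    if sc not in (1, 2):
        raise ValueError("scaling must be 1 or 2")
    th = np.asarray(theta, dtype=float)
    p_r = rod_closed_form(th, t, params.phi_r, params)
    p_c = cone_profile(th, params.B1, params.B2, params.b1, params.b2)
    denom = params.beta * np.asarray(p_c)
    if sc == 2:
        denom = denom + params.eta
    out = params.alpha * np.asarray(p_r) / denom
    return float(out) if np.ndim(theta) == 0 and np.ndim(t) == 0 else out


def extract_degeneration_times(result: SimulationResult,
                               fraction: float = DEGENERATION_FRACTION) -> DegenerationProfile:
    """Per-node first crossing of ``p_c / p_c_healthy = fraction``.

    Crossing times are linearly interpolated between saved outputs; nodes
    whose survival fraction never reaches the threshold within the saved
    horizon are flagged as non-degenerated.
    """
    if len(result.times) < 2:
        raise ValueError("result must contain at least 2 saved times")
    healthy = result.params.cone_profile(result.mesh)
    ratio = result.p_c / healthy
    n = len(result.mesh)
    times = result.times
    t_degen = np.full(n, np.nan)
    degenerated = np.zeros(n, dtype=bool)

    increases = np.diff(ratio, axis=0)
    if np.any(increases > 1e-6):
        warnings.warn("cone survival fraction increased between outputs "
                      f"(max jump {increases.max():.2e})", RuntimeWarning)

    below = ratio <= fraction
    for i in range(n):
        if not below[:, i].any():
            continue
        k = int(np.argmax(below[:, i]))
        degenerated[i] = True
        if k == 0:
            t_degen[i] = times[0]
            continue
        r0, r1 = ratio[k - 1, i], ratio[k, i]
        if r1 == r0:
            t_degen[i] = times[k]
        else:
            t_degen[i] = times[k - 1] + (fraction - r0) / (r1 - r0) * (times[k] - times[k - 1])
    return DegenerationProfile(theta=result.mesh.copy(), t_degen=t_degen,
                               degenerated=degenerated, fraction=fraction)
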