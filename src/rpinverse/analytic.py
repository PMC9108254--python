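"""Closed-form asymptotic solutions of the inverse problem.

Under the quasi-steady-state approximation, cone degeneration at
eccentricity ``theta`` initiates when the QSSA TF concentration drops to
the local threshold ``f_crit(theta)``.  Because rods decay exponentially
this condition inverts algebraically, giving (Scaling 1, decay negligible):

    t_degen(theta)   = (1/phi_r) [ ln( alpha B3 theta / (beta B2 f_crit) )
                                   - (b3 - b2) theta ]
    phi_r_inv(theta) = the same bracket divided by the target time
    f_crit_inv(theta)= (alpha B3 theta / (beta B2))
                       e^{ -((b3 - b2) theta + phi_r t_degen(theta)) }

Under Scaling 2 the TF decay term joins the dominant balance and
``beta B2`` is replaced by ``beta B2 + eta e^{b2 theta}`` throughout.

The approximation breaks down near the fovea (the logarithm diverges as
``theta -> 0``); profile-level helpers therefore evaluate from a minimum
interior eccentricity and extend flat below it, and the numerical inverse
supersedes the analytic one in that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParameters, SpatialProfile
from .targets import TargetProfile

__all__ = [
    "t_degen_analytic",
    "phi_r_inverse",
    "f_crit_inverse",
    "analytic_inverse_profile",
]


def _check_positive_theta(theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0.0) or np.any(th > 1.0):
        raise ValueError("theta must lie in (0, 1]: the asymptotic formulas "
                         "break down at the fovea (log divergence)")
    return th


def _denominator(params: ModelParameters, theta, scaling: int):
    """``beta B2`` (Scaling 1) or ``beta B2 + eta e^{b2 theta}`` (Scaling 2)."""
    if scaling not in (1, 2):
        raise ValueError("scaling must be 1 or 2")
    base = params.beta * params.B2
    if scaling == 2:
        return base + params.eta * np.exp(params.b2 * np.asarray(theta, float))
    return base


def t_degen_analytic(theta, phi_r, f_crit, params: ModelParameters,
                     scaling: int | None = None, clamp: bool = True):
    """Asymptotic cone degeneration time for given rate/threshold values.

    ``phi_r`` and ``f_crit`` may be scalars or arrays matching ``theta``.
    Negative predictions (degeneration before onset, possible for extreme
    parameters) are clamped to 0 when ``clamp`` is set.
    """
    th = _check_positive_theta(theta)
    sc = scaling if scaling is not None else params.scaling
    phi = np.asarray(phi_r, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi_r must be strictly positive")
    fc = np.asarray(f_crit, dtype=float)
    p = params
    bracket = (np.log(p.alpha * p.B3 * th / (_denominator(p, th, sc) * fc))
               - (p.b3 - p.b2) * th)
    out = bracket / phi
    if clamp:
        out = np.maximum(out, 0.0)
    return float(out) if np.ndim(theta) == 0 else out


def phi_r_inverse(theta, target, f_crit, params: ModelParameters,
                  scaling: int | None = None):
    """Rod degeneration-rate profile reproducing a target degeneration time.

    ``target`` is a :class:`TargetProfile` or any callable of ``theta``
    (or a scalar time).  The TF threshold is held fixed at ``f_crit``.
    """
    th = _check_positive_theta(theta)
    sc = scaling if scaling is not None else params.scaling
    t_target = np.asarray(target(th) if callable(target) else target, dtype=float)
    if np.any(t_target <= 0):
        raise ValueError("target degeneration times must be strictly positive")
    p = params
    bracket = (np.log(p.alpha * p.B3 * th / (_denominator(p, th, sc) * f_crit))
               - (p.b3 - p.b2) * th)
    out = bracket / t_target
    return float(out) if np.ndim(theta) == 0 else out


def f_crit_inverse(theta, target, phi_r, params: ModelParameters,
                   scaling: int | None = None):
    """TF threshold profile reproducing a target degeneration time.

    Well-defined at the fovea (value 0 by the ``theta`` prefactor); the rod
    degeneration rate is held fixed at ``phi_r``.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0.0) or np.any(th > 1.0):
        raise ValueError("theta must lie in [0, 1]")
    sc = scaling if scaling is not None else params.scaling
    t_target = np.asarray(target(th) if callable(target) else target, dtype=float)
    p = params
    out = (p.alpha * p.B3 * th / _denominator(p, th, sc)
           * np.exp(-((p.b3 - p.b2) * th + phi_r * t_target)))
    return float(out) if np.ndim(theta) == 0 else out


def analytic_inverse_profile(target, which: str, params: ModelParameters,
                             mesh: np.ndarray,
                             fixed_value: float | None = None,
                             scaling: int | None = None) -> SpatialProfile:
    """Analytic inverse evaluated on a mesh, with fovea handling.

    ``which`` selects ``"phi_r"`` (fixed counterpart ``f_crit``, default
    3e-5) or ``"f_crit"`` (fixed counterpart ``phi_r``, default 7.33e-2).
    Nodes at or below the first interior mesh node are filled flat from the
    nearest valid value — the asymptotics break down at the fovea and the
    numerical inverse is expected to supersede this region.
    """
    mesh = np.asarray(mesh, dtype=float)
    sc = scaling if scaling is not None else params.scaling
    interior = mesh > 0.0
    values = np.empty_like(mesh)
    if which == "phi_r":
        fixed = 3e-5 if fixed_value is None else fixed_value
        values[interior] = phi_r_inverse(mesh[interior], target, fixed, params, sc)
    elif which == "f_crit":
        fixed = 7.33e-2 if fixed_value is None else fixed_value
        values[interior] = f_crit_inverse(mesh[interior], target, fixed, params, sc)
    else:
        raise ValueError("which must be 'phi_r' or 'f_crit'")
    if not interior.all():
        first = np.argmax(interior)
        values[:first] = values[first]
    # Flat fill any non-positive values from the nearest valid interior node
    # (keeps the profile usable as an optimizer initializer).
    bad = values <= 0.0
    if bad.all():
        raise ValueError("analytic inverse is non-positive everywhere")
    if bad.any():
        good_idx = np.flatnonzero(~bad)
        for i in np.flatnonzero(bad):
            values[i] = values[good_idx[np.argmin(np.abs(good_idx - i))]]
    return SpatialProfile((mesh, values), name=f"{which}_inv_analytic")


def inverse_to_frame(mesh: np.ndarray, values: np.ndarray, which: str,
                     scaling: int, fixed_value: float) -> pd.DataFrame:
    """Tidy export of an inverse profile with its fixed-parameter metadata."""
    return pd.DataFrame({"theta": mesh, "value": values, "which": which,
                         "scaling": scaling, "fixed_value": fixed_value})
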