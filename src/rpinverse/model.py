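"""Model constants, healthy photoreceptor profiles, and shared containers.

The model describes rod-derived cone viability factor (RdCVF, the "trophic
factor", TF) dynamics on a 1D spherical-cap retina spanning the fovea
(``theta = 0``) to the ora serrata (``theta = 1`` in scaled eccentricity,
``Theta = 1.33`` rad physically).  All quantities are dimensionless.

Two asymptotic regimes are supported for the TF production (``alpha``) and
consumption (``beta``) rates:

* **Scaling 1** — production/consumption dominate decay
  (``alpha = 7.01e4``, ``beta = 1.79e6``);
* **Scaling 2** — production/consumption balance decay
  (``alpha = 7.01e2``, ``beta = 1.79e4``).

The TF decay rate ``eta = 1.79e2`` is common to both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Union

import numpy as np

__all__ = [
    "ModelParameters",
    "SpatialProfile",
    "StateFields",
    "rod_profile",
    "cone_profile",
    "rod_cone_ratio",
    "make_parameters",
    "as_profile",
]

#: Ora serrata eccentricity in radians (the physical half-angle of the domain).
THETA_ORA_SERRATA = 1.33

#: Asymptotic bookkeeping parameter, O(1e-2). Used only in derivation
#: cross-checks and documentation, never at runtime.
EPSILON = 1e-2

_SCALINGS = {
    1: {"alpha": 7.01e4, "beta": 1.79e6},
    2: {"alpha": 7.01e2, "beta": 1.79e4},
}

_TABLE_DEFAULTS = {
    "Theta": THETA_ORA_SERRATA,
    "D_f": 0.237,
    "eta": 1.79e2,
    "phi_r": 7.33e-2,
    "f_crit": 3e-5,
    "B1": 1.56,
    "B2": 0.158,
    "B3": 10.6,
    "b1": 71.8,
    "b2": 2.67,
    "b3": 3.06,
}


class SpatialProfile:
    """A scalar field over dimensionless eccentricity ``theta in [0, 1]``.

    Either wraps a closed-form callable of ``theta`` or a ``(grid, values)``
    pair evaluated by piecewise-linear interpolation.  Grid form requires a
    strictly increasing grid with endpoints 0 and 1; evaluation at grid
    nodes reproduces the stored values exactly.
    """

    def __init__(
        self,
        representation: Union[Callable[[np.ndarray], np.ndarray], tuple],
        name: str = "",
    ):
        self.name = name
        if callable(representation):
            self._func = representation
            self._grid = None
            self._values = None
        else:
            grid, values = representation
            grid = np.asarray(grid, dtype=float)
            values = np.asarray(values, dtype=float)
            if grid.ndim != 1 or grid.shape != values.shape:
                raise ValueError("grid and values must be 1-D arrays of equal length")
            if not np.all(np.diff(grid) > 0):
                raise ValueError("grid must be strictly increasing")
            if not (grid[0] == 0.0 and grid[-1] == 1.0):
                raise ValueError("grid must span [0, 1] exactly")
            self._func = None
            self._grid = grid
            self._values = values

    @property
    def is_grid(self) -> bool:
        return self._grid is not None

    @property
    def grid(self):
        return self._grid

    @property
    def values(self):
        return self._values

    def __call__(self, theta):
        theta_arr = np.asarray(theta, dtype=float)
        if np.any(theta_arr < 0.0) or np.any(theta_arr > 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if self._func is not None:
            out = np.asarray(self._func(theta_arr), dtype=float)
            out = np.broadcast_to(out, theta_arr.shape).copy() if out.shape != theta_arr.shape else out
        else:
            out = np.interp(theta_arr, self._grid, self._values)
        if np.isscalar(theta) or np.ndim(theta) == 0:
            return float(out)
        return out

    def on_grid(self, theta_grid: np.ndarray) -> np.ndarray:
        """Evaluate on a mesh, returned as a plain array."""
        return np.atleast_1d(np.asarray(self(theta_grid), dtype=float))


ProfileLike = Union[float, SpatialProfile, Callable]


def as_profile(value: ProfileLike, name: str = "") -> SpatialProfile:
    """Coerce a scalar, callable, or profile into a :class:`SpatialProfile`."""
    if isinstance(value, SpatialProfile):
        return value
    if callable(value):
        return SpatialProfile(value, name=name)
    const = float(value)
    return SpatialProfile(lambda th, c=const: np.full_like(np.asarray(th, float), c), name=name)


@dataclass
class ModelParameters:
    """All constants of the dimensionless model.

    ``phi_r`` (mutation-induced rod degeneration rate) and ``f_crit`` (TF
    threshold concentration below which cones degenerate) may be scalars or
    :class:`SpatialProfile` objects; everything else is a positive scalar.
    """

    Theta: float = THETA_ORA_SERRATA
    D_f: float = 0.237
    alpha: float = 7.01e4
    beta: float = 1.79e6
    eta: float = 1.79e2
    phi_r: ProfileLike = 7.33e-2
    f_crit: ProfileLike = 3e-5
    B1: float = 1.56
    B2: float = 0.158
    B3: float = 10.6
    b1: float = 71.8
    b2: float = 2.67
    b3: float = 3.06
    epsilon: float = EPSILON
    scaling: int = 1

    def __post_init__(self):
        for name in ("Theta", "D_f", "alpha", "beta", "eta", "B1", "B2", "B3", "b1", "b2", "b3", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        check = np.linspace(0.0, 1.0, 21)
        if np.any(as_profile(self.phi_r).on_grid(check) < 0):
            raise ValueError("phi_r must be non-negative on [0, 1]")
        if np.any(as_profile(self.f_crit).on_grid(check) <= 0):
            raise ValueError("f_crit must be strictly positive on [0, 1]")

    # -- healthy profiles -------------------------------------------------
    def rod_profile(self, theta):
        return rod_profile(theta, self.B3, self.b3)

    def cone_profile(self, theta):
        return cone_profile(theta, self.B1, self.B2, self.b1, self.b2)

    def phi_r_profile(self) -> SpatialProfile:
        return as_profile(self.phi_r, "phi_r")

    def f_crit_profile(self) -> SpatialProfile:
        return as_profile(self.f_crit, "f_crit")

    def with_(self, **overrides) -> "ModelParameters":
        return replace(self, **overrides)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        """Flat key-value form; spatial profiles serialize to grid samples."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("phi_r", "f_crit") and not np.isscalar(v):
                prof = as_profile(v)
                grid = prof.grid if prof.is_grid else np.linspace(0, 1, 101)
                out[f.name] = {"theta": list(map(float, grid)),
                               "values": list(map(float, prof.on_grid(grid)))}
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        kwargs = dict(d)
        for key in ("phi_r", "f_crit"):
            v = kwargs.get(key)
            if isinstance(v, dict):
                kwargs[key] = SpatialProfile((np.asarray(v["theta"]), np.asarray(v["values"])), name=key)
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))


@dataclass
class StateFields:
    """Fields ``(f, p_r, p_c)`` on a uniform eccentricity mesh at time ``t``."""

    mesh: np.ndarray
    f: np.ndarray
    p_r: np.ndarray
    p_c: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        n = len(self.mesh)
        if not (len(self.f) == len(self.p_r) == len(self.p_c) == n):
            raise ValueError("all fields must match the mesh length")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.f, self.p_r, self.p_c])

    @classmethod
    def unpack(cls, mesh: np.ndarray, y: np.ndarray, t: float = 0.0) -> "StateFields":
        n = len(mesh)
        return cls(mesh=mesh, f=y[:n], p_r=y[n:2 * n], p_c=y[2 * n:], t=t)


def _check_domain(theta) -> np.ndarray:
    arr = np.asarray(theta, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("theta must lie in [0, 1]")
    return arr


def rod_profile(theta, B3: float = 10.6, b3: float = 3.06):
    """Healthy rod density ``B3 * theta * exp(-b3 * theta)``.

    Zero at the fovea (rods are absent from the foveal centre), peaking in
    the mid-periphery at ``theta = 1/b3``.
    """
    arr = _check_domain(theta)
    out = B3 * arr * np.exp(-b3 * arr)
    return float(out) if np.ndim(theta) == 0 else out


def cone_profile(theta, B1: float = 1.56, B2: float = 0.158, b1: float = 71.8, b2: float = 2.67):
    """Healthy cone density ``B1*exp(-b1*theta) + B2*exp(-b2*theta)``.

    Strictly decreasing: cones are densest at the fovea with a steep
    fall-off (the ``b1`` term) plus a gentle peripheral decline (``b2``).
    """
    arr = _check_domain(theta)
    out = B1 * np.exp(-b1 * arr) + B2 * np.exp(-b2 * arr)
    return float(out) if np.ndim(theta) == 0 else out


def rod_cone_ratio(theta, params: ModelParameters | None = None):
    """Healthy rod:cone density ratio; 0 at the fovea, single-peaked."""
    p = params or ModelParameters()
    arr = _check_domain(theta)
    out = rod_profile(arr, p.B3, p.b3) / cone_profile(arr, p.B1, p.B2, p.b1, p.b2)
    return float(out) if np.ndim(theta) == 0 else out


def make_parameters(scaling: int = 1, **overrides) -> ModelParameters:
    """Build the default parameter set for one of the two asymptotic scalings.

    Parameters
    ----------
    scaling
        1 (decay negligible) or 2 (decay in the dominant balance); selects
        ``alpha`` and ``beta``.
    **overrides
        Any declared :class:`ModelParameters` field, e.g. ``phi_r=0`` or a
        spatial ``f_crit`` profile.
    """
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be 1 or 2, got {scaling!r}")
    valid = {f.name for f in fields(ModelParameters)}
    unknown = set(overrides) - valid
    if unknown:
        raise KeyError(f"unknown parameter override(s): {sorted(unknown)}")
    kwargs = dict(_TABLE_DEFAULTS)
    kwargs.update(_SCALINGS[scaling])
    kwargs["scaling"] = scaling
    kwargs.update(overrides)
    return ModelParameters(**kwargs)
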