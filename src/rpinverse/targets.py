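"""Library of target cone-degeneration-time profiles and reporting units.

The targets idealize the clinically observed geometries of visual-field
loss in retinitis pigmentosa:

* **Uniform** — simultaneous loss everywhere (comparison case);
* **Pattern 1A** — peripheral restriction: degeneration earliest at the
  periphery, latest at the fovea (linear and quadratic variants);
* **Pattern 1B** — 1A plus a para-foveal ring scotoma: an early-degenerating
  annulus around ``theta_d1`` (linear, quadratic, exponential variants);
* **Pattern 3** — mid-peripheral onset near ``theta_d3``/``theta_d4``
  spreading both ways (two piecewise-linear, a quadratic, and a cubic
  variant).

All profiles map eccentricity ``theta in [0, 1]`` to a dimensionless
degeneration time in ``[t0, t2]`` with landmarks ``t0 < t1 < t2``
(defaults 100, 150, 200, roughly 11-22 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import THETA_ORA_SERRATA

__all__ = [
    "TargetProfileParams",
    "TargetProfile",
    "make_target",
    "cubic_coefficients",
    "theta_to_degrees",
    "time_to_years",
    "PATTERNS",
]

#: Dimensional reporting factor (years per dimensionless time unit).
#: Reporting convenience only; never used in computation.
YEARS_PER_TIME_UNIT = 0.1105


@dataclass(frozen=True)
class TargetProfileParams:
    """Landmark times, breakpoint eccentricities, and shape constants.

    ``thetad2`` is tied to ``thetad1`` by ``thetad2 = (thetad1 + 1) / 2``
    (midway between the ring and the ora serrata).  The cubic coefficients
    ``C0..C3`` are computed from the landmarks, not free.
    """

    t0: float = 100.0
    t1: float = 150.0
    t2: float = 200.0
    thetad1: float = 0.1
    thetad3: float = 0.3
    thetad4: float = 0.4
    thetad5: float = 0.6
    A1: float = 125.0
    A2: float = 600.0
    A3: float = 75.0
    a1: float = 71.8
    a2: float = 3.06

    def __post_init__(self):
        if not (self.t0 < self.t1 < self.t2):
            raise ValueError("landmark times must satisfy t0 < t1 < t2")
        if not (0 < self.thetad1 < self.thetad3 < self.thetad4 < self.thetad5 < 1):
            raise ValueError("breakpoints must satisfy "
                             "0 < thetad1 < thetad3 < thetad4 < thetad5 < 1")

    @property
    def thetad2(self) -> float:
        return (self.thetad1 + 1.0) / 2.0

    def cubic(self) -> tuple:
        return cubic_coefficients(self.t0, self.t1, self.t2, self.thetad4)


def cubic_coefficients(t0: float, t1: float, t2: float, thetad4: float) -> tuple:
    """Coefficients of the cubic Pattern-3 profile ``C0 + C1 x + C2 x^2 + C3 x^3``.

    The cubic is pinned by four conditions: value ``t2`` at the fovea,
    a minimum ``t0`` at ``thetad4`` (value and zero slope), and value
    ``t1`` at the ora serrata.  Written as closed-form rationals:

    ``C1 = [-2(t2-t0) + 3(t2-t0) x - (t2-t1) x^3] / (x (1-x)^2)``
    ``C2 = [ (t2-t0) - 3(t2-t0) x^2 + 2(t2-t1) x^3] / (x^2 (1-x)^2)``
    ``C3 = [-(t2-t0) + 2(t2-t0) x - (t2-t1) x^2] / (x^2 (1-x)^2)``

    with ``x = thetad4``.  Defaults give (200, -577.8, 1013.9, -486.1).
    """
    x = thetad4
    if x <= 0.0 or x >= 1.0:
        raise ZeroDivisionError("thetad4 must lie strictly inside (0, 1)")
    d20 = t2 - t0
    d21 = t2 - t1
    den = x * (1.0 - x) ** 2
    C0 = t2
    C1 = (-2.0 * d20 + 3.0 * d20 * x - d21 * x ** 3) / den
    C2 = (d20 - 3.0 * d20 * x ** 2 + 2.0 * d21 * x ** 3) / (x * den)
    C3 = (-d20 + 2.0 * d20 * x - d21 * x ** 2) / (x * den)
    return C0, C1, C2, C3


@dataclass(frozen=True)
class TargetProfile:
    """A named degeneration-time pattern, evaluable as ``t_degen(theta)``."""

    pattern: str
    subpattern: str
    params: TargetProfileParams

    @property
    def name(self) -> str:
        return f"{self.pattern}/{self.subpattern}" if self.subpattern else self.pattern

    def __call__(self, theta):
        th = np.asarray(theta, dtype=float)
        if np.any(th < 0.0) or np.any(th > 1.0):
            raise ValueError("theta must lie in [0, 1]")
        out = _EVALUATORS[(self.pattern, self.subpattern)](th, self.params)
        return float(out) if np.ndim(theta) == 0 else out

    def to_frame(self, n: int = 1001) -> pd.DataFrame:
        th = np.linspace(0.0, 1.0, n)
        return pd.DataFrame({"theta": th, "t_degen": self(th)})

    def to_csv(self, path, n: int = 1001) -> None:
        self.to_frame(n).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pattern formulas.  Piecewise targets are evaluated exactly as defined,
# right-continuous at breakpoints; no smoothing.

def _uniform(th, p):
    return np.full_like(th, p.t1)


def _p1a_linear(th, p):
    return p.t2 - (p.t2 - p.t0) * th


def _p1a_quad_up(th, p):
    return (p.t2 - p.t0) * (th - 1.0) ** 2 + p.t0


def _p1a_quad_down(th, p):
    return p.t2 - (p.t2 - p.t0) * th ** 2


def _p1b_linear(th, p):
    d1, d2 = p.thetad1, p.thetad2
    return np.select(
        [th <= d1, th <= d2],
        [p.t2 - (p.t2 - p.t1) / d1 * th,
         p.t0 + (p.t1 - p.t0) / (d2 - d1) * (th - d1)],
        default=p.t1 + (p.t1 - p.t0) / (1.0 - d2) * (d2 - th),
    )


def _p1b_quadratic(th, p):
    d1, d2 = p.thetad1, p.thetad2
    return np.where(
        th <= d1,
        (p.t2 - p.t1) / d1 ** 2 * (th - d1) ** 2 + p.t1,
        p.t1 - (p.t1 - p.t0) / (d2 - 1.0) ** 2 * (th - d2) ** 2,
    )


def _p1b_exponential(th, p):
    # Reconstructed sum-of-exponentials ring profile: equals t2 at the
    # fovea (A1 + A3 = t2), dips toward the ring, and rises to a
    # mid-/far-peripheral maximum of about t1 near theta = 1/a2.
    return p.A1 * np.exp(-p.a1 * th) + p.A2 * th * np.exp(-p.a2 * th) + p.A3


def _p3_linear1(th, p):
    d4 = p.thetad4
    return np.where(
        th <= d4,
        p.t2 - (p.t2 - p.t0) / d4 * th,
        p.t0 + (p.t1 - p.t0) / (1.0 - d4) * (th - d4),
    )


def _p3_linear2(th, p):
    d3, d5 = p.thetad3, p.thetad5
    return np.select(
        [th <= d3, th <= d5],
        [p.t2 - (p.t2 - p.t1) / d3 * th, np.full_like(th, p.t0)],
        default=p.t0 + (p.t1 - p.t0) / (1.0 - d5) * (th - d5),
    )


def _p3_quadratic(th, p):
    d3, d4 = p.thetad3, p.thetad4
    return np.where(
        th <= d3,
        (p.t2 - p.t1) / d3 ** 2 * (th - d3) ** 2 + p.t1,
        (p.t1 - p.t0) / (1.0 - d4) ** 2 * (th - d4) ** 2 + p.t0,
    )


def _p3_cubic(th, p):
    C0, C1, C2, C3 = p.cubic()
    return C0 + C1 * th + C2 * th ** 2 + C3 * th ** 3


_EVALUATORS = {
    ("uniform", ""): _uniform,
    ("1A", "linear"): _p1a_linear,
    ("1A", "quadratic_up"): _p1a_quad_up,
    ("1A", "quadratic_down"): _p1a_quad_down,
    ("1B", "linear"): _p1b_linear,
    ("1B", "quadratic"): _p1b_quadratic,
    ("1B", "exponential"): _p1b_exponential,
    ("3", "linear1"): _p3_linear1,
    ("3", "linear2"): _p3_linear2,
    ("3", "quadratic"): _p3_quadratic,
    ("3", "cubic"): _p3_cubic,
}

#: All recognized (pattern, subpattern) pairs.
PATTERNS = tuple(sorted(_EVALUATORS))


def make_target(pattern: str, subpattern: str = "",
                params: TargetProfileParams | None = None) -> TargetProfile:
    """Build a named target profile; raises on unrecognized pairs."""
    key = (pattern, subpattern or "")
    if key not in _EVALUATORS:
        raise KeyError(f"unknown target {key!r}; known: {PATTERNS}")
    return TargetProfile(pattern=key[0], subpattern=key[1],
                         params=params or TargetProfileParams())


def theta_to_degrees(theta, Theta: float = THETA_ORA_SERRATA):
    """Convert scaled eccentricity to visual degrees (``theta * Theta * 180/pi``)."""
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0.0) or np.any(th > 1.0):
        raise ValueError("theta must lie in [0, 1]")
    out = th * Theta * 180.0 / math.pi
    return float(out) if np.ndim(theta) == 0 else out


def time_to_years(t, factor: float = YEARS_PER_TIME_UNIT):
    """Convert dimensionless time to years for reporting (default 0.1105 yr/unit)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    out = arr * factor
    return float(out) if np.ndim(t) == 0 else out
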