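"""Domain types and shared radial machinery for the annular perfusion model.

The left-ventricle wall is modelled as a saturated porous annulus
``r1 <= r <= r2`` (a unit-height short-axis slice).  Hydraulic conductivity
grows quadratically with radius, ``K(r) = K1 (r/r1)^2``, mimicking the
coronary tree whose vessel calibre increases from the endocardium outward,
while the specific storage ``Ss`` (the elastic swelling capacity of the
vessel/fibre matrix) is uniform.  Transmural pressure ``p`` (blood pressure
in excess of the capillary reference ``p_c``) obeys a diffusion equation
driven by a pulsatile epicardial inflow and drained by a distributed
capillary sink.

In the log-radial coordinate ``x = ln(r/r1)`` the governing equation used by
the analytical solutions is

    dp/dt = alpha * (p_xx + 3 p_x + p_thth) - delta * w(t),

with ``alpha = K1/(Ss1 r1^2)`` the radial diffusivity rate (1/s), ``delta``
the capillary sink rate (Pa/s) and ``w(t)`` the inflow waveform.  The radial
eigenfunctions are ``exp(-3x/2) sin(nu_m x / W)`` where the ``nu_m`` solve
``tan(nu) = 2 nu / (3 W)`` and ``W = ln(r2/r1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MMHG_PA",
    "GAMMA_BLOOD",
    "AnnulusGeometry",
    "TissueParams",
    "DriveParams",
    "StenosisSpec",
    "EigenSet",
    "make_geometry",
    "solve_eigenvalues",
    "delta_stress",
    "diffusivity",
]

#: Pascals per millimetre of mercury.
MMHG_PA = 133.322

#: Specific weight of blood, rho * g with rho = 1060 kg/m^3, g = 9.81 m/s^2.
GAMMA_BLOOD = 1060.0 * 9.81

#: Log-thickness at which the radial eigenproblem degenerates (the Robin
#: condition sprouts a hyperbolic mode and the trigonometric basis used by
#: the series solutions stops being complete).
W_PATHOLOGICAL = 2.0 / 3.0


class ValidationError(ValueError):
    """A physical parameter failed its invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class AnnulusGeometry:
    """Annular flow domain: endocardial radius ``r1`` and wall thickness ``s``.

    ``r2 = r1 + s`` and ``W = ln(r2/r1)`` are derived exactly.
    """

    r1: float
    s: float
    r2: float = field(init=False)
    W: float = field(init=False)

    def __post_init__(self) -> None:
        _require(self.r1 > 0, f"endocardial radius r1 must be > 0, got {self.r1}")
        _require(self.s > 0, f"wall thickness s must be > 0, got {self.s}")
        object.__setattr__(self, "r2", self.r1 + self.s)
        object.__setattr__(self, "W", math.log(self.r2 / self.r1))

    def x_of_r(self, r):
        """Log-radial coordinate ``x = ln(r/r1)`` of radius ``r``."""
        r = np.asarray(r, dtype=float)
        if np.any(r < self.r1 * (1 - 1e-12)) or np.any(r > self.r2 * (1 + 1e-12)):
            raise ValidationError(
                f"radius outside wall [{self.r1}, {self.r2}]: "
                f"[{np.min(r)}, {np.max(r)}]"
            )
        return np.log(np.clip(r, self.r1, self.r2) / self.r1)


def make_geometry(r1: float, s: float) -> AnnulusGeometry:
    """Build an :class:`AnnulusGeometry`, validating positivity."""
    return AnnulusGeometry(r1=float(r1), s=float(s))


@dataclass(frozen=True)
class TissueParams:
    """Constitutive constants of the equivalent porous myocardium.

    Parameters
    ----------
    K1 : float
        Hydraulic conductivity at the endocardium (m/s); ``K(r)=K1 (r/r1)^2``.
    Ss1 : float
        Specific storage (1/m), uniform across the wall.
    gamma : float
        Specific weight of blood (N/m^3).
    p_c : float
        Capillary reference pressure (Pa), added back for display in mmHg.
    """

    K1: float = 1e-10
    Ss1: float = 1e-3 / 0.3048
    gamma: float = GAMMA_BLOOD
    p_c: float = 20.0 * MMHG_PA

    def __post_init__(self) -> None:
        for name in ("K1", "Ss1", "gamma", "p_c"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    def alpha(self, geom: AnnulusGeometry) -> float:
        """Radial diffusivity rate ``alpha = K1/(Ss1 r1^2)`` (1/s)."""
        return self.K1 / (self.Ss1 * geom.r1**2)

    def K_at(self, r, geom: AnnulusGeometry):
        """Conductivity ``K(r) = K1 (r/r1)^2``."""
        return self.K1 * (np.asarray(r, dtype=float) / geom.r1) ** 2

    def K2(self, geom: AnnulusGeometry) -> float:
        """Conductivity at the epicardium."""
        return self.K1 * (geom.r2 / geom.r1) ** 2


def diffusivity(geom: AnnulusGeometry, tissue: TissueParams) -> float:
    """``alpha = K1/(Ss1 r1^2)`` (1/s)."""
    return tissue.alpha(geom)


@dataclass(frozen=True)
class DriveParams:
    """One perfusion scenario: inflow amplitude, sink rate and heart period.

    ``q0`` is the mid-diastole/mid-systole inflow rate per unit wall height
    (m^2/s); the pulsatile inflow is ``q0 * (1 - cos(2 pi t / T))``.
    ``delta`` is the capillary sink rate (Pa/s).
    """

    q0: float
    delta: float
    T: float

    def __post_init__(self) -> None:
        _require(self.q0 >= 0, "inflow amplitude q0 must be >= 0")
        _require(self.delta >= 0, "sink rate delta must be >= 0")
        _require(self.T > 0, "cardiac period T must be > 0")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi / self.T


@dataclass(frozen=True)
class StenosisSpec:
    """Sectorally reduced epicardial inflow.

    The sector ``[-theta_s/2, theta_s/2)`` receives inflow ``xi * q0``
    (``0 <= xi <= 1``; ``xi = 1`` encodes no stenosis).  ``t0`` is the phase
    of the cardiac cycle at which the occlusion forms.
    """

    theta_s: float
    xi: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        _require(0 <= self.theta_s <= 2 * math.pi + 1e-12,
                 f"sector angle must be in [0, 2pi], got {self.theta_s}")
        _require(0 <= self.xi <= 1, f"severity xi must be in [0, 1], got {self.xi}")
        _require(self.t0 >= 0, "onset phase t0 must be >= 0")

    def in_sector(self, theta):
        """Membership of the half-open underperfused sector (mod 2 pi)."""
        th = np.mod(np.asarray(theta, dtype=float) + math.pi, 2 * math.pi) - math.pi
        return (th >= -self.theta_s / 2) & (th < self.theta_s / 2)


@dataclass(frozen=True)
class EigenSet:
    """Radial eigenvalues ``nu_m`` of ``tan(nu) = 2 nu/(3W)`` on ``(0, inf)``.

    ``nu`` holds the ``M`` smallest strictly positive roots in increasing
    order.  For ``W < 2/3`` the first root lies in ``(0, pi/2)`` -- it is the
    fundamental (slowest-decaying) radial mode; subsequent roots occupy
    ``((m-1) pi, (m-1) pi + pi/2)``.
    """

    nu: np.ndarray
    W: float

    @property
    def M(self) -> int:
        return len(self.nu)

    @property
    def k(self) -> np.ndarray:
        """Radial wavenumbers ``k_m = nu_m / W`` in the log coordinate."""
        return self.nu / self.W

    @property
    def norms(self) -> np.ndarray:
        """Squared L2 norms ``int_0^W sin^2(k_m x) dx`` of the eigenfunctions
        under the natural weight ``exp(3x)``."""
        return self.W / 2 - np.sin(2 * self.nu) / (4 * self.k)

    def omega_decay(self, alpha: float, n: int = 0) -> np.ndarray:
        """Decay rates ``Omega_{m,n} = alpha (n^2 + k_m^2 + 9/4)``."""
        return alpha * (n * n + self.k**2 + 2.25)

    def residuals(self) -> np.ndarray:
        """Scaled eigencondition residuals
        ``|sin(nu) - (2/(3W)) nu cos(nu)| / (1 + (2/(3W)) nu)``.

        The raw tangent form is ill-conditioned near the branch asymptotes
        (its derivative grows like ``nu tan^2 nu``), so the certificate is
        stated for the equivalent scaled root function.
        """
        c = 2.0 / (3.0 * self.W)
        return np.abs(np.sin(self.nu) - c * self.nu * np.cos(self.nu)) / (
            1.0 + c * self.nu)


def solve_eigenvalues(W: float, M: int) -> EigenSet:
    """Return the ``M`` smallest positive roots of ``tan(nu) = 2 nu / (3W)``.

    Each root is bracketed inside its tangent branch and refined with Brent's
    method, then polished with Newton steps in extended precision.  Failure
    to bracket a root is a hard error.
    """
    if M < 1:
        raise ValidationError(f"M must be >= 1, got {M}")
    _require(W > 0, f"W must be > 0, got {W}")
    c = 2.0 / (3.0 * W)

    def g(nu: float) -> float:
        # scaled root function, monotone sign change per branch
        return math.sin(nu) - c * nu * math.cos(nu)

    roots: list[float] = []
    # branch 0 (0, pi/2) holds a nontrivial root iff the line slope c > 1
    branch = 0 if c > 1.0 else 1
    eps = 1e-9
    while len(roots) < M:
        lo = branch * math.pi + eps
        hi = branch * math.pi + math.pi / 2 - eps
        if g(lo) * g(hi) > 0:
            raise RuntimeError(
                f"failed to bracket eigenvalue in branch {branch} for W={W}")
        r = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
        roots.append(r)
        branch += 1
    nu = np.array(roots, dtype=np.longdouble)
    # Newton polish in extended precision on the scaled root function
    for _ in range(3):
        s_, co = np.sin(nu), np.cos(nu)
        f = s_ - c * nu * co
        fp = co - c * co + c * nu * s_
        nu = nu - f / fp
    return EigenSet(nu=nu.astype(float), W=float(W))


def delta_stress(delta_H: float, T_H: float, T: float, q0_H: float,
                 q0: float, spec: StenosisSpec | None = None) -> float:
    """Capillary sink rate under altered metabolic demand.

    The sink (oxygen consumption) is taken proportional to heart frequency
    ``1/T`` and to the circumferentially weighted inflow
    ``[(2 pi - theta_s) + xi theta_s] q0``:

        delta = delta_H * (T_H / (2 pi q0_H)) * [(2 pi - theta_s)
                + xi theta_s] * q0 / T

    With no stenosis this reduces to ``delta_H * (T_H/T) * (q0/q0_H)``.
    """
    for name, v in (("delta_H", delta_H), ("T_H", T_H), ("T", T), ("q0_H", q0_H)):
        _require(v > 0, f"{name} must be > 0")
    _require(q0 >= 0, "q0 must be >= 0")
    theta_s = spec.theta_s if spec is not None else 0.0
    xi = spec.xi if spec is not None else 1.0
    weight = (2 * math.pi - theta_s) + xi * theta_s
    return delta_H * (T_H / (2 * math.pi * q0_H)) * weight * q0 / T
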