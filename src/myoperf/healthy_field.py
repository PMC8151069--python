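"""Axisymmetric regime solution for healthy perfusion.

The healthy wall is fed uniformly around the epicardium by the pulsatile
inflow ``q_H(t) = q0 (1 - cos(2 pi t / T))``.  In the log-radial coordinate
``x = ln(r/r1)`` the transmural pressure solves

    dp/dt = alpha (p_xx + 3 p_x) - delta_H f(t),     f(t) = 1 - cos(w t)
    p(0, t) = 0,    p_x(W, t) = F0 f(t),             F0 = gamma q0/(2 pi K2)

The steady response to the cycle-mean drive is

    p*(x) = a x + c (1 - exp(-3x)),   a = delta/(3 alpha),
    c = (F0 - a) exp(3W) / 3,

and the regime (t -> infinity) solution is the quasi-steady part ``p* f(t)``
plus a harmonic eigenfunction series whose coefficients ``b_m`` are the
(negated) Sturm-Liouville projections of ``p*``.

Two evaluations are provided:

``mode="exact"``
    The regime solution of the PDE above (finite-difference verified).  At
    the reference tissue parameters the eigenmode response times far exceed
    the heart period, so this field is quasi-static: the series cancels most
    of the quasi-steady oscillation and ``p ~ p*`` throughout the cycle.
``mode="envelope"``
    The quasi-steady envelope ``p*(x) f(t)``: the steady response to the
    instantaneous inflow.  This is the evaluation used by the clinical
    calibration readouts (diastolic-peak pressure, systolic collapse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._series import int_exp_sin, int_xexp_sin
from .model_core import (
    AnnulusGeometry,
    DriveParams,
    EigenSet,
    TissueParams,
    ValidationError,
    W_PATHOLOGICAL,
    solve_eigenvalues,
)

__all__ = [
    "inflow_healthy",
    "HealthyCoefficients",
    "healthy_coefficients",
    "healthy_pressure",
    "healthy_flow",
    "HealthyField",
    "regime_diastolic_peak",
    "regime_systolic_peak",
]


def inflow_healthy(t, drive: DriveParams):
    """Pulsatile healthy inflow ``q0 (1 - cos(2 pi t/T))`` per unit height."""
    t = np.asarray(t, dtype=float)
    return drive.q0 * (1.0 - np.cos(drive.omega * t))


def regime_diastolic_peak(T: float, horizon: float = 7200.0) -> float:
    """First diastolic peak after ``horizon`` seconds: ``t = n T/2``, n odd.

    ``n = Int(horizon/(T/2)) + 1``; n is forced odd so the instant is a
    diastolic (inflow-maximum) peak rather than a systolic zero.
    """
    n = int(horizon / (T / 2)) + 1
    if n % 2 == 0:
        n += 1
    return n * T / 2


def regime_systolic_peak(T: float, horizon: float = 7200.0) -> float:
    """First systolic instant (``t = n T``, inflow zero) after ``horizon``."""
    return (int(horizon / T) + 1) * T


@dataclass(frozen=True)
class HealthyCoefficients:
    """Assembled series data for one healthy scenario."""

    geom: AnnulusGeometry
    tissue: TissueParams
    drive: DriveParams
    eigen: EigenSet
    a: float          # delta/(3 alpha), quasi-steady log slope (Pa)
    c: float          # cubic-mode amplitude (Pa)
    b: np.ndarray     # harmonic series coefficients (Pa)
    Omega: np.ndarray  # modal decay rates (1/s)

    @property
    def F0(self) -> float:
        """Neumann datum amplitude ``gamma q0 / (2 pi K2)`` (Pa)."""
        return (self.tissue.gamma * self.drive.q0
                / (2 * math.pi * self.tissue.K2(self.geom)))

    def pstar(self, x):
        """Steady profile ``a x + c (1 - exp(-3x))`` (Pa)."""
        x = np.asarray(x, dtype=float)
        return self.a * x + self.c * (1.0 - np.exp(-3.0 * x))

    def dpstar_dx(self, x):
        x = np.asarray(x, dtype=float)
        return self.a + 3.0 * self.c * np.exp(-3.0 * x)


def healthy_coefficients(geom: AnnulusGeometry, tissue: TissueParams,
                         drive: DriveParams,
                         eigen: EigenSet | None = None,
                         M: int = 50) -> HealthyCoefficients:
    """Project the steady profile onto the radial eigenbasis.

    ``b_m = -<p*, phi_m> / N_m`` with weight ``exp(3x)``,
    ``phi_m = exp(-3x/2) sin(k_m x)``; all integrals in closed form.
    """
    if geom.W >= W_PATHOLOGICAL:
        raise ValidationError(
            f"pathological geometry: W = ln(r2/r1) = {geom.W:.4f} >= 2/3; "
            "the radial eigenbasis degenerates for such thick annuli")
    if eigen is None:
        eigen = solve_eigenvalues(geom.W, M)
    alpha = tissue.alpha(geom)
    F0 = tissue.gamma * drive.q0 / (2 * math.pi * tissue.K2(geom))
    a = drive.delta / (3.0 * alpha)
    c = (F0 - a) * math.exp(3.0 * geom.W) / 3.0
    k = eigen.k
    W = geom.W
    proj = (a * int_xexp_sin(1.5, k, W)
            + c * (int_exp_sin(1.5, k, W) - int_exp_sin(-1.5, k, W)))
    b = -proj / eigen.norms
    Omega = eigen.omega_decay(alpha)
    return HealthyCoefficients(geom=geom, tissue=tissue, drive=drive,
                               eigen=eigen, a=a, c=c, b=b, Omega=Omega)


def _harmonic_response(coeffs: HealthyCoefficients, t: float, M: int,
                       regime: bool) -> np.ndarray:
    """Per-mode Duhamel response ``int_0^t exp(-Omega (t-s)) f'(s) ds``."""
    om = coeffs.drive.omega
    Om = coeffs.Omega[:M]
    denom = Om * Om + om * om
    resp = om * (Om * np.sin(om * t) - om * np.cos(om * t)) / denom
    if not regime:
        resp = resp + om * om * np.exp(-Om * t) / denom
    return resp


def _check_args(coeffs: HealthyCoefficients, M: int | None) -> int:
    Mmax = coeffs.eigen.M
    if M is None:
        return Mmax
    if not 1 <= M <= Mmax:
        raise ValidationError(f"M must be in [1, {Mmax}], got {M}")
    return M


def healthy_pressure(r, t: float, coeffs: HealthyCoefficients,
                     M: int | None = None, mode: str = "exact",
                     regime: bool = True):
    """Transmural pressure (Pa, above ``p_c``) at radius ``r`` and time ``t``.

    ``mode="exact"`` evaluates the regime series solution (set
    ``regime=False`` to retain the start-up transients from a no-flow initial
    state); ``mode="envelope"`` evaluates the quasi-steady envelope
    ``p*(x) f(t)``.
    """
    M = _check_args(coeffs, M)
    x = coeffs.geom.x_of_r(r)
    f = 1.0 - math.cos(coeffs.drive.omega * t)
    qs = coeffs.pstar(x) * f
    if mode == "envelope":
        return qs
    if mode != "exact":
        raise ValidationError(f"unknown mode {mode!r}")
    k = coeffs.eigen.k[:M]
    resp = _harmonic_response(coeffs, t, M, regime)
    xcol = np.atleast_1d(x)[..., None]
    ser = (np.exp(-1.5 * xcol) * np.sin(xcol * k)) @ (coeffs.b[:M] * resp)
    out = qs + ser.reshape(np.shape(x))
    return out if np.ndim(r) else float(out)


def healthy_pressure_gradient_x(r, t: float, coeffs: HealthyCoefficients,
                                M: int | None = None, mode: str = "exact",
                                regime: bool = True):
    """``dp/dx`` (Pa), analytic term-by-term derivative."""
    M = _check_args(coeffs, M)
    x = coeffs.geom.x_of_r(r)
    f = 1.0 - math.cos(coeffs.drive.omega * t)
    dqs = coeffs.dpstar_dx(x) * f
    if mode == "envelope":
        return dqs
    k = coeffs.eigen.k[:M]
    resp = _harmonic_response(coeffs, t, M, regime)
    xcol = np.atleast_1d(x)[..., None]
    dphi = np.exp(-1.5 * xcol) * (-1.5 * np.sin(xcol * k) + k * np.cos(xcol * k))
    ser = dphi @ (coeffs.b[:M] * resp)
    out = dqs + ser.reshape(np.shape(x))
    return out if np.ndim(r) else float(out)


def healthy_flow(r, t: float, coeffs: HealthyCoefficients,
                 M: int | None = None, mode: str = "exact",
                 regime: bool = True):
    """Signed radial Darcy flow rate ``U_r = -(K(r)/gamma) dp/dr`` (m/s).

    Negative values point toward the endocardium (the physiological
    direction of arterial perfusion in this model).
    """
    r_arr = np.asarray(r, dtype=float)
    dpdx = healthy_pressure_gradient_x(r, t, coeffs, M, mode, regime)
    K = coeffs.tissue.K_at(r_arr, coeffs.geom)
    out = -(K / coeffs.tissue.gamma) * dpdx / r_arr
    return out if np.ndim(r) else float(out)


class HealthyField:
    """Samplable healthy perfusion field.

    Thin object wrapper over :func:`healthy_pressure` / :func:`healthy_flow`
    with the uniform (r, theta, t) sampling interface shared with the
    stenotic field.
    """

    def __init__(self, geom: AnnulusGeometry, tissue: TissueParams,
                 drive: DriveParams, M: int = 50, mode: str = "exact",
                 regime: bool = True):
        self.coeffs = healthy_coefficients(geom, tissue, drive, M=M)
        self.geom = geom
        self.tissue = tissue
        self.drive = drive
        self.mode = mode
        self.regime = regime

    @property
    def t_diastolic_peak(self) -> float:
        return regime_diastolic_peak(self.drive.T)

    @property
    def t_systolic_peak(self) -> float:
        return regime_systolic_peak(self.drive.T)

    def pressure(self, r, t: float, theta=None):
        del theta  # axisymmetric
        return healthy_pressure(r, t, self.coeffs, mode=self.mode,
                                regime=self.regime)

    def flow(self, r, t: float, theta=None):
        """(U_r, U_theta, |U|); U_theta is identically zero."""
        del theta
        ur = healthy_flow(r, t, self.coeffs, mode=self.mode,
                          regime=self.regime)
        return ur, np.zeros_like(np.asarray(ur)), np.abs(ur)

    def flow_magnitude(self, r, theta, t: float):
        """|U| on a broadcastable (r, theta) grid; theta only sets shape."""
        r_b, _ = np.broadcast_arrays(np.asarray(r, dtype=float),
                                     np.asarray(theta, dtype=float))
        return np.abs(healthy_flow(r_b, t, self.coeffs, mode=self.mode,
                                   regime=self.regime))

    def sample_rt(self, r_values, t_values, what: str = "pressure"):
        """Rectangular (r, t) array of pressure (Pa) or |U| (m/s)."""
        out = np.empty((len(r_values), len(t_values)))
        for j, t in enumerate(t_values):
            if what == "pressure":
                out[:, j] = self.pressure(np.asarray(r_values), t)
            elif what == "flow":
                out[:, j] = self.flow(np.asarray(r_values), t)[2]
            else:
                raise ValidationError(f"unknown quantity {what!r}")
        return out
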