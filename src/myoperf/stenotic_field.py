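"""Non-axisymmetric solution for sectorally reduced coronary inflow.

An epicardial stenosis starves the sector ``[-theta_s/2, theta_s/2)`` of the
wall, which receives inflow ``xi q0 h(t)`` instead of ``q0 h(t)``, with
``h(t) = 1 - cos(2 pi (t + t0)/T)`` carrying the onset phase ``t0``.  In
log-radial coordinates the pressure solves

    dp/dt = alpha (p_xx + 3 p_x + p_thth) - delta h(t)
    p(0, th, t) = 0
    p_x(W, th, t) = F(th) h(t)          F(th) = gamma q_s(th) / (2 pi K2)
    p(x, th, 0)  = p_H(x, t0)           (healthy field at onset)

with homogeneous angular Neumann conditions at th = 0, pi (the solution is
even in th about the sector axis, hence the cos(n th) basis).

Construction: the epicardial datum is expanded in angular harmonics
``F = Fbar + sum_n F_n cos(n th)``; for each harmonic an exact steady
lifting is built (the axisymmetric ``a x + c0 (1-exp(-3x))`` profile for
n = 0 and ``A_n exp(-3x/2) sinh(eta_n x)`` with ``eta_n = sqrt(n^2 + 9/4)``
for n >= 1), and the remainder is expanded over the radial eigenfunctions
``phi_m = exp(-3x/2) sin(k_m x)``.  Duhamel's principle gives each modal
amplitude in closed form, including the healthy-history initial condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._series import int_exp_sin, int_sinh_sin_scaled, int_xexp_sin
from .model_core import (
    AnnulusGeometry,
    DriveParams,
    EigenSet,
    StenosisSpec,
    TissueParams,
    ValidationError,
    W_PATHOLOGICAL,
    solve_eigenvalues,
)
from .healthy_field import HealthyCoefficients, healthy_coefficients

__all__ = [
    "inflow_stenotic",
    "StenoticCoefficients",
    "stenotic_coefficients",
    "stenotic_pressure",
    "stenotic_flow",
    "StenoticField",
]

_CHUNK = 1 << 16  # evaluation chunk, keeps basis matrices ~tens of MB


def inflow_stenotic(theta, t, drive: DriveParams, spec: StenosisSpec):
    """Sector inflow rate ``q_s(theta, t)`` per unit height (m^2/s).

    ``xi q0 h(t)`` inside the half-open sector ``[-theta_s/2, theta_s/2)``,
    ``q0 h(t)`` elsewhere, ``h(t) = 1 - cos(2 pi (t + t0)/T)``.
    """
    h = 1.0 - np.cos(drive.omega * (np.asarray(t, dtype=float) + spec.t0))
    base = np.where(spec.in_sector(theta), spec.xi * drive.q0, drive.q0)
    return base * h


@dataclass(frozen=True)
class StenoticCoefficients:
    """Assembled modal data for one stenotic scenario.

    ``smn[:, 0]`` are the projections of the axisymmetric lifting onto the
    radial eigenfunctions, ``smn[:, n]`` those of the n-th angular harmonic;
    the series coefficients of the printed classical solution correspond to
    ``Bm = -smn[:, 0] (+ initial-condition terms)`` and ``Bmn = -smn[:, n]``.
    """

    geom: AnnulusGeometry
    tissue: TissueParams
    drive: DriveParams          # stenotic drive (q0, delta, T)
    spec: StenosisSpec
    eigen: EigenSet
    healthy: HealthyCoefficients  # pre-onset history (drive_H)
    N: int                      # angular truncation
    a: float                    # delta/(3 alpha) (Pa)
    c0: float                   # axisymmetric cubic-mode amplitude (Pa)
    Fbar: float                 # mean Neumann datum (Pa)
    Fn: np.ndarray              # angular harmonic data (Pa), n = 1..N
    eta: np.ndarray             # sqrt(n^2 + 9/4)
    lift_den: np.ndarray        # stable sinh-mode denominators
    smn: np.ndarray             # (M, N+1) lifting projections (Pa)
    ic_proj: np.ndarray         # (M,) healthy-history projections (Pa)
    Omega: np.ndarray           # (M, N+1) decay rates (1/s)

    @property
    def M(self) -> int:
        return self.eigen.M

    @property
    def h0(self) -> float:
        """Inflow waveform at onset, ``h(0) = 1 - cos(2 pi t0 / T)``."""
        return 1.0 - math.cos(self.drive.omega * self.spec.t0)

    # ---- steady lifting S(x, theta) -------------------------------------
    def _sn_radial(self, x):
        """Radial profiles of the angular harmonics, shape (*x.shape, N)."""
        W = self.geom.W
        xc = np.asarray(x, dtype=float)[..., None]
        e1 = np.exp(-self.eta * (W - xc))
        e2 = np.exp(-self.eta * (W + xc))
        pref = self.Fn * math.exp(1.5 * W) / self.lift_den
        return np.exp(-1.5 * xc) * (e1 - e2) * pref

    def _dsn_radial(self, x):
        W = self.geom.W
        xc = np.asarray(x, dtype=float)[..., None]
        e1 = np.exp(-self.eta * (W - xc))
        e2 = np.exp(-self.eta * (W + xc))
        pref = self.Fn * math.exp(1.5 * W) / self.lift_den
        return np.exp(-1.5 * xc) * (-1.5 * (e1 - e2)
                                    + self.eta * (e1 + e2)) * pref

    def s0_profile(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * x + self.c0 * (1.0 - np.exp(-3.0 * x))

    def ds0_profile(self, x):
        x = np.asarray(x, dtype=float)
        return self.a + 3.0 * self.c0 * np.exp(-3.0 * x)


def stenotic_coefficients(geom: AnnulusGeometry, tissue: TissueParams,
                          drive_healthy: DriveParams,
                          drive_sten: DriveParams, spec: StenosisSpec,
                          eigen: EigenSet | None = None,
                          N: int = 50, M: int = 50) -> StenoticCoefficients:
    """Assemble the modal expansion of the stenotic boundary-value problem."""
    if N < 1 or M < 1:
        raise ValidationError("truncation orders N, M must be >= 1")
    if abs(geom.W - W_PATHOLOGICAL) < 1e-9 or geom.W >= W_PATHOLOGICAL:
        raise ValidationError(
            f"pathological geometry: W = ln(r2/r1) = {geom.W:.4f} >= 2/3")
    if eigen is None:
        eigen = solve_eigenvalues(geom.W, M)
    healthy = healthy_coefficients(geom, tissue, drive_healthy, eigen=eigen)

    alpha = tissue.alpha(geom)
    K2 = tissue.K2(geom)
    W = geom.W
    k = eigen.k
    q0, qp = drive_sten.q0, spec.xi * drive_sten.q0
    qbar = q0 - (q0 - qp) * spec.theta_s / (2 * math.pi)
    Fbar = tissue.gamma * qbar / (2 * math.pi * K2)
    n = np.arange(1, N + 1, dtype=float)
    Fn = tissue.gamma * (qp - q0) * np.sin(n * spec.theta_s / 2) / (
        n * math.pi**2 * K2)

    a = drive_sten.delta / (3.0 * alpha)
    c0 = (Fbar - a) * math.exp(3.0 * W) / 3.0
    eta = np.sqrt(n * n + 2.25)
    lift_den = (eta - 1.5) + (eta + 1.5) * np.exp(-2.0 * eta * W)

    # projections of the liftings onto the radial eigenfunctions
    norms = eigen.norms
    s0 = (a * int_xexp_sin(1.5, k, W)
          + c0 * (int_exp_sin(1.5, k, W) - int_exp_sin(-1.5, k, W))) / norms
    # <A_n sinh(eta x), sin(k x)>: stable via tanh form
    pref = Fn * math.exp(1.5 * W) / lift_den        # amplitude of e^{-eta W} pair
    # A_n sinh(eta x) = pref * (e^{-eta(W-x)} - e^{-eta(W+x)})/1; its plain
    # integral against sin equals pref * 2 e^{-eta W} * J_cosh with
    # J_cosh = int sinh sin / cosh(eta W):
    # sinh(eta x) = cosh(eta W) * [sinh/cosh]; combine stably:
    jc = int_sinh_sin_scaled(eta, k, W)             # (M, N)
    amp = pref * (1.0 + np.exp(-2.0 * eta * W))     # = A_n cosh(eta W)
    sn = (amp * jc) / norms[:, None]
    smn = np.concatenate([s0[:, None], sn], axis=1)

    # healthy-history projections: p_H(x, t0) expanded over phi_m
    omH = drive_healthy.omega
    OmH = healthy.Omega
    fH = 1.0 - math.cos(omH * spec.t0)
    respH = omH * (OmH * np.sin(omH * spec.t0)
                   - omH * np.cos(omH * spec.t0)) / (OmH**2 + omH**2)
    ic_proj = healthy.b * (respH - fH)

    Omega = alpha * (np.concatenate([[0.0], n])[None, :] ** 2
                     + k[:, None] ** 2 + 2.25)
    return StenoticCoefficients(
        geom=geom, tissue=tissue, drive=drive_sten, spec=spec, eigen=eigen,
        healthy=healthy, N=N, a=a, c0=c0, Fbar=Fbar, Fn=Fn, eta=eta,
        lift_den=lift_den, smn=smn, ic_proj=ic_proj, Omega=Omega)


def _duhamel(coeffs: StenoticCoefficients, t: float, M: int, N: int,
             regime: bool) -> np.ndarray:
    """Modal amplitudes v_{m,n}(t) of the eigenfunction series, (M, N+1)."""
    om = coeffs.drive.omega
    t0 = coeffs.spec.t0
    Om = coeffs.Omega[:M, :N + 1]
    den = Om * Om + om * om

    def G(u):
        return om * (Om * math.sin(om * u) - om * math.cos(om * u)) / den

    s = coeffs.smn[:M, :N + 1]
    v = -s * G(t + t0)
    if not regime:
        decay = np.exp(-Om * t)
        gamma_tr = -decay * G(t0)
        v = v - s * gamma_tr
        ic = -s * coeffs.h0
        ic[:, 0] += coeffs.ic_proj[:M]
        v = v + ic * decay
    return v


def _check_mn(coeffs: StenoticCoefficients, M, N):
    M = coeffs.M if M is None else M
    N = coeffs.N if N is None else N
    if not 1 <= M <= coeffs.M:
        raise ValidationError(f"M must be in [1, {coeffs.M}]")
    if not 0 <= N <= coeffs.N:
        raise ValidationError(f"N must be in [0, {coeffs.N}]")
    return M, N


def _eval_field(coeffs: StenoticCoefficients, r, theta, t, M, N, mode,
                regime, kind):
    """Shared evaluator; kind in {'p', 'dx', 'dth'}."""
    M, N = _check_mn(coeffs, M, N)
    h = 1.0 - math.cos(coeffs.drive.omega * (t + coeffs.spec.t0))
    r_b, th_b = np.broadcast_arrays(np.asarray(r, dtype=float),
                                    np.asarray(theta, dtype=float))
    shape = r_b.shape
    x = coeffs.geom.x_of_r(r_b).ravel()
    # fold theta to [-pi, pi); the field is even so cos(n th) is unaffected
    th = th_b.ravel()
    out = np.empty(x.size)
    if mode == "envelope":
        v = None
    elif mode == "exact":
        v = _duhamel(coeffs, t, M, N, regime)  # (M, N+1)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    k = coeffs.eigen.k[:M]
    nn = np.arange(0, N + 1, dtype=float)
    for lo in range(0, x.size, _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        xs, ths = x[sl], th[sl]
        xc = xs[:, None]
        if kind == "dth":
            prof = np.zeros((xs.size, N + 1))
            if N >= 1:
                prof[:, 1:] = coeffs._sn_radial(xs)[:, :N] * h
            if v is not None:
                phi = np.exp(-1.5 * xc) * np.sin(xc * k)
                prof += phi @ v
            ang = -np.sin(ths[:, None] * nn) * nn
            out[sl] = np.einsum("ij,ij->i", prof, ang)
            continue
        if kind == "p":
            prof0 = coeffs.s0_profile(xs) * h
            profn = coeffs._sn_radial(xs)[:, :N] * h if N >= 1 else None
            basis = lambda: np.exp(-1.5 * xc) * np.sin(xc * k)  # noqa: E731
        else:  # 'dx'
            prof0 = coeffs.ds0_profile(xs) * h
            profn = coeffs._dsn_radial(xs)[:, :N] * h if N >= 1 else None
            basis = lambda: np.exp(-1.5 * xc) * (  # noqa: E731
                -1.5 * np.sin(xc * k) + k * np.cos(xc * k))
        prof = np.zeros((xs.size, N + 1))
        prof[:, 0] = prof0
        if profn is not None:
            prof[:, 1:] += profn
        if v is not None:
            prof += basis() @ v
        ang = np.cos(ths[:, None] * nn)
        out[sl] = np.einsum("ij,ij->i", prof, ang)
    out = out.reshape(shape)
    return out if shape else float(out)


def stenotic_pressure(r, theta, t: float, coeffs: StenoticCoefficients,
                      M: int | None = None, N: int | None = None,
                      mode: str = "exact", regime: bool = True):
    """Transmural pressure (Pa above p_c); symmetric in theta about the
    sector axis.  ``regime=False`` retains onset transients and the healthy
    initial condition."""
    return _eval_field(coeffs, r, theta, t, M, N, mode, regime, "p")


def stenotic_flow(r, theta, t: float, coeffs: StenoticCoefficients,
                  M: int | None = None, N: int | None = None,
                  mode: str = "exact", regime: bool = True):
    """Darcy flow components ``(U_r, U_theta, |U|)`` in m/s.

    ``U_r = -(K/gamma) dp/dr``, ``U_theta = -(K/(gamma r)) dp/dtheta``; both
    derivatives are analytic term-by-term.
    """
    r_b = np.broadcast_arrays(np.asarray(r, dtype=float),
                              np.asarray(theta, dtype=float))[0]
    dpdx = _eval_field(coeffs, r, theta, t, M, N, mode, regime, "dx")
    dpdth = _eval_field(coeffs, r, theta, t, M, N, mode, regime, "dth")
    K = coeffs.tissue.K_at(r_b, coeffs.geom)
    g = coeffs.tissue.gamma
    ur = -(K / g) * dpdx / r_b
    ut = -(K / g) * dpdth / r_b
    return ur, ut, np.hypot(ur, ut)


class StenoticField:
    """Samplable stenotic perfusion field (same interface as HealthyField)."""

    def __init__(self, geom: AnnulusGeometry, tissue: TissueParams,
                 drive_healthy: DriveParams, drive_sten: DriveParams,
                 spec: StenosisSpec, M: int = 50, N: int = 50,
                 mode: str = "exact", regime: bool = True):
        self.coeffs = stenotic_coefficients(geom, tissue, drive_healthy,
                                            drive_sten, spec, N=N, M=M)
        self.geom = geom
        self.tissue = tissue
        self.drive = drive_sten
        self.spec = spec
        self.mode = mode
        self.regime = regime

    @property
    def t_diastolic_peak(self) -> float:
        from .healthy_field import regime_diastolic_peak
        return regime_diastolic_peak(self.drive.T)

    def pressure(self, r, t: float, theta=0.0):
        return stenotic_pressure(r, theta, t, self.coeffs, mode=self.mode,
                                 regime=self.regime)

    def flow(self, r, t: float, theta=0.0):
        return stenotic_flow(r, theta, t, self.coeffs, mode=self.mode,
                             regime=self.regime)

    def flow_magnitude(self, r, theta, t: float):
        return self.flow(r, t, theta)[2]
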