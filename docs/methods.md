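# Methods

## Model and assumptions

The left-ventricle wall is idealised as a unit-height, structurally
homogeneous short-axis slice: a saturated porous annulus `r1 ≤ r ≤ r2`,
`r2 = r1 + s`, perfused by the arterial side of the coronary tree.  The
solid phase (myocardial fibres and vessel walls) and the blood share the
load in the sense of consolidation theory: the total vertical stress splits
into the fibre stress and the transmural blood pressure `p`, referenced to
the capillary pressure `p_c` so that `p = 0` marks the arterial/venous
limit of the capillaries.  Physical ingredients:

* **Conductivity** `K(r) = K1 (r/r1)²` — vessel calibre grows linearly with
  radius along the tree, and conductivity with its square.
* **Specific storage** `Ss` — uniform; encodes the elastic rearrangement of
  blood-filled vessel volume over the cycle (diastolic swelling / systolic
  drainage).
* **Capillary sink** — the blood leaving the arterial network through the
  capillaries, modelled as a uniform sink of rate `δ` (Pa/s), modulated by
  the same waveform as the inflow (sink, storage and conductivity all scale
  with the instantaneous vascular porosity, so their ratios are constants).
* **Drive** — a single-harmonic coronary inflow per unit height,
  `q(t) = q0 (1 − cos 2πt/T)`, distributed over the epicardial circle; a
  stenosis scales it by `ξ ∈ [0, 1]` over the sector `|θ| < Θs/2`.

Ventricle torsion, wall-thickness variation, longitudinal flow, collateral
circuits, the venous network and post-necrosis property changes are outside
the model.

In the log-radial coordinate `x = ln(r/r1)`, `W = ln(r2/r1)`:

    ∂p/∂t = α (p_xx + 3 p_x + p_θθ) − δ w(t),      α = K1/(Ss1 r1²)
    p(0, θ, t) = 0
    p_x(W, θ, t) = γ q(θ, t) / (2π K2)             K2 = K(r2)

This operator (conservative form `(1/r²)∂r(α r⁴ ∂r p)`) is the one whose
exact solution carries the `(r1/r)^{3/2}` radial envelope, the decay rates
`Ω = α(n² + ν²/W² + 9/4)` and the eigencondition `tan ν = 2ν/(3W)` used
throughout; the finite-difference oracle discretises the same form, and the
two agree to better than 1%.

## Solution structure

* **Eigenbasis.** `φ_m(x) = e^{−3x/2} sin(ν_m x/W)` with `tan ν = 2ν/(3W)`.
  For `W < 2/3` the slope `2/(3W) > 1` and the *first* root lies in
  `(0, π/2)`; it is the fundamental (slowest) mode and must be kept — the
  basis is incomplete without it.  Subsequent roots occupy
  `((m−1)π, (m−1)π + π/2)`.  At `W ≥ 2/3` a hyperbolic mode replaces it and
  the coefficient constructors refuse the geometry as pathological (the
  physiological wall has `W ≈ 0.3`).
* **Healthy field.** Steady profile `p*(x) = a x + c(1 − e^{−3x})`,
  `a = δ/(3α)`, `c = (F0 − a)e^{3W}/3`, `F0 = γq0/(2πK2)`; series
  coefficients are the negated projections `b_m = −⟨p*, φ_m⟩/‖φ_m‖²`
  (weight `e^{3x}`, exact norms `W/2 − sin 2ν/(4k)`), with closed-form
  integrals; the regime time dependence is the first-order harmonic
  response of each mode.
* **Stenotic field.** The epicardial datum is expanded in `cos nθ`; each
  harmonic gets an exact steady lifting — `A_n e^{−3x/2} sinh(η_n x)` with
  `η_n = √(n² + 9/4)` — and the remainder evolves by Duhamel kernels.  The
  healthy pre-stenotic state at the onset phase `t0` supplies the initial
  condition through its own modal projections, so the full (non-regime)
  evaluation reproduces the healthy field at `t = 0` to truncation accuracy.
  `sinh`/`cosh` combinations are evaluated through `tanh`-saturated forms,
  stable to arbitrary `n·W`.

Truncation defaults are M = 50 radial and N = 50 angular modes,
independently configurable; mid-wall pressure changes by about 5×10⁻⁶
(relative) between M = 50 and M = 200.

## Time scales, and the two evaluation modes

With the reference tissue constants (`K1 = 1e-10 m/s`,
`Ss1 = 1e-3/0.3048 m⁻¹` — water-saturated fine-grained media, matching the
5–10 µm capillary scale), the fundamental decay time `1/Ω₁` is ~15 minutes:
hours to reach regime (hence the regime evaluation instant
`t_dp = nT/2`, `n = Int(7200/(T/2)) + 1`, forced odd so the instant is a
diastolic inflow peak), and much slower than the ~1 s heart period.  The
exact regime field is therefore **quasi-static**: the bulk pressure hovers
near the steady response to the cycle-mean drive, and only a thin
epicardial boundary layer follows the pulsation.

The clinical comparisons, by contrast, are phrased in terms of pulsatile
quantities — a diastolic peak pressure of 112–155 mmHg, a systolic collapse
to ≈0.  These readouts correspond to the **quasi-steady envelope**
`p*(r)·w(t)`: the steady response to the instantaneous inflow, i.e. the
fast-diffusion limit of the same model.  The package exposes both modes on
every field object.  All protocol readouts (calibration windows, TPR
tables, exported maps) use the envelope mode; PDE-fidelity checks
(finite-difference agreement, boundary conditions, initial-condition
coupling) use the exact mode.  TPR itself is nearly mode-independent, since
both modes share the steady radial profile and TPR is a ratio.

## TPR protocol

Three concentric layers of equal thickness (configurable fractions) split
the wall; TPR = area-weighted mean `|U|` over the subendocardial layer
(restricted to the territory sector for a stenotic run) divided by the mean
over the entire subepicardial ring, midpoint quadrature on a 201×720 polar
grid (envelope readout converges to ~1e-7 under grid doubling).  Territory
sectors: LAD 180°, RCA 108°, CX 72°; severe-disease aggregates use cohort
weights 23/17/9 for the rest/stress protocol and a plain mean for the
stress-CTP protocol.

Stress (adenosine hyperemia) shortens the period (`T/TH = 0.8055`) and
rescales the sink in proportion to heart frequency and circumferentially
weighted inflow:

    δ = δH · (TH / 2π q0H) · [(2π − Θs) + ξ Θs] · q0 / T .

## Calibration

Each clinical protocol fixes `q0H`, `δH`, `TH` (rest/stress MDCT:
2.5e-9 m²/s, 3.0 Pa/s, 60/58 s, windows at rest; stress CTP: 2.7e-9 m²/s,
2.5 Pa/s, windows under stress) and leaves the endocardial radius free in
20–30 mm.  `calibrate()` scans r1, requires the envelope diastolic-peak
epicardial pressure `p2 + p_c` and the healthy TPR to fall inside the
protocol windows, refines the feasibility edge by bisection, and returns
the smallest feasible radius.  The selection rule realises the model's
physiological account — subendocardial flow dominance (healthy TPR > 1),
which strengthens monotonically as the cavity shrinks — and pins the
healthy TPR at the top of the clinical band.  Blood specific weight is
`γ = ρg` with ρ = 1060 kg/m³; `p_c = 20 mmHg`.

## Severity curve and threshold

`ξ(sten)` — the residual-inflow fraction as a function of % diameter
stenosis — follows relative coronary flow reserve.  Lacking a tabulated
curve, the default map is piecewise-linear through (0, 1.0), (50, 0.90),
(80, 0.55), (100, 0.0), anchored at the published point ξ(80%) = 0.55; it
is a documented stand-in, and every stenotic-band number inherits it.
`tpr_curve` evaluates the territory-averaged stress TPR over a severity
grid, `fit_quartic` fits a quartic by least squares, and
`threshold_stenosis` brackets the smallest crossing of a TPR threshold on
[0, 100]%.  The package also carries a reference quartic for the average
stress curve whose TPR = 0.99 crossing sits at 75.7% stenosis; its linear
coefficient is stored with the sign that makes the polynomial consistent
with the published severity-band values and threshold.

## Verification

* Eigenvalues: bracketed Brent per tangent branch, Newton-polished in
  extended precision; certified by the scaled residual
  `|sin ν − (2/(3W))ν cos ν|/(1 + (2/(3W))ν) < 1e-12` (the raw tangent form
  is ill-conditioned near the branch asymptotes), and cross-checked against
  a dense-scan bisection oracle.
* Series coefficients: closed-form projection integrals verified against
  adaptive quadrature.
* Fields: endocardial Dirichlet and epicardial Neumann data are satisfied
  analytically; mirror symmetry and the angular Neumann conditions hold by
  construction; the ξ = 1 stenotic solution collapses onto the healthy one
  to machine precision.
* Dynamics: a conservative-form Crank–Nicolson solver (log-radial
  finite-volume faces, trapezoidal stepping, per-step flux balance at
  machine precision) reproduces the series within 1% L∞ — from the no-flow
  start to regime for the healthy problem, and from the healthy-history
  initial condition through the onset transient for the stenotic one; a
  rescaled-conductivity variant exercises the full start-up-to-regime path
  in seconds, and grid refinement confirms second-order convergence.

## Known limitations

* The quasi-static/envelope duality above is intrinsic to the calibrated
  diffusivity: the exact dynamics cannot produce the pulsatile clinical
  pressures, and the envelope is not a solution of the dynamic equation.
  Conclusions that depend on intra-cycle pressure dynamics should use the
  exact mode and treat the clinical-window calibration as a quasi-steady
  convention.
* Computed stress and severe-stenosis TPRs sit below the published clinical
  averages: the frequency-rescaled sink and the exact sector modes (whose
  subendocardial flow deficit exceeds the imposed epicardial one by a
  factor ≈ 2.3) depress the ratio more strongly than the published severity
  curve suggests.  The orderings — rest above stress, TPR falling with
  severity, subendocardial vulnerability — are all reproduced.
* The `ξ(sten)` map is a stand-in; band-level comparisons inherit it.
* Single sector, 2-D slice, no collaterals, prenecrosis regime only.
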