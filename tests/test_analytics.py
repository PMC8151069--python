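import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myoperf as mp
from myoperf.hemodynamic_analytics import StressScenario, _readouts


class _SyntheticField:
    """Stand-in sampler with a prescribed |U|(r, theta) (synthetic, for
    quadrature tests only)."""

    def __init__(self, geom, fn):
        self.geom = geom
        self.fn = fn
        self.t_diastolic_peak = 0.0

    def flow_magnitude(self, r, theta, t):
        r, theta = np.broadcast_arrays(np.asarray(r), np.asarray(theta))
        return self.fn(r, theta)


class TestComputeTPR:
    def test_uniform_field_gives_unity(self, ref_geom):
        fld = _SyntheticField(ref_geom, lambda r, th: np.full_like(r, 3.3e-9))
        rep = mp.compute_tpr(fld, nr=64, ntheta=16)
        assert rep.tpr == pytest.approx(1.0, rel=1e-12)

    def test_quadrature_self_convergence(self, ref_geom, tissue, drive_rest,
                                         healthy_field):
        env = mp.HealthyField(ref_geom, tissue, drive_rest, mode="envelope")
        t = env.t_diastolic_peak
        r1 = mp.compute_tpr(env, t=t, nr=201, ntheta=4).tpr
        r2 = mp.compute_tpr(env, t=t, nr=402, ntheta=8).tpr
        assert abs(r2 - r1) < 1e-4
        # the exact-mode field carries thin oscillatory boundary layers, so
        # its quadrature converges more slowly but still below 3e-4
        e1 = mp.compute_tpr(healthy_field, t=t, nr=201, ntheta=4).tpr
        e2 = mp.compute_tpr(healthy_field, t=t, nr=402, ntheta=8).tpr
        assert abs(e2 - e1) < 3e-4

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_global_rescaling(self, ref_geom, scale):
        rng = np.random.default_rng(7)
        coef = rng.uniform(0.5, 1.5, size=4)

        def fn(r, th):
            u = coef[0] + coef[1] * (r - ref_geom.r1) / ref_geom.s \
                + coef[2] * np.cos(th) ** 2 + coef[3] * np.sin(3 * th) ** 2
            return np.abs(u)

        f1 = _SyntheticField(ref_geom, fn)
        f2 = _SyntheticField(ref_geom, lambda r, th: scale * fn(r, th))
        t1 = mp.compute_tpr(f1, nr=64, ntheta=32).tpr
        t2 = mp.compute_tpr(f2, nr=64, ntheta=32).tpr
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_zero_field_is_error(self, ref_geom):
        fld = _SyntheticField(ref_geom, lambda r, th: np.zeros_like(r))
        with pytest.raises(mp.ValidationError, match="degenerate"):
            mp.compute_tpr(fld, nr=16, ntheta=8)

    def test_bad_layer_fractions_rejected(self, ref_geom):
        with pytest.raises(mp.ValidationError):
            mp.LayerDecomposition(ref_geom, fractions=(0.5, 0.6, -0.1))


class TestTerritoryAverage:
    def test_identical_values_pass_through(self):
        assert mp.territory_average({"LAD": 0.9, "RCA": 0.9, "CX": 0.9}) \
            == pytest.approx(0.9)

    def test_cohort_weights(self):
        vals = {"LAD": 1.0, "RCA": 0.8, "CX": 0.6}
        got = mp.territory_average(vals, mp.LINDE_WEIGHTS)
        assert got == pytest.approx((23 * 1.0 + 17 * 0.8 + 9 * 0.6) / 49,
                                    rel=1e-14)

    def test_missing_key_is_error(self):
        with pytest.raises(mp.ValidationError, match="missing"):
            mp.territory_average({"LAD": 1.0}, mp.LINDE_WEIGHTS)

    def test_empty_map_is_error(self):
        with pytest.raises(mp.ValidationError):
            mp.territory_average({})


class TestXiMap:
    def test_anchors(self):
        assert mp.default_xi_map(0.0) == pytest.approx(1.0)
        assert mp.default_xi_map(80.0) == pytest.approx(0.55)
        assert mp.default_xi_map(100.0) == pytest.approx(0.0)

    def test_monotone_non_increasing(self):
        s = np.linspace(0, 100, 201)
        xi = mp.default_xi_map(s)
        assert np.all(np.diff(xi) <= 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.default_xi_map(101.0)


class TestQuarticFit:
    def test_exact_recovery_of_reference_polynomial(self):
        s = np.linspace(0, 100, 11)
        tpr = np.polyval(mp.REFERENCE_STRESS_QUARTIC, s)
        coeffs, rms = mp.fit_quartic(list(zip(s, tpr)))
        assert np.allclose(coeffs, mp.REFERENCE_STRESS_QUARTIC,
                           rtol=1e-8, atol=1e-10)
        assert rms < 1e-10

    def test_constant_curve_has_zero_nonconstant_coefficients(self):
        s = np.linspace(0, 100, 9)
        coeffs, _ = mp.fit_quartic([(v, 1.07) for v in s])
        assert np.allclose(coeffs[:4], 0.0, atol=1e-12)
        assert coeffs[4] == pytest.approx(1.07)

    def test_noisy_curve_recovers_generator_within_three_se(self):
        rng = np.random.default_rng(1234)
        s = np.linspace(0, 100, 41)
        truth = np.asarray(mp.REFERENCE_STRESS_QUARTIC)
        sigma = 0.01
        y = np.polyval(truth, s) + rng.normal(0, sigma, s.size)
        coeffs, _ = mp.fit_quartic(list(zip(s, y)))
        # standard errors of the polynomial LS estimator
        V = np.vander(s, 5)
        cov = sigma**2 * np.linalg.inv(V.T @ V)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(coeffs - truth) < 3 * se)

    def test_too_few_points_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.fit_quartic([(0, 1.0), (50, 0.9), (100, 0.5), (25, 0.95)])


class TestThreshold:
    def test_reference_quartic_crossing_near_75(self):
        got = mp.threshold_stenosis(mp.REFERENCE_STRESS_QUARTIC, 0.99)
        assert 74.0 <= got <= 76.0

    def test_threshold_at_curve_start(self):
        poly = mp.REFERENCE_STRESS_QUARTIC
        got = mp.threshold_stenosis(poly, np.polyval(poly, 0.0))
        assert got == pytest.approx(0.0, abs=1e-6)

    def test_unreachable_threshold_is_error(self):
        with pytest.raises(mp.ValidationError, match="not crossed"):
            mp.threshold_stenosis(mp.REFERENCE_STRESS_QUARTIC, 2.0)


class TestMeanRelativeError:
    def test_identical_series(self):
        assert mp.mean_relative_error([1.0, 0.9], [1.0, 0.9]) == 0.0

    def test_uniform_ten_percent(self):
        obs = np.array([0.9, 1.0, 1.1])
        assert mp.mean_relative_error(1.1 * obs, obs) == pytest.approx(0.1)

    def test_hand_computed_example(self):
        assert mp.mean_relative_error([1.0, 2.0], [2.0, 1.0]) \
            == pytest.approx(0.75)

    def test_zero_observed_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.mean_relative_error([1.0], [0.0])


class TestCalibration:
    def test_rest_protocol_feasible_point(self, linde_cal):
        res = linde_cal
        plo, phi = res.targets.pressure_mmHg
        tlo, thi = res.targets.tpr
        assert plo <= res.p2_prime_mmHg <= phi
        assert tlo <= res.tpr <= thi
        assert 0.020 <= res.geom.r1 <= 0.030

    def test_selected_radius_maximises_tpr(self, linde_cal):
        """A slightly larger radius must give a smaller healthy TPR."""
        r_lo, r_hi = linde_cal.feasible_r1
        t_mid, _ = _readouts(0.5 * (r_lo + r_hi), linde_cal.geom.s,
                             mp.TissueParams(), linde_cal.drive)
        assert t_mid < linde_cal.tpr

    def test_stress_protocol_feasible_point(self, george_cal):
        res = george_cal
        plo, phi = res.targets.pressure_mmHg
        assert plo <= res.p2_prime_mmHg <= phi
        assert res.targets.tpr[0] <= res.tpr <= res.targets.tpr[1]

    def test_healthy_tpr_exceeds_one_at_both_calibrations(self, linde_cal,
                                                          george_cal):
        assert linde_cal.tpr > 1.0
        assert george_cal.tpr > 1.0

    def test_empty_target_interval_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.CalibrationTargets(pressure_mmHg=(150.0, 120.0),
                                  tpr=(0.9, 1.1), q0H=1e-9, deltaH=1.0,
                                  TH=1.0)

    def test_infeasible_targets_fail_loudly_with_best_candidate(self):
        bad = mp.CalibrationTargets(pressure_mmHg=(400.0, 500.0),
                                    tpr=(0.93, 1.05), q0H=2.5e-9,
                                    deltaH=3.0, TH=60 / 58)
        with pytest.raises(mp.CalibrationError) as ei:
            mp.calibrate(bad, n_grid=31)
        assert ei.value.best is not None


class TestScenarioOrderings:
    def test_stress_tpr_below_rest_tpr(self, linde_cal):
        sc = StressScenario(geom=linde_cal.geom, tissue=mp.TissueParams(),
                            q0H=mp.LINDE.q0H, deltaH=mp.LINDE.deltaH,
                            TH=mp.LINDE.TH, T=mp.LINDE.T_stress,
                            mode="envelope")
        rest = mp.compute_tpr(
            mp.HealthyField(linde_cal.geom, mp.TissueParams(),
                            sc.healthy_drive(), mode="envelope"),
            ntheta=1).tpr
        stress = sc.territory_tpr(0.0, 1.0)
        assert stress < rest

    def test_wider_sector_starves_subendocardium(self, linde_cal):
        """Sector-mean subendocardial flow falls monotonically as the
        underperfused territory widens; the TPR itself falls over narrow to
        moderate sectors (for very wide sectors the subepicardial reference
        drops too, so the ratio is no longer monotone)."""
        tis = mp.TissueParams()
        drive = mp.DriveParams(q0=mp.LINDE.q0H, delta=mp.LINDE.deltaH,
                               T=mp.LINDE.TH)
        reps = []
        for deg in (40, 72, 108, 180):
            spec = mp.StenosisSpec(theta_s=math.radians(deg), xi=0.55)
            fld = mp.StenoticField(linde_cal.geom, tis, drive, drive, spec,
                                   M=30, N=30, mode="envelope")
            reps.append(mp.compute_tpr(fld, sector=spec.theta_s,
                                       nr=101, ntheta=360))
        nums = [r.subendo_mean for r in reps]
        assert nums == sorted(nums, reverse=True)
        tprs = [r.tpr for r in reps[:3]]
        assert tprs == sorted(tprs, reverse=True)
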