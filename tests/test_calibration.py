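import math

import numpy as np
import pytest

from nadquant.calibration import (
    STANDARD_SERIES_UM,
    CalibrationPoint,
    LotObservation,
    assign_lot,
    correction_factor,
    fit_curve,
    interpolate_amount,
    loq_from_series,
    on_column_amounts,
)


def exact_points(slope=100.0, series=STANDARD_SERIES_UM, s2n=1e6):
    amounts = on_column_amounts(series)
    return [
        CalibrationPoint(nominal_conc=c, on_column_pmol=a, light_area=slope * a,
                         s2n=s2n if a > 0 else 0.0)
        for c, a in zip(series, amounts)
    ]


class TestOnColumnAmounts:
    def test_series_endpoints_bracket_the_linear_range(self):
        amounts = on_column_amounts(STANDARD_SERIES_UM)
        nonzero = amounts[amounts > 0]
        assert nonzero.min() == pytest.approx(0.125)
        assert nonzero.max() == pytest.approx(250.0)

    def test_zero_concentration_gives_zero(self):
        assert on_column_amounts([0.0])[0] == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            on_column_amounts([-1.0])


class TestFitCurve:
    def test_exact_line(self):
        curve = fit_curve("X", exact_points(slope=100.0))
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.linear_range == (0.125, 250.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = on_column_amounts(STANDARD_SERIES_UM)[1:]
        y = 80.0 * x + 5.0 + rng.normal(0, 3.0, size=x.size)
        points = [
            CalibrationPoint(nominal_conc=c, on_column_pmol=a, light_area=v)
            for c, a, v in zip(STANDARD_SERIES_UM[1:], x, y)
        ]
        curve = fit_curve("X", points)
        # closed-form least squares via the normal equations
        A = np.vstack([x, np.ones_like(x)]).T
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert curve.slope == pytest.approx(slope, rel=1e-9)
        assert curve.intercept == pytest.approx(intercept, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curve("X", exact_points()[:3])  # zero level plus two points

    def test_linear_range_drops_deviant_low_point(self):
        points = exact_points(slope=100.0)
        bad = points[1]
        points[1] = CalibrationPoint(
            nominal_conc=bad.nominal_conc,
            on_column_pmol=bad.on_column_pmol,
            light_area=bad.light_area * 0.5,  # 50% low: outside back-calc tolerance
            s2n=bad.s2n,
        )
        curve = fit_curve("X", points)
        assert curve.linear_range[0] == pytest.approx(0.25)


class TestInterpolateAmount:
    def test_midpoint_of_2um_and_6um_standards_is_5_pmol(self):
        """An area halfway between the 2 uM (2.5 pmol) and 6 uM (7.5 pmol)
        standards back-calculates to 5 pmol of heavy metabolite."""
        points = exact_points(slope=123.4)
        curve = fit_curve("X", points)
        area_2um = next(p.light_area for p in points if p.nominal_conc == 2.0)
        area_6um = next(p.light_area for p in points if p.nominal_conc == 6.0)
        pmol, in_range = interpolate_amount(curve, (area_2um + area_6um) / 2)
        assert pmol == pytest.approx(5.0, abs=1e-9)
        assert in_range

    def test_standard_point_back_calculates_to_itself(self):
        points = exact_points()
        curve = fit_curve("X", points)
        area_2um = next(p.light_area for p in points if p.nominal_conc == 2.0)
        assert interpolate_amount(curve, area_2um)[0] == pytest.approx(2.5)

    def test_forward_inverse_round_trip(self):
        curve = fit_curve("X", exact_points(slope=77.0))
        for pmol in (0.2, 3.0, 199.0):
            area = curve.slope * pmol + curve.intercept
            assert interpolate_amount(curve, area)[0] == pytest.approx(pmol, rel=1e-9)

    def test_amount_outside_linear_range_flagged(self):
        curve = fit_curve("X", exact_points())
        _, in_range = interpolate_amount(curve, curve.slope * 1000.0)
        assert not in_range


class TestLOQ:
    def test_exact_crossing_at_grid_point(self):
        points = [
            CalibrationPoint(0.1, 0.125, 10.0, s2n=5.0),
            CalibrationPoint(0.2, 0.25, 20.0, s2n=10.0),
            CalibrationPoint(0.6, 0.75, 60.0, s2n=30.0),
        ]
        assert loq_from_series(points).pmol == pytest.approx(0.25)

    def test_proportional_s2n_interpolates_to_true_crossing(self):
        # S/N = 40 x pmol -> crossing at exactly 0.25 pmol
        points = [
            CalibrationPoint(c, p, 100 * p, s2n=40.0 * p)
            for c, p in zip(STANDARD_SERIES_UM[1:],
                            on_column_amounts(STANDARD_SERIES_UM)[1:])
        ]
        est = loq_from_series(points)
        assert not est.censored
        assert est.pmol == pytest.approx(0.25, rel=1e-6)

    def test_series_never_reaching_10_is_censored(self):
        points = [
            CalibrationPoint(c, p, 100 * p, s2n=1.0)
            for c, p in zip(STANDARD_SERIES_UM[1:],
                            on_column_amounts(STANDARD_SERIES_UM)[1:])
        ]
        est = loq_from_series(points)
        assert est.censored and est.pmol == pytest.approx(250.0)


class TestAssignLot:
    def curves(self):
        return {"NAD": fit_curve("NAD", exact_points(slope=100.0))}

    def test_identical_replicates_have_zero_cv(self):
        obs = {"NAD": LotObservation(heavy_area=2000.0, light_area=25000.0,
                                     light_pmol=250.0, light_s2n=1e5)}
        lot = assign_lot([obs, obs], self.curves())
        assert lot.assigned_pmol["NAD"] == pytest.approx(20.0)
        assert lot.replicate_cv["NAD"] == 0.0

    def test_ratio_assignment_invariant_under_injection_rescale(self):
        obs = {"NAD": LotObservation(heavy_area=2000.0, light_area=25000.0,
                                     light_pmol=250.0, light_s2n=1e5)}
        s = 0.37  # any injection-wide multiplicative factor
        scaled = {"NAD": LotObservation(heavy_area=2000.0 * s,
                                        light_area=25000.0 * s,
                                        light_pmol=250.0, light_s2n=1e5)}
        a = assign_lot([obs, obs], self.curves()).assigned_pmol["NAD"]
        b = assign_lot([scaled, scaled], self.curves()).assigned_pmol["NAD"]
        assert b == pytest.approx(a, rel=1e-12)

    def test_missing_surrogate_target_is_tolerated(self):
        curves = {
            "NAD": fit_curve("NAD", exact_points()),
            "IMP": fit_curve("IMP", exact_points()),
        }
        obs = {"NAD": LotObservation(heavy_area=2000.0, light_area=25000.0,
                                     light_pmol=250.0, light_s2n=1e5)}
        lot = assign_lot([obs, obs], curves)  # no IMP heavy peak anywhere
        assert "IMP" not in lot.assigned_pmol
        assert lot.via["IMP"] == "NMN"

    def test_missing_heavy_peak_for_direct_metabolite_is_an_error(self):
        curves = {
            "NAD": fit_curve("NAD", exact_points()),
            "ATP": fit_curve("ATP", exact_points()),
        }
        obs = {"NAD": LotObservation(heavy_area=2000.0)}
        with pytest.raises(ValueError, match="ATP"):
            assign_lot([obs, obs], curves)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            assign_lot([{}], self.curves())


class TestCorrectionFactor:
    def points(self, rf):
        return [
            CalibrationPoint(c, p, rf * p, s2n=1e6)
            for c, p in zip(STANDARD_SERIES_UM[1:],
                            on_column_amounts(STANDARD_SERIES_UM)[1:])
        ]

    def test_identical_response_factors_give_unity(self):
        assert correction_factor(self.points(50.0), self.points(50.0)) == pytest.approx(1.0)

    def test_double_response_gives_two(self):
        assert correction_factor(self.points(100.0), self.points(50.0)) == pytest.approx(2.0)

    def test_zero_surrogate_response_rejected(self):
        with pytest.raises(ValueError):
            correction_factor(self.points(100.0), self.points(0.0))
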