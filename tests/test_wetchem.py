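import numpy as np
import pytest

from dnjquant import wetchem
from dnjquant.synthetic_data import generate_dose_response, generate_hplc_calibration


class TestCalibrationLimits:
    def test_exact_line_with_constant_blanks(self):
        levels = np.array([5.0, 10.0, 20.0, 40.0])
        areas = 2.5 * levels + 1.0
        curve = wetchem.fit_calibration(levels, areas, np.full(6, 1.0))
        assert curve.slope == pytest.approx(2.5, abs=1e-12)
        assert curve.intercept == pytest.approx(1.0, abs=1e-10)
        assert curve.sigma == 0.0
        assert curve.lod == 0.0
        assert curve.r2 == pytest.approx(1.0)

    def test_formula_in_consistent_units(self):
        # sigma = 1, S = 3.3 => LOD = 1, LOQ = 10/3.3
        assert wetchem.lod_from_blank(1.0, 3.3) == pytest.approx(1.0)
        assert wetchem.loq_from_blank(1.0, 3.3) == pytest.approx(10.0 / 3.3)

    def test_loq_lod_ratio_invariant(self):
        rng = np.random.default_rng(0)
        levels = np.array([3.14, 25.0, 50.0, 100.0, 157.14])
        areas = 88.68 * levels - 0.06 + rng.normal(0, 2.0, levels.size)
        blanks = rng.normal(0.0, 1.5, 8)
        curve = wetchem.fit_calibration(levels, areas, blanks)
        assert curve.loq / curve.lod == pytest.approx(10.0 / 3.3, abs=1e-12)
        assert curve.lod > 0

    def test_printed_lod_reproduces_printed_loq(self):
        # chlorogenic acid / neochlorogenic acid / rutin worked examples
        for lod, loq in [(3.52, 10.67), (2.82, 8.55), (4.07, 12.33)]:
            assert round(wetchem.loq_from_lod(lod), 2) == loq

    def test_round_trip_with_generator(self):
        df = generate_hplc_calibration(sigma_blank=0.8, seed=4)
        cal = df[df["concentration"] > 0]
        blanks = df.loc[df["concentration"] == 0, "area"]
        curve = wetchem.fit_calibration(cal["concentration"], cal["area"], blanks)
        assert curve.slope == pytest.approx(88.68, rel=0.01)
        assert curve.range_high == pytest.approx(157.14)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wetchem.fit_calibration([1.0, 2.0], [1.0, 2.0], np.zeros(6))
        with pytest.raises(ValueError):
            wetchem.fit_calibration([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], np.zeros(3))
        with pytest.raises(ValueError, match="slope"):
            wetchem.fit_calibration([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], np.zeros(6))


class TestRecovery:
    def test_full_recovery(self):
        pct, suspect = wetchem.recovery_percent(10.0, 2.0, 8.0)
        assert pct == pytest.approx(100.0)
        assert not suspect

    def test_zero_recovery_flagged(self):
        pct, suspect = wetchem.recovery_percent(2.0, 2.0, 8.0)
        assert pct == 0.0 and suspect

    def test_worked_example_ninety_point_four(self):
        pct, suspect = wetchem.recovery_percent(10.0, 2.0, 8.85)
        assert round(pct, 1) == 90.4
        assert not suspect

    def test_added_must_be_positive(self):
        with pytest.raises(ValueError):
            wetchem.recovery_percent(10.0, 2.0, 0.0)


class TestRsd:
    def test_constant_replicates(self):
        assert wetchem.rsd_percent([1.0, 1.0, 1.0]) == 0.0

    def test_two_point_formula(self):
        # sd([9, 11]) = sqrt(2), mean 10 -> 14.142...%
        assert wetchem.rsd_percent([9.0, 11.0]) == pytest.approx(100.0 * np.sqrt(2) / 10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(5.0, 10.0, 8)
        assert wetchem.rsd_percent(3.7 * v) == pytest.approx(wetchem.rsd_percent(v))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            wetchem.rsd_percent([1.0])
        with pytest.raises(ValueError):
            wetchem.rsd_percent([-1.0, 1.0])


class TestDpph:
    def test_no_scavenging(self):
        pct, clipped = wetchem.dpph_inhibition(1.0, 1.0)
        assert pct == 0.0 and not clipped

    def test_complete_scavenging(self):
        pct, _ = wetchem.dpph_inhibition(1.0, 0.0)
        assert pct == 100.0

    def test_three_quarters(self):
        pct, _ = wetchem.dpph_inhibition(1.0, 0.25)
        assert pct == pytest.approx(75.0)

    def test_clipping_flagged(self):
        pct, clipped = wetchem.dpph_inhibition(1.0, 1.2)
        assert pct == 0.0 and clipped

    def test_blank_must_be_positive(self):
        with pytest.raises(ValueError):
            wetchem.dpph_inhibition(0.0, 0.5)


class TestEc50:
    def test_midpoint_interpolation(self):
        res = wetchem.ec50_from_curve([(1.0, 25.0), (3.0, 75.0)])
        assert res.ec50 == pytest.approx(2.0)

    def test_exact_fifty_percent_point(self):
        res = wetchem.ec50_from_curve([(1.0, 30.0), (2.5, 50.0), (4.0, 80.0)])
        assert res.ec50 == 2.5

    def test_redundant_outer_points_do_not_move_estimate(self):
        base = wetchem.ec50_from_curve([(1.0, 25.0), (3.0, 75.0)])
        padded = wetchem.ec50_from_curve(
            [(0.1, 5.0), (0.5, 10.0), (1.0, 25.0), (3.0, 75.0), (9.0, 95.0)]
        )
        assert padded.ec50 == pytest.approx(base.ec50)

    def test_generator_round_trip_within_two_percent(self):
        df = generate_dose_response(
            ec50_true=2.0, hill=1.0, conc_grid=np.linspace(0.5, 3.3, 8), noise_sd=0.0
        )
        res = wetchem.ec50_from_curve(df[["concentration", "inhibition"]].to_numpy())
        assert abs(res.ec50 - 2.0) / 2.0 < 0.02

    def test_no_crossing_errors(self):
        with pytest.raises(ValueError, match="outside measured range"):
            wetchem.ec50_from_curve([(1.0, 5.0), (2.0, 20.0)])

    def test_non_monotone_noise_is_regularized(self):
        df = generate_dose_response(
            ec50_true=2.0, conc_grid=np.linspace(0.5, 3.3, 8), noise_sd=3.0, seed=6
        )
        res = wetchem.ec50_from_curve(df[["concentration", "inhibition"]].to_numpy())
        mono = res.curve_points[:, 1]
        assert np.all(np.diff(mono) >= -1e-12)
        assert 1.0 < res.ec50 < 3.0


class TestContentAndRdi:
    def test_extraction_defaults(self):
        # 10 µg/mL in 15 mL from 0.5 g -> 300 µg/g
        assert wetchem.content_per_gram(10.0) == pytest.approx(300.0)

    def test_mass_scaling(self):
        a = wetchem.content_per_gram(10.0, 15.0, 0.5)
        b = wetchem.content_per_gram(10.0, 15.0, 1.0)
        assert a == pytest.approx(2.0 * b)

    def test_zero_concentration(self):
        assert wetchem.content_per_gram(0.0) == 0.0

    def test_supplement_level_coverage(self):
        # 1 µg/g, 0.5 g units, 6/day -> 3 µg/day -> 0.01% of 30 mg
        assert wetchem.rdi_coverage(1.0, 0.5, 6) == pytest.approx(0.01)

    def test_tea_level_coverage(self):
        # strongest tea at 2 g/day covers 6.615% of the 30 mg reference
        assert wetchem.rdi_coverage(992.314, 2.0, 1) == pytest.approx(6.615, abs=5e-4)

    def test_common_scaling_cancels(self):
        a = wetchem.rdi_coverage(500.0, 1.0, 2, rdi_mg=30.0)
        b = wetchem.rdi_coverage(1000.0, 1.0, 2, rdi_mg=60.0)
        assert a == pytest.approx(b)

    def test_unit_round_trip(self):
        # µg/g -> mg/day -> back
        content, unit_mass, units = 750.0, 1.5, 2
        mg_day = wetchem.rdi_coverage(content, unit_mass, units) / 100.0 * 30.0
        assert mg_day * 1000.0 / (unit_mass * units) == pytest.approx(content, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            wetchem.rdi_coverage(1.0, 0.5, 6, rdi_mg=0.0)
        with pytest.raises(ValueError):
            wetchem.content_per_gram(10.0, 15.0, 0.0)


def test_validation_summary_table_layout():
    curve = wetchem.fit_calibration(
        [3.14, 25.0, 50.0, 157.14],
        [88.68 * c - 0.06 for c in [3.14, 25.0, 50.0, 157.14]],
        np.full(6, 0.0),
    )
    table = wetchem.validation_summary({"DNJ": (curve, 90.4, 7.5)})
    assert table.loc["equation", "DNJ"].startswith("y = 88.68x")
    assert table.loc["recovery_pct", "DNJ"] == 90.4
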