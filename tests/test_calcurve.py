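"""Calibration curves: parsing, interpolation, reservoir shifts,
mixing, and single-date calibration against a brute-force oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from tidechron import calcurve as cc
from tidechron.synthetic import make_toy_curve

FIVE_ROWS = """# toy curve
# calBP, 14C age, error
1000,1100,20
800,900,18
600,700,15
400,450,12
200,230,10
"""


def _toy(nodes):
    cal, mu, sig = zip(*nodes)
    return cc.CalibrationCurve("toy", cal, mu, sig)


class TestParsing:
    def test_round_trip_preserves_data_rows(self, tmp_path):
        src = tmp_path / "toy.14c"
        src.write_text(FIVE_ROWS)
        curve = cc.parse_curve_file(src, "toy", "terrestrial")
        assert len(curve) == 5
        out = tmp_path / "out.14c"
        cc.write_curve_file(curve, out)
        reparsed = cc.parse_curve_file(out, "toy", "terrestrial")
        np.testing.assert_array_equal(curve.cal_bp, reparsed.cal_bp)
        np.testing.assert_array_equal(curve.c14_age, reparsed.c14_age)
        np.testing.assert_array_equal(curve.sigma, reparsed.sigma)

    def test_comments_only_file_is_degenerate(self, tmp_path):
        src = tmp_path / "empty.14c"
        src.write_text("# just\n# comments\n")
        with pytest.raises(cc.DegenerateCurveError):
            cc.parse_curve_file(src, "empty", "terrestrial")

    def test_malformed_row_names_line_number(self, tmp_path):
        src = tmp_path / "bad.14c"
        src.write_text("# header\n1000,1100,20\n800,oops,18\n")
        with pytest.raises(cc.CurveParseError, match="line 3"):
            cc.parse_curve_file(src, "bad", "terrestrial")

    def test_bundled_curves_load(self, shcal20, marine20):
        assert shcal20.kind == "terrestrial"
        assert marine20.kind == "marine"
        assert len(shcal20) > 100 and len(marine20) > 100


class TestLookup:
    def test_grid_node_identity(self):
        curve = _toy([(1000, 1100, 20), (800, 900, 18), (600, 700, 15)])
        assert cc.curve_lookup(curve, 800) == (900.0, 18.0)

    def test_segment_midpoint_is_arithmetic_mean(self):
        curve = _toy([(1000, 1100, 20), (800, 900, 18)])
        mu, sig = cc.curve_lookup(curve, 900)
        assert mu == pytest.approx((1100 + 900) / 2)
        assert sig == pytest.approx((20 + 18) / 2)

    def test_beyond_oldest_node_raises(self):
        curve = _toy([(1000, 1100, 20), (800, 900, 18)])
        with pytest.raises(cc.OutOfRangeError):
            cc.curve_lookup(curve, 1001)


class TestReservoirShift:
    def test_zero_offset_is_identity(self, marine20):
        shifted = cc.shift_marine(marine20, cc.ReservoirOffset("fixed", 0.0, 0.0))
        np.testing.assert_array_equal(shifted.c14_age, marine20.c14_age)
        np.testing.assert_array_equal(shifted.sigma, marine20.sigma)

    def test_regional_offset_quadrature(self):
        # Delta-R -314 +/- 52 on a node (1400, 20): mean adds, sds add
        # in quadrature
        curve = cc.CalibrationCurve("m", [700, 600], [1400, 1300], [20, 20], kind="marine")
        shifted = cc.shift_marine(curve, cc.ReservoirOffset("fixed", -314.0, 52.0))
        assert shifted.c14_age[0] == pytest.approx(1086.0)
        assert shifted.sigma[0] == pytest.approx(math.sqrt(400 + 2704))

    def test_shift_additivity(self, marine20):
        one = cc.shift_marine(
            cc.shift_marine(marine20, cc.ReservoirOffset("fixed", -10.0, 0.0)),
            cc.ReservoirOffset("fixed", -10.0, 0.0),
        )
        two = cc.shift_marine(marine20, cc.ReservoirOffset("fixed", -20.0, 0.0))
        np.testing.assert_allclose(one.c14_age, two.c14_age)

    def test_constant_delta_r_shifts_mu_exactly(self, marine20):
        for c in (-250.0, 37.5, 120.0):
            shifted = cc.shift_marine(marine20, cc.ReservoirOffset("fixed", c, 0.0))
            np.testing.assert_allclose(shifted.c14_age - marine20.c14_age, c)

    def test_terrestrial_input_rejected(self, shcal20):
        with pytest.raises(cc.CurveError):
            cc.shift_marine(shcal20, cc.ReservoirOffset("fixed", -100.0, 0.0))


class TestMixing:
    def test_endpoints_reproduce_components_exactly(self, shcal20, marine20):
        grid = np.arange(0.0, 4000.0, 37.0)
        m0 = cc.mix_curves(shcal20, marine20, 0.0)
        m1 = cc.mix_curves(shcal20, marine20, 1.0)
        np.testing.assert_array_equal(m0.mu(grid), shcal20.mu(grid))
        np.testing.assert_array_equal(m0.sigma_at(grid), shcal20.sigma_at(grid))
        np.testing.assert_array_equal(m1.mu(grid), marine20.mu(grid))
        np.testing.assert_array_equal(m1.sigma_at(grid), marine20.sigma_at(grid))

    def test_half_mixture_formula(self):
        terr = cc.CalibrationCurve("t", [500, 400], [1000, 950], [10, 10])
        mar = cc.CalibrationCurve("m", [500, 400], [1400, 1350], [20, 20], kind="marine")
        mix = cc.mix_curves(terr, mar, 0.5)
        assert float(mix.mu(500)) == pytest.approx(1200.0)
        assert float(mix.sigma_at(500)) == pytest.approx(math.sqrt(25 + 100))

    @pytest.mark.parametrize("m", [-0.01, 1.01])
    def test_fraction_outside_unit_interval_rejected(self, shcal20, marine20, m):
        with pytest.raises(ValueError):
            cc.mix_curves(shcal20, marine20, m)


def brute_force_calibration(det, curve, lo, hi):
    """Independent oracle: normal likelihood on an explicit grid using
    scipy's pdf, normalized by direct summation."""
    grid = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float)
    mu = np.array([float(curve.mu(t)) for t in grid])
    sig = np.array(
        [math.sqrt(det.sigma**2 + float(curve.sigma_at(t)) ** 2) for t in grid]
    )
    lik = stats.norm.pdf(det.age, loc=mu, scale=sig)
    return grid, lik / lik.sum()


class TestCalibrateSingle:
    def test_flat_curve_gives_uniform_density(self):
        curve = cc.CalibrationCurve("flat", [2000, 1000, 0], [800, 800, 800], [1, 1, 1])
        det = cc.RadiocarbonDetermination("x", 800, 5)
        dens = cc.calibrate_single(det, curve)
        assert np.allclose(dens.weights, dens.weights[0])

    def test_matches_brute_force_oracle_on_toy_curve(self):
        curve = _toy([(1400, 1300, 25), (900, 950, 15), (400, 420, 10)])
        det = cc.RadiocarbonDetermination("x", 1000, 20)
        dens = cc.calibrate_single(det, curve)
        grid, ref = brute_force_calibration(det, curve, *curve.span)
        i0 = int(dens.grid[0] - grid[0])
        sub = ref[i0 : i0 + dens.grid.size]
        assert 0.5 * np.abs(dens.weights - sub / sub.sum()).sum() < 1e-12

    def test_normalization(self, shcal20):
        det = cc.RadiocarbonDetermination("x", 895, 20)
        dens = cc.calibrate_single(det, shcal20)
        assert abs(dens.weights.sum() - 1.0) < 1e-9

    def test_off_curve_measurement_raises_window_error(self):
        curve = _toy([(1000, 1100, 5), (800, 900, 5)])
        det = cc.RadiocarbonDetermination("x", 50000, 10)
        with pytest.raises(cc.CurveError):
            cc.calibrate_single(det, curve)

    def test_median_on_reference_curve_matches_oracle(self, shcal20):
        det = cc.RadiocarbonDetermination("x", 895, 20)
        dens = cc.calibrate_single(det, shcal20)
        lo = max(shcal20.span[0], cc.DEFAULT_WINDOW[0])
        hi = min(shcal20.span[1], cc.DEFAULT_WINDOW[1])
        grid, ref = brute_force_calibration(det, shcal20, lo, hi)
        cdf = np.cumsum(ref)
        median_ref = float(np.interp(0.5, cdf, grid))
        assert abs(dens.median_bp() - median_ref) <= 1.0

    def test_randomized_toy_curves_match_oracle(self, rng):
        # the core oracle-equivalence property over wiggly random curves
        for _ in range(20):
            n_nodes = rng.integers(4, 9)
            cal = np.sort(rng.uniform(0, 3000, n_nodes))
            cal[0], cal[-1] = 0.0, 3000.0
            mu = cal * rng.uniform(0.7, 1.2) + rng.normal(0, 60, n_nodes).cumsum()
            sig = rng.uniform(5, 40, n_nodes)
            curve = make_toy_curve(list(zip(cal, mu, sig)), jitter=rng.uniform(0, 15), seed=int(rng.integers(1e6)))
            target = float(curve.mu(rng.uniform(200, 2800)))
            det = cc.RadiocarbonDetermination("x", target, float(rng.uniform(8, 40)))
            dens = cc.calibrate_single(det, curve, window=curve.span)
            grid, ref = brute_force_calibration(det, curve, *curve.span)
            i0 = int(dens.grid[0] - grid[0])
            sub = ref[i0 : i0 + dens.grid.size]
            tv = 0.5 * (np.abs(dens.weights - sub / sub.sum()).sum())
            assert tv < 1e-9
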