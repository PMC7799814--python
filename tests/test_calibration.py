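"""Curve parsing and single-date calibration against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from paleodem import (
    CalibrationCurve,
    calibrate,
    identity_curve,
    read_curve,
    uncalibrate_sample,
)
from paleodem.calibration import density_matrix
from paleodem.errors import CalibrationRangeError, CurveFormatError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCurve:
    def test_parses_intcal_dialect_with_headers(self, tmp_path):
        p = _write(
            tmp_path,
            "toy.14c",
            "# Toy curve\n# CAL BP, 14C age BP, Error\n5000,4400,20\n4000,3600,15\n3000,2900,18\n",
        )
        curve = read_curve(p)
        assert curve.cal_bp.size == 3
        # linear interpolation between knots
        assert curve.c14_at(4500) == pytest.approx(4000.0)

    def test_identity_curve_file_interpolates_identically(self, tmp_path):
        rows = "\n".join(f"{v},{v},1" for v in range(3000, 6001, 100))
        p = _write(tmp_path, "ident.14c", "# header\n" + rows + "\n")
        curve = read_curve(p)
        assert curve.c14_at(4321.0) == pytest.approx(4321.0)

    def test_row_order_is_canonicalized(self, tmp_path):
        asc = _write(tmp_path, "asc.csv", "cal_bp,c14_bp,error\n3000,2900,10\n4000,3600,12\n5000,4400,20\n")
        desc = _write(tmp_path, "desc.csv", "cal_bp,c14_bp,error\n5000,4400,20\n4000,3600,12\n3000,2900,10\n")
        a, d = read_curve(asc), read_curve(desc)
        np.testing.assert_array_equal(a.cal_bp, d.cal_bp)
        np.testing.assert_array_equal(a.c14_bp, d.c14_bp)
        np.testing.assert_array_equal(a.sigma_curve, d.sigma_curve)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "bad.14c", "5000,4400,20\n4000,oops,15\n")
        with pytest.raises(CurveFormatError, match=":2"):
            read_curve(p)

    def test_non_monotone_cal_rejected(self):
        with pytest.raises(CurveFormatError, match="monotone"):
            CalibrationCurve([5000, 3000, 4000], [4400, 2900, 3600], [10, 10, 10])


class TestCalibrate:
    def test_identity_curve_gives_discretized_gaussian(self, ident):
        d = calibrate((4000, 20), ident, normalize=False)
        expected = stats.norm.pdf(d.grid, loc=4000.0, scale=20.0)
        assert np.max(np.abs(d.density - expected)) < 1e-9
        assert d.mode == 4000.0

    def test_normalized_density_sums_to_one(self, synth_curve, rng):
        for _ in range(100):
            cra = rng.uniform(3000, 5500)
            err = rng.uniform(15, 120)
            d = calibrate((cra, err), synth_curve, normalize=True)
            assert d.mass == pytest.approx(1.0, abs=1e-6)

    def test_brute_force_oracle_on_piecewise_curve(self):
        # two-segment toy curve; oracle evaluates the Normal formula
        # independently at every grid year via direct interpolation
        curve = CalibrationCurve([2000, 3500, 5000], [1900, 3300, 4600], [20, 30, 25])
        d = calibrate((3000, 30), curve, normalize=False)
        for theta, got in zip(d.grid, d.density):
            m = np.interp(theta, [2000, 3500, 5000], [1900, 3300, 4600])
            s = np.interp(theta, [2000, 3500, 5000], [20, 30, 25])
            want = stats.norm.pdf(3000.0, loc=m, scale=np.hypot(30.0, s))
            assert got == pytest.approx(want, rel=1e-12)

    def test_invariant_to_row_ordering_and_grid_extension(self):
        knots = np.arange(2000.0, 6001.0, 50.0)
        c14 = 0.9 * knots
        sig = np.full(knots.size, 15.0)
        a = CalibrationCurve(knots, c14, sig)
        b = CalibrationCurve(knots[::-1], c14[::-1], sig[::-1])
        wide = CalibrationCurve(
            np.r_[[1000.0], knots, [8000.0]], np.r_[[900.0], c14, [7200.0]], np.r_[[15.0], sig, [15.0]]
        )
        da, db, dw = (calibrate((3600, 25), c) for c in (a, b, wide))
        np.testing.assert_array_equal(da.grid, db.grid)
        np.testing.assert_allclose(da.density, db.density)
        np.testing.assert_array_equal(da.grid, dw.grid)
        np.testing.assert_allclose(da.density, dw.density)

    def test_tail_trim_keeps_almost_all_mass(self, synth_curve):
        full = calibrate((4000, 30), synth_curve, tail_mass=1e-12)
        trimmed = calibrate((4000, 30), synth_curve, tail_mass=1e-5)
        assert trimmed.mass == pytest.approx(full.mass, rel=5e-5)
        assert trimmed.grid.size < full.grid.size

    def test_out_of_range_date_raises(self, synth_curve):
        with pytest.raises(CalibrationRangeError):
            calibrate((20000, 30), synth_curve)

    def test_density_matrix_matches_single_calibration(self, synth_curve, config):
        cras, errs = [4000.0, 5200.0], [30.0, 60.0]
        mat = density_matrix(cras, errs, synth_curve, config.grid)
        for i, (cra, err) in enumerate(zip(cras, errs)):
            d = calibrate((cra, err), synth_curve, tail_mass=1e-12)
            lookup = dict(zip(d.grid, d.density))
            dense = np.array([lookup.get(g, 0.0) for g in config.grid])
            # beyond the |z| ≤ 6 support the matrix keeps O(1e-10) density
            np.testing.assert_allclose(mat[i], dense, atol=1e-9)


class TestUncalibrate:
    def test_zero_curve_noise_returns_curve_mean(self, ident, rng):
        s = uncalibrate_sample(4000.0, ident, 25.0, rng)
        assert s.cra == 4000.0
        assert s.error == 25.0

    def test_sampling_statistics_match_curve_error(self, rng):
        curve = identity_curve(0, 10000, sigma=25.0)
        draws = np.array([uncalibrate_sample(4000.0, curve, 30.0, rng).cra for _ in range(10000)])
        assert abs(draws.mean() - 4000.0) < 1.0
        assert abs(draws.std() - 25.0) < 1.0

    def test_round_trip_concentrates_near_theta(self, synth_curve, rng):
        theta, lab_err = 4500.0, 30.0
        s_curve = float(synth_curve.sigma_at(theta))
        half = 3.0 * np.hypot(s_curve, lab_err)
        for _ in range(20):
            samp = uncalibrate_sample(theta, synth_curve, lab_err, rng)
            d = calibrate(samp, synth_curve, normalize=True)
            near = np.abs(d.grid - theta) <= half
            assert d.density[near].sum() >= 0.5

    def test_theta_outside_span_raises(self, synth_curve, rng):
        with pytest.raises(CalibrationRangeError):
            uncalibrate_sample(20000.0, synth_curve, 30.0, rng)
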