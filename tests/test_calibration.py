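import numpy as np
import pytest

from nightrange.calibration import (
    CalibrationModel,
    StablePixelOptions,
    apply_calibration,
    calibrate_stack,
    fit_calibration,
    select_stable_pixels,
)
from nightrange.errors import InputError, InsufficientDataError, RankError
from nightrange.grids import CompositeGrid
from nightrange.synthetic import (
    DistortionSpec,
    NightscapeParams,
    apply_distortion,
    make_nightscape,
)

TRUTH_COEFFS = (-1.0, 1.2, -0.003)


def _simulate_pairs(n=10_000, coeffs=TRUTH_COEFFS, noise_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 63, n)
    c0, c1, c2 = coeffs
    ref = c0 + c1 * t + c2 * t * t + rng.normal(0, noise_sd, n)
    return ref, t


class TestFitCalibration:
    def test_identity_fit(self):
        t = np.linspace(0, 63, 200)
        c = fit_calibration(t, t)
        assert c == pytest.approx((0.0, 1.0, 0.0), abs=1e-6)

    def test_exact_quadratic_recovered(self):
        t = np.linspace(0, 63, 100)
        ref = 2.0 + 0.9 * t + 0.001 * t * t
        c = fit_calibration(ref, t)
        assert c == pytest.approx((2.0, 0.9, 0.001), abs=1e-6)

    def test_noisy_recovery_within_tolerance(self):
        ref, t = _simulate_pairs(seed=42)
        c0, c1, c2 = fit_calibration(ref, t)
        assert abs(c0 - TRUTH_COEFFS[0]) <= 0.2
        assert abs(c1 - TRUTH_COEFFS[1]) <= 0.02
        assert abs(c2 - TRUTH_COEFFS[2]) <= 5e-4

    def test_outlier_robustness_vs_ols(self):
        # 10% of points shifted +40 DN; truth is the identity
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 63, 5000)
        ref = t.copy()
        outliers = rng.choice(t.size, size=t.size // 10, replace=False)
        ref[outliers] += 40.0
        c0, c1, c2 = fit_calibration(ref, t)
        assert abs(c0) <= 0.2 and abs(c1 - 1.0) <= 0.02 and abs(c2) <= 5e-4
        # an OLS quadratic on the same data is pulled off the truth
        X = np.column_stack([np.ones_like(t), t, t * t])
        ols = np.linalg.lstsq(X, ref, rcond=None)[0]
        assert abs(ols[0]) > 0.2 or abs(ols[1] - 1.0) > 0.02 or abs(ols[2]) > 5e-4

    def test_determinism(self):
        ref, t = _simulate_pairs(n=2000, seed=3)
        assert fit_calibration(ref, t) == fit_calibration(ref, t)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration(np.arange(10.0), np.arange(10.0))

    def test_degenerate_target(self):
        with pytest.raises(RankError):
            fit_calibration(np.arange(100.0), np.full(100, 5.0))

    def test_statsmodels_quantreg_agreement(self):
        # independent L1 route: statsmodels median regression
        import statsmodels.api as sm

        ref, t = _simulate_pairs(n=3000, seed=11)
        ours = fit_calibration(ref, t)
        X = sm.add_constant(np.column_stack([t, t * t]))
        theirs = sm.QuantReg(ref, X).fit(q=0.5).params
        assert ours == pytest.approx(tuple(theirs), abs=0.05)


class TestSelectStablePixels:
    def test_all_zero_reference_insufficient(self, grid_factory):
        ref = grid_factory(0.0)
        tgt = grid_factory(10.0)
        with pytest.raises(InsufficientDataError):
            select_stable_pixels(ref, tgt)

    def test_all_positive_selects_everything(self, grid_factory):
        ref = grid_factory(10.0)
        tgt = grid_factory(12.0)
        idx = select_stable_pixels(ref, tgt, StablePixelOptions(max_pixels=None))
        assert idx.shape[0] == ref.dn.size

    def test_trimming_excludes_changed_pixels(self, unit_grid, grid_factory):
        rng = np.random.default_rng(5)
        base = rng.uniform(5, 55, unit_grid.shape)
        changed = rng.random(unit_grid.shape) < 0.05
        tgt_dn = base.copy()
        tgt_dn[changed] = np.clip(tgt_dn[changed] + 30.0, 0, 63)
        ref = grid_factory(base)
        tgt = grid_factory(tgt_dn)
        idx = select_stable_pixels(
            ref, tgt, StablePixelOptions(trim=True, k=3.0, max_pixels=None)
        )
        kept = set(map(tuple, idx))
        changed_pixels = set(zip(*np.nonzero(changed)))
        excluded = changed_pixels - kept
        assert len(excluded) >= 0.9 * len(changed_pixels)

    def test_subsample_cap_and_determinism(self, grid_factory):
        ref = grid_factory(10.0)
        tgt = grid_factory(11.0)
        opts = StablePixelOptions(max_pixels=100, subsample_seed=1)
        a = select_stable_pixels(ref, tgt, opts)
        b = select_stable_pixels(ref, tgt, opts)
        assert a.shape == (100, 2)
        np.testing.assert_array_equal(a, b)


class TestApplyCalibration:
    def test_identity_is_noop(self, grid_factory):
        g = grid_factory(np.linspace(0, 63, 64 * 64).reshape(64, 64))
        out = apply_calibration(g, (0.0, 1.0, 0.0))
        np.testing.assert_array_equal(out.dn, g.dn)

    def test_zero_preserved_despite_offset(self, grid_factory):
        dn = np.zeros((64, 64))
        dn[0, 1] = 10.0
        out = apply_calibration(grid_factory(dn), (5.0, 1.0, 0.0))
        assert out.dn[0, 0] == 0.0
        assert out.dn[0, 1] == 15.0

    def test_clamped_at_63(self, grid_factory):
        out = apply_calibration(grid_factory(60.0), (0.0, 1.1, 0.0))
        assert (out.dn == 63.0).all()

    def test_nonfinite_coeffs_rejected(self, grid_factory):
        with pytest.raises(InputError):
            apply_calibration(grid_factory(1.0), (0.0, float("nan"), 0.0))


def _distorted_stack(noise_sd=0.0, seed=0, n_years=5, coeffs=TRUTH_COEFFS):
    # growth 0: the truth is temporally constant, so every co-lit pixel is a
    # genuinely stable pixel and recovery against truth is well-posed
    params = NightscapeParams(
        grid_rows=64, grid_cols=96, n_years=n_years, n_urban_seeds=12,
        growth_rate=0.0, base_brightness_decay=2.0, noise_sd=0.0, seed=seed,
    )
    truth = make_nightscape(params)
    years = [g.year for g in truth]
    ref_year = years[len(years) // 2]
    dcoeffs = {y: (coeffs if y != ref_year else (0.0, 1.0, 0.0)) for y in years}
    spec = DistortionSpec(coeffs=dcoeffs, noise_sd=noise_sd)
    observed = [apply_distortion(g, spec, seed=seed) for g in truth]
    return truth, observed, ref_year


class TestCalibrateStack:
    def test_identical_grids_identity_coeffs(self, grid_factory):
        stack = [grid_factory(np.tile(np.linspace(1, 60, 64), (64, 1)), year=2000 + i)
                 for i in range(3)]
        _, model = calibrate_stack(stack)
        for c in model.coefficients.values():
            assert c == pytest.approx((0.0, 1.0, 0.0), abs=1e-6)

    def test_single_year_stack_identity(self, grid_factory):
        g = grid_factory(5.0, year=1997)
        calibrated, model = calibrate_stack([g])
        assert model.reference_year == 1997
        assert model.coefficients == {1997: (0.0, 1.0, 0.0)}
        np.testing.assert_array_equal(calibrated[0].dn, g.dn)

    def test_reference_year_unchanged(self):
        truth, observed, ref_year = _distorted_stack()
        calibrated, model = calibrate_stack(observed, reference_year=ref_year)
        assert model.reference_year == ref_year
        ref_out = next(g for g in calibrated if g.year == ref_year)
        ref_in = next(g for g in observed if g.year == ref_year)
        np.testing.assert_array_equal(ref_out.dn, ref_in.dn)

    def test_missing_reference_year(self, grid_factory):
        with pytest.raises(InputError):
            calibrate_stack([grid_factory(1.0, year=2000)], reference_year=1990)

    def test_noisy_recovery_rmse(self):
        truth, observed, ref_year = _distorted_stack(noise_sd=1.0, seed=4)
        calibrated, _ = calibrate_stack(observed, reference_year=ref_year)
        for t, c in zip(truth, calibrated):
            if t.year == ref_year:
                continue
            stable = (t.dn > 0) & (t.dn < 63)
            rmse = np.sqrt(np.mean((c.dn[stable] - t.dn[stable]) ** 2))
            assert rmse <= 1.1 * 1.0

    def test_idempotence(self):
        truth, observed, ref_year = _distorted_stack(noise_sd=0.5, seed=9)
        calibrated, _ = calibrate_stack(observed, reference_year=ref_year)
        twice, model2 = calibrate_stack(calibrated, reference_year=ref_year)
        for a, b in zip(calibrated, twice):
            assert np.abs(a.dn - b.dn).max() <= 0.1

    def test_noiseless_monotone_distortion_recovered(self):
        truth, observed, ref_year = _distorted_stack(noise_sd=0.0, coeffs=(2.0, 0.9, 0.0))
        _, model = calibrate_stack(
            observed, reference_year=ref_year, opts=StablePixelOptions(max_pixels=None)
        )
        for year, (c0, c1, c2) in model.coefficients.items():
            if year == ref_year:
                continue
            # fitted map must invert the linear distortion: g(h(x)) = x
            x = np.linspace(1, 60, 50)
            h = 2.0 + 0.9 * x
            g = c0 + c1 * h + c2 * h * h
            assert np.abs(g - x).max() <= 1e-3

    def test_nonmonotone_coefficients_warn(self, grid_factory):
        from nightrange.calibration import _warn_if_nonmonotone

        with pytest.warns(UserWarning, match="non-monotone"):
            _warn_if_nonmonotone((0.0, 1.0, -0.05), 1999)

    def test_model_json_roundtrip(self, tmp_path):
        truth, observed, ref_year = _distorted_stack()
        _, model = calibrate_stack(observed, reference_year=ref_year)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = CalibrationModel.from_json(p)
        assert back.reference_year == model.reference_year
        for y, c in model.coefficients.items():
            assert back.coefficients[y] == pytest.approx(c)
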