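import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinecage import ctprep
from spinecage.ctprep import (
    CalibrationParams,
    fit_hu_threshold,
    hu_to_porosity_cortical,
    hu_to_porosity_trabecular,
    porosity_field,
    resample_isotropic,
    segment_by_threshold,
)
from spinecage.volume import ImageVolume


@pytest.fixture
def cal():
    return CalibrationParams(
        hu_mode_trab=200.0, hu_min_trab=50.0, hu_threshold=900.0, hu_min_cort=400.0
    )


class TestPorosityLaws:
    def test_trabecular_anchor_points(self, cal):
        assert hu_to_porosity_trabecular(cal.hu_mode_trab, cal) == 0.85
        assert hu_to_porosity_trabecular(cal.hu_min_trab, cal) == 0.92

    def test_trabecular_direct_substitution(self, cal):
        # halfway between mode (200 -> 0.85) and min (50 -> 0.92)
        assert np.isclose(hu_to_porosity_trabecular(125.0, cal), 0.885)

    def test_cortical_anchor_points(self, cal):
        assert hu_to_porosity_cortical(cal.hu_threshold, cal) == 0.0
        assert hu_to_porosity_cortical(cal.hu_min_cort, cal) == 0.5
        assert np.isclose(hu_to_porosity_cortical(650.0, cal), 0.25)

    def test_above_threshold_is_dense_cortical(self, cal):
        assert hu_to_porosity_cortical(2000.0, cal) == 0.0

    @given(
        hu1=st.floats(-500, 3000),
        hu2=st.floats(-500, 3000),
    )
    @settings(max_examples=200, deadline=None)
    def test_porosity_non_increasing_in_hu(self, hu1, hu2):
        cal = CalibrationParams(200.0, 50.0, 900.0, 400.0)
        lo, hi = min(hu1, hu2), max(hu1, hu2)
        assert hu_to_porosity_trabecular(lo, cal) >= hu_to_porosity_trabecular(hi, cal)
        assert hu_to_porosity_cortical(lo, cal) >= hu_to_porosity_cortical(hi, cal)

    def test_matches_per_voxel_oracle_on_random_grid(self, cal, rng):
        hu = rng.uniform(-100, 1500, size=(16, 16, 16))
        vec_t = hu_to_porosity_trabecular(hu, cal)
        vec_c = hu_to_porosity_cortical(hu, cal)
        for idx in np.ndindex(4, 4, 4):  # spot-check a sub-block exhaustively
            h = hu[idx]
            slope = (cal.phi_max_trab - cal.phi_mode_trab) / (
                cal.hu_min_trab - cal.hu_mode_trab
            )
            expect_t = min(
                max(cal.phi_mode_trab + (h - cal.hu_mode_trab) * slope, 0.0), 1.0
            )
            expect_c = min(
                max(
                    (cal.hu_threshold - h)
                    / (cal.hu_threshold - cal.hu_min_cort)
                    * cal.phi_max_cort,
                    0.0,
                ),
                cal.phi_max_cort,
            )
            assert vec_t[idx] == pytest.approx(expect_t, abs=1e-15)
            assert vec_c[idx] == pytest.approx(expect_c, abs=1e-15)

    def test_recovery_matches_phantom_truth_inside_labels(self, small_phantom):
        _, vol, truth = small_phantom
        cal = truth.calibration
        trab = truth.labels == ctprep.TRABECULAR
        cort = truth.labels == ctprep.CORTICAL
        field = porosity_field(vol, trab, cort, cal)
        assert np.abs(field.porosity[trab] - truth.porosity_truth[trab]).max() < 1e-12
        assert np.abs(field.porosity[cort] - truth.porosity_truth[cort]).max() < 1e-12
        assert np.all(field.porosity[truth.labels == 0] == 0.0)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            CalibrationParams(200.0, 250.0, 900.0, 400.0)


class TestResampling:
    def test_constant_volume_resamples_exactly(self):
        vol = ImageVolume(np.full((8, 8, 6), 7.5), (0.326, 0.326, 0.6))
        out = resample_isotropic(vol, 0.326)
        assert np.allclose(out.values, 7.5, atol=1e-9)
        assert out.spacing == (0.326, 0.326, 0.326)

    def test_identity_resampling_preserves_values(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 100, (10, 10, 10))
        vol = ImageVolume(v, (0.5, 0.5, 0.5))
        out = resample_isotropic(vol, 0.5)
        assert out.shape == vol.shape
        assert np.abs(out.values - v).max() < 1e-6 * 100

    def test_linear_ramp_reproduced_by_cubic_bspline(self):
        # B-splines reproduce linear functions exactly (to interpolation eps)
        z = np.arange(40) * 0.6
        v = np.broadcast_to(z, (6, 6, 40)).copy()
        vol = ImageVolume(v, (0.326, 0.326, 0.6))
        out = resample_isotropic(vol, 0.326)
        zc = out.origin[2] + 0.326 * np.arange(out.shape[2])
        # B-spline prefilter edge effects decay geometrically; test the
        # interior away from the axial boundaries
        inner = (zc > 5.0) & (zc < z.max() - 5.0)
        expect = np.broadcast_to(zc, out.shape)[:, :, inner]
        got = out.values[:, :, inner]
        assert np.abs(got - expect).max() < 1e-6 * z.max()

    def test_physical_extent_preserved(self):
        vol = ImageVolume(np.zeros((10, 10, 10)), (0.326, 0.326, 0.6))
        out = resample_isotropic(vol, 0.4)
        for a in range(3):
            assert abs(out.shape[a] * 0.4 - vol.shape[a] * vol.spacing[a]) <= 0.4

    def test_nonfinite_input_rejected(self):
        v = np.zeros((4, 4, 4))
        v[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            ImageVolume(v, (1, 1, 1))
        with pytest.raises(ValueError):
            resample_isotropic(ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1)), -1.0)


class TestSegmentation:
    def test_full_range_selects_everything(self, rng):
        vol = ImageVolume(rng.uniform(-100, 100, (6, 6, 6)), (1, 1, 1))
        assert segment_by_threshold(vol, -np.inf, np.inf).all()

    def test_disjoint_windows_give_disjoint_labels(self, rng):
        vol = ImageVolume(rng.uniform(0, 100, (6, 6, 6)), (1, 1, 1))
        lo = segment_by_threshold(vol, 0, 50)
        hi = segment_by_threshold(vol, 50.001, 100)
        assert not (lo & hi).any()

    def test_cortical_shell_recovered_on_phantom(self, small_phantom):
        spec, vol, truth = small_phantom
        cort_true = truth.labels == ctprep.CORTICAL
        got = segment_by_threshold(
            vol, spec.hu_cortical_range[0] * 0.8, np.inf,
            morphology_ops=[("closing", 1)],
        )
        recall = (got & cort_true).sum() / cort_true.sum()
        assert recall >= 0.95


class TestHuThresholdFit:
    def test_normal_samples_quantile_matches_closed_form(self, rng):
        x = rng.standard_normal(200_000)
        thr, diag = fit_hu_threshold(x, family="normal", cdf_level=0.98)
        assert not diag["fallback"]
        assert thr == pytest.approx(2.0537, abs=0.02)

    def test_median_level_returns_median(self, rng):
        x = rng.normal(100, 10, 50_000)
        thr, _ = fit_hu_threshold(x, family="normal", cdf_level=0.5)
        assert thr == pytest.approx(np.median(x), abs=0.2)

    def test_fallback_returns_empirical_quantile(self, rng):
        # negative data break the gamma fit -> flagged empirical fallback
        x = np.concatenate([rng.normal(-50, 5, 5000), rng.normal(60, 5, 5000)])
        thr, diag = fit_hu_threshold(x, family="gamma", cdf_level=0.98)
        assert diag["fallback"]
        assert thr == pytest.approx(np.quantile(x, 0.98), abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_hu_threshold(np.zeros(50))
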