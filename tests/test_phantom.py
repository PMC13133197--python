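import numpy as np
import pytest

from spinecage.ctprep import CORTICAL, OUTSIDE, TRABECULAR
from spinecage.phantom import (
    PhantomSpec,
    make_two_vertebra_scene,
    make_vertebra_phantom,
)


def small_spec(**kw):
    base = dict(body_half_axes=(10.0, 8.0, 7.0), seed=5)
    base.update(kw)
    return PhantomSpec(**base)


class TestSingleVertebra:
    def test_same_seed_gives_bit_identical_volumes(self):
        v1, t1 = make_vertebra_phantom(small_spec())
        v2, t2 = make_vertebra_phantom(small_spec())
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(t1.labels, t2.labels)

    def test_different_seed_changes_the_volume(self):
        v1, _ = make_vertebra_phantom(small_spec(seed=5))
        v2, _ = make_vertebra_phantom(small_spec(seed=6))
        assert not np.array_equal(v1.values, v2.values)

    def test_trabecular_histogram_unimodal_with_mode_near_target(self, small_phantom):
        spec, vol, truth = small_phantom
        hu = vol.values[truth.labels == TRABECULAR]
        lo = spec.hu_trabecular_mode - 3 * spec.hu_trabecular_spread
        hi = spec.hu_trabecular_mode + 3 * spec.hu_trabecular_spread
        hist, edges = np.histogram(hu, bins=np.arange(lo, hi, 3.0))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(mode - spec.hu_trabecular_mode) <= 0.02 * spec.hu_trabecular_mode
        # unimodality: heavily smoothed histogram rises to its peak and falls
        from scipy.ndimage import gaussian_filter1d

        sm = gaussian_filter1d(hist.astype(float), 4.0)
        k = int(np.argmax(sm))
        tol = 0.02 * sm.max()
        assert np.all(np.diff(sm[: k + 1]) >= -tol)
        assert np.all(np.diff(sm[k:]) <= tol)

    def test_cortical_shell_encloses_trabecular_core(self, small_phantom):
        _, _, truth = small_phantom
        trab = truth.labels == TRABECULAR
        cort = truth.labels == CORTICAL
        assert trab.any() and cort.any()
        # every boundary voxel of the body is cortical: dilate trabecular by
        # one voxel stays inside the body
        from scipy.ndimage import binary_dilation

        grown = binary_dilation(trab)
        assert not (grown & (truth.labels == OUTSIDE)).any()

    def test_truth_fields_have_valid_ranges(self, small_phantom):
        _, _, truth = small_phantom
        inside = truth.labels != OUTSIDE
        assert truth.porosity_truth[inside].min() >= 0.0
        assert truth.porosity_truth[inside].max() <= 1.0
        d = truth.direction_truth[truth.labels == TRABECULAR]
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)

    def test_degenerate_half_axes_rejected(self):
        with pytest.raises(ValueError, match="half-axes"):
            PhantomSpec(body_half_axes=(0.0, 8.0, 7.0))

    def test_isotropic_spec_normalizes_texture_direction(self):
        s = small_spec(texture_direction=(0, 0, 2))
        assert np.allclose(s.texture_direction, (0, 0, 1))

    def test_invalid_anisotropy_rejected(self):
        with pytest.raises(ValueError):
            small_spec(texture_anisotropy=1.0)


class TestTwoVertebraScene:
    def test_gap_thickness_matches_request_within_one_voxel(self):
        spec = small_spec()
        vol, truth = make_two_vertebra_scene(spec, gap_mm=9.0)
        z1, z2 = truth.gap_z
        assert abs((z2 - z1) - 9.0) <= spec.spacing[2] + 1e-9

    def test_minimal_gap_keeps_bodies_disjoint(self):
        spec = small_spec()
        _, truth = make_two_vertebra_scene(spec, gap_mm=0.6)
        lower = (truth.labels == 1) | (truth.labels == 2)
        upper = (truth.labels == 11) | (truth.labels == 12)
        assert lower.any() and upper.any()
        assert not (lower & upper).any()
        # at least one empty slice between them
        zl = np.where(lower.any(axis=(0, 1)))[0].max()
        zu = np.where(upper.any(axis=(0, 1)))[0].min()
        assert zu - zl >= 2

    def test_mirrored_texture_direction_gives_identical_labels(self):
        _, t1 = make_two_vertebra_scene(small_spec(texture_direction=(0, 0, 1)), 9.0)
        _, t2 = make_two_vertebra_scene(small_spec(texture_direction=(0, 0, -1)), 9.0)
        assert np.array_equal(t1.labels, t2.labels)

    def test_zero_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            make_two_vertebra_scene(small_spec(), 0.0)

    def test_footprint_reported_for_scaffold_fitting(self):
        spec = small_spec()
        _, truth = make_two_vertebra_scene(spec, 9.0)
        assert truth.footprint["half_axes_mm"] == spec.body_half_axes[:2]


def test_export_round_trip(tmp_path, small_phantom):
    from spinecage.phantom import export_phantom
    from spinecage.volume import read_volume

    spec, vol, truth = small_phantom
    paths = export_phantom(vol, truth, spec, tmp_path)
    back = read_volume(paths["hu.nii.gz"])
    assert np.allclose(back.values, vol.values, atol=1e-5)
    assert np.allclose(back.spacing, vol.spacing)
    lab = read_volume(paths["labels.nrrd"])
    assert np.array_equal(lab.values.astype(int), truth.labels)
    import yaml

    cfg = yaml.safe_load((tmp_path / "phantom.yaml").read_text())
    assert cfg["seed"] == spec.seed
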