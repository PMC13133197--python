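import numpy as np
import pytest

from spinecage.anisotropy import (
    aspect_ratio,
    boundary_flag,
    gradient_structure_tensor,
    morphologic_anisotropy,
    pooled_fabric,
)
from spinecage.volume import ImageVolume


def brute_force_gst(values, label, spacing, window):
    """Dense loop oracle: windowed average of gradient outer products."""
    g = np.gradient(values.astype(float), *spacing, edge_order=1)
    h = window // 2
    nx, ny, nz = values.shape
    out = np.zeros(values.shape + (3, 3))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = np.zeros((3, 3))
                cnt = 0
                for di in range(-h, h + 1):
                    for dj in range(-h, h + 1):
                        for dk in range(-h, h + 1):
                            # 'nearest' padding at the array border
                            a = min(max(i + di, 0), nx - 1)
                            b = min(max(j + dj, 0), ny - 1)
                            c = min(max(k + dk, 0), nz - 1)
                            if not label[a, b, c]:
                                continue
                            v = np.array([g[0][a, b, c], g[1][a, b, c], g[2][a, b, c]])
                            acc += np.outer(v, v)
                            cnt += 1
                if cnt:
                    out[i, j, k] = acc / cnt
    return out


def test_gst_eigenvalues_match_dense_oracle_on_random_volume(rng):
    values = rng.standard_normal((9, 9, 9))
    label = np.ones((9, 9, 9), bool)
    vol = ImageVolume(values, (0.5, 0.5, 0.5))
    fab = gradient_structure_tensor(vol, label, window=3)
    ref = brute_force_gst(values, label, vol.spacing, 3)
    act = ~fab.isotropic & label
    for idx in np.argwhere(act)[::7]:
        t = ref[tuple(idx)]
        t = t / np.trace(t)
        w = np.linalg.eigvalsh(t)
        assert np.abs(np.sort(w) - fab.eigenvalues[tuple(idx)]).max() < 1e-10


def test_constant_volume_flags_everything_isotropic():
    vol = ImageVolume(np.full((12, 12, 12), 42.0), (1, 1, 1))
    lab = np.ones((12, 12, 12), bool)
    fab = gradient_structure_tensor(vol, lab)
    assert fab.isotropic.all()
    assert np.all(fab.DA == 0.0)
    assert np.all(fab.R == 1.0)


def test_pure_z_gradient_gives_e3_along_z():
    z = np.arange(16, dtype=float)
    vol = ImageVolume(np.broadcast_to(z, (16, 16, 16)).copy(), (1, 1, 1))
    lab = np.ones((16, 16, 16), bool)
    fab = gradient_structure_tensor(vol, lab)
    act = ~fab.isotropic
    assert act.any()
    # lambda1 = lambda2 = 0; max eigenvector parallel to z
    assert np.abs(fab.eigenvalues[act][:, :2]).max() < 1e-12
    e3 = fab.eigenvectors[act][:, :, 2]
    assert np.abs(np.abs(e3[:, 2]) - 1.0).max() < 1e-10


def test_axis_permuted_volume_permutes_eigenvectors(rng):
    # exact equivariance under a 90 degree grid rotation (x <-> z)
    v = rng.standard_normal((14, 14, 14))
    from scipy.ndimage import gaussian_filter

    v = gaussian_filter(v, 1.2)
    lab = np.ones(v.shape, bool)
    fab = gradient_structure_tensor(ImageVolume(v, (1, 1, 1)), lab)
    vol_rot = ImageVolume(np.transpose(v, (2, 1, 0)), (1, 1, 1))
    fab_rot = gradient_structure_tensor(vol_rot, lab)
    i = (7, 6, 5)
    irot = (5, 6, 7)
    assert np.allclose(
        np.sort(fab.eigenvalues[i]), np.sort(fab_rot.eigenvalues[irot]), atol=1e-10
    )
    e1 = fab.eigenvectors[i][:, 0]
    e1r = fab_rot.eigenvectors[irot][:, 0]
    assert np.isclose(abs(np.dot(e1[::-1], e1r)), 1.0, atol=1e-8)


class TestBoundaryFlag:
    def test_interior_of_large_region_not_flagged(self):
        lab = np.zeros((21, 21, 21), bool)
        lab[2:-2, 2:-2, 2:-2] = True
        flags = boundary_flag(lab, window=7)
        assert not flags[10, 10, 10]

    def test_half_space_boundary_flagged_matches_counting_oracle(self):
        lab = np.zeros((20, 20, 20), bool)
        lab[:, :, :10] = True  # half-space; windows at the face are ~50% out
        flags = boundary_flag(lab, window=7, max_outside_fraction=0.25)
        assert flags[10, 10, 9]
        # voxel 3 layers deep: window spans k in [4, 10] -> 1/7 outside < 25%
        assert not flags[10, 10, 6]
        # counting oracle at the face voxel: 3 of 7 planes outside
        assert 3 / 7 > 0.25

    def test_unit_outside_fraction_flags_nothing(self):
        lab = np.zeros((10, 10, 10), bool)
        lab[5, 5, 5] = True
        assert not boundary_flag(lab, window=7, max_outside_fraction=1.0).any()


class TestAnisotropyMeasures:
    @pytest.mark.parametrize(
        "lam1, lam3, da", [(1.0, 1.0, 0.0), (0.0, 2.0, 1.0), (1.0, 4.0, 0.75)]
    )
    def test_degree_of_anisotropy(self, lam1, lam3, da):
        assert morphologic_anisotropy(lam1, lam3) == pytest.approx(da)

    @pytest.mark.parametrize("lam1, lam3, r", [(1.0, 1.0, 1.0), (1.0, 3.0, 3.0)])
    def test_aspect_ratio(self, lam1, lam3, r):
        assert aspect_ratio(lam1, lam3) == pytest.approx(r)
        if r == 1.0:
            assert np.degrees(np.arctan(r)) == pytest.approx(45.0)

    def test_aspect_ratio_capped_for_degenerate_lambda1(self):
        assert aspect_ratio(0.0, 1.0) == 10.0
        assert aspect_ratio(1e-9, 1.0, r_max=5.0) == 5.0

    def test_da_from_reported_mean_aspect_ratio(self):
        # DA = 0.38 <=> lambda1/lambda3 = 0.62 <=> R ~ 1.61
        assert aspect_ratio(0.62, 1.0) == pytest.approx(1.6129, abs=1e-3)


def test_da_invariant_under_intensity_scaling(rng):
    v = rng.standard_normal((12, 12, 12))
    lab = np.ones(v.shape, bool)
    f1 = gradient_structure_tensor(ImageVolume(v, (1, 1, 1)), lab)
    f2 = gradient_structure_tensor(ImageVolume(1000.0 * v, (1, 1, 1)), lab)
    act = ~f1.isotropic
    assert np.abs(f1.DA[act] - f2.DA[act]).max() < 1e-9


def test_pooled_fabric_empty_label_returns_neutral():
    vol = ImageVolume(np.zeros((8, 8, 8)), (1, 1, 1))
    lab = np.zeros((8, 8, 8), bool)
    fab = gradient_structure_tensor(vol, lab)
    pooled = pooled_fabric(fab)
    assert pooled["DA"] == 0.0 and pooled["n_voxels"] == 0


def test_window_larger_than_volume_rejected():
    vol = ImageVolume(np.zeros((5, 5, 5)), (1, 1, 1))
    with pytest.raises(ValueError):
        gradient_structure_tensor(vol, np.ones((5, 5, 5), bool), window=7)
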