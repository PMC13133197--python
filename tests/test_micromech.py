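import numpy as np
import pytest

from spinecage.micromech import (
    CorticalModelParams,
    ElasticityField,
    cortical_stiffness,
    dilute_estimate,
    isotropic_fallback_stiffness,
    mori_tanaka,
    nearest_voxel_assign,
    _water_stiffness,
)
from spinecage.tetmesh import mesh_from_labels
from spinecage.voigt import is_positive_definite, isotropic_stiffness, voigt_to_mandel


PARAMS = CorticalModelParams()
C_MATRIX = isotropic_stiffness(20.0, 0.3)


class TestCorticalModel:
    def test_zero_porosity_returns_matrix_exactly(self):
        assert np.allclose(cortical_stiffness(0.0), C_MATRIX, atol=1e-12)
        assert np.allclose(isotropic_fallback_stiffness(0.0), C_MATRIX, atol=1e-12)

    def test_dilute_limit_matches_first_order_eshelby(self):
        f = 1e-4
        water = _water_stiffness(PARAMS)
        for shape, fn in (
            ("cylinder", cortical_stiffness),
            ("sphere", isotropic_fallback_stiffness),
        ):
            mt = fn(f)
            dil = dilute_estimate(C_MATRIX, water, f, shape, 0.3)
            # MT and dilute agree to O(f^2)
            assert np.abs(mt - dil).max() < 10 * f**2 * C_MATRIX.max() / f
            assert np.abs(mt - dil).max() < 1e-4

    def test_cylinder_model_transversely_isotropic_about_axis3(self):
        C = cortical_stiffness(0.1)
        assert np.isclose(C[0, 0], C[1, 1])
        assert np.isclose(C[3, 3], C[4, 4])
        assert not np.isclose(C[0, 0], C[2, 2])  # axial stiffer than transverse
        assert C[2, 2] > C[0, 0]

    def test_axial_modulus_in_reported_cortical_band(self):
        # porosity 0.05-0.15 -> highest modulus component ~15-19 GPa
        for phi in (0.05, 0.10, 0.15):
            S = np.linalg.inv(cortical_stiffness(phi))
            E_ax = 1 / S[2, 2]
            E_tr = 1 / S[0, 0]
            assert 15.0 < E_ax < 19.5
            assert E_tr < E_ax

    def test_porosity_above_cortical_max_clamped(self):
        assert np.allclose(cortical_stiffness(0.7), cortical_stiffness(0.5))

    def test_sphere_model_isotropic_and_vanishing_shear_limit(self):
        C = isotropic_fallback_stiffness(0.3)
        assert np.isclose(C[0, 0], C[1, 1])
        assert np.isclose(C[3, 3], C[4, 4])
        assert np.isclose(C[3, 3], C[5, 5])
        assert np.isclose(C[0, 1], C[0, 2])
        G_high = isotropic_fallback_stiffness(0.99)[3, 3]
        assert G_high < 0.05 * C_MATRIX[3, 3]

    def test_sphere_mt_matches_scalar_bulk_shear_closed_form(self):
        # classic Mori-Tanaka K*, G* for spherical inclusions
        phi = 0.3
        E, nu = 20.0, 0.3
        Km, Gm = E / (3 * (1 - 2 * nu)), E / (2 * (1 + nu))
        Ki, Gi = 2.3, 0.0
        K_mt = Km + phi * (Ki - Km) * (3 * Km + 4 * Gm) / (
            3 * Km + 4 * Gm + 3 * (1 - phi) * (Ki - Km)
        )
        zeta = Gm * (9 * Km + 8 * Gm) / (6 * (Km + 2 * Gm))
        G_mt = Gm + phi * (Gi - Gm) * (Gm + zeta) / (
            Gm + zeta + (1 - phi) * (Gi - Gm)
        )
        C = isotropic_fallback_stiffness(phi)
        K_got = C[:3, :3].sum() / 9
        G_got = C[3, 3]
        assert K_got == pytest.approx(K_mt, rel=1e-10)
        assert G_got == pytest.approx(G_mt, rel=1e-10)

    def test_result_below_voigt_bound(self):
        for phi in (0.1, 0.3, 0.45):
            C = isotropic_fallback_stiffness(phi)
            bound = (1 - phi) * C_MATRIX + phi * _water_stiffness(PARAMS)
            w_c = np.linalg.eigvalsh(voigt_to_mandel(C))
            w_b = np.linalg.eigvalsh(voigt_to_mandel(bound))
            assert w_c.max() <= w_b.max() * (1 + 1e-9)

    def test_moduli_monotone_in_porosity(self):
        phis = np.linspace(0, 0.45, 8)
        Cs = [cortical_stiffness(p) for p in phis]
        for a, b in zip(Cs, Cs[1:]):
            assert b[2, 2] <= a[2, 2] + 1e-12
            assert b[3, 3] <= a[3, 3] + 1e-12

    def test_symmetric_positive_definite(self):
        for phi in (0.0, 0.2, 0.49):
            for C in (cortical_stiffness(phi), isotropic_fallback_stiffness(phi)):
                assert np.abs(C - C.T).max() < 1e-9 * np.abs(C).max()
                assert is_positive_definite(C)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cortical_stiffness(-0.1)
        with pytest.raises(ValueError):
            isotropic_fallback_stiffness(1.0)
        with pytest.raises(ValueError):
            mori_tanaka(C_MATRIX, C_MATRIX, 0.1, "cube", 0.3)


class TestNearestVoxelAssign:
    def _field(self, idx, Cs, shape, spacing=(1.0, 1.0, 1.0)):
        return ElasticityField(
            voxel_indices=np.asarray(idx),
            stiffness=np.asarray(Cs),
            symmetry_class=np.array(["isotropic"] * len(idx)),
            shape=shape,
            spacing=spacing,
        )

    def test_centroid_at_voxel_centre_gets_that_voxel(self):
        lab = np.ones((2, 2, 2), np.uint8)
        mesh = mesh_from_labels(lab, (1, 1, 1))
        idx = np.argwhere(lab > 0)
        Cs = np.stack([np.eye(6) * (i + 1) for i in range(len(idx))])
        fld = self._field(idx, Cs, lab.shape)
        C, pick, outside = nearest_voxel_assign(mesh, fld)
        assert not outside.any()
        centers = idx + 0.0  # voxel centres at index * spacing
        for e in range(mesh.n_elements):
            d = np.linalg.norm(centers - mesh.centroids()[e], axis=1)
            best = np.min(d)
            cands = np.where(np.isclose(d, best, atol=1e-12))[0]
            assert pick[e] in cands

    def test_uniform_field_gives_identical_materials(self):
        lab = np.ones((2, 2, 2), np.uint8)
        mesh = mesh_from_labels(lab, (1, 1, 1))
        idx = np.argwhere(lab > 0)
        C0 = isotropic_stiffness(5.0, 0.3)
        fld = self._field(idx, np.broadcast_to(C0, (len(idx), 6, 6)).copy(), lab.shape)
        C, _, _ = nearest_voxel_assign(mesh, fld)
        assert np.allclose(C, C0)

    def test_two_voxel_field_matches_exhaustive_oracle(self, rng):
        lab = np.ones((4, 4, 4), np.uint8)
        mesh = mesh_from_labels(lab, (0.7, 0.7, 0.7))
        idx = np.array([[0, 0, 0], [3, 3, 3]])
        Cs = np.stack([np.eye(6), 2 * np.eye(6)])
        fld = self._field(idx, Cs, lab.shape, spacing=(0.7, 0.7, 0.7))
        C, pick, _ = nearest_voxel_assign(mesh, fld)
        centers = idx * 0.7
        for e, cent in enumerate(mesh.centroids()):
            d = np.linalg.norm(centers - cent, axis=1)
            assert pick[e] == int(np.argmin(d))

    def test_empty_field_rejected(self):
        lab = np.ones((1, 1, 1), np.uint8)
        mesh = mesh_from_labels(lab, (1, 1, 1))
        fld = self._field(np.zeros((0, 3), int), np.zeros((0, 6, 6)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            nearest_voxel_assign(mesh, fld)
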