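import numpy as np
import pytest

from spinecage.damage import (
    DamageReport,
    DamageThresholds,
    damaged_trabecular_volume,
    failed_volume,
    fixation_metrics,
    macroscopic_response,
    von_mises,
)


THR = DamageThresholds(tension=100.0, compression=350.0)


def make_principal(n, smax=0.0, smin=0.0):
    ps = np.zeros((n, 3))
    ps[:, 2] = smax
    ps[:, 0] = smin
    return ps


class TestFailedVolume:
    def test_zero_stress_gives_zero_percent(self):
        ps = make_principal(10)
        assert failed_volume(ps, np.ones(10), THR) == 0.0

    def test_exactly_ten_percent_of_volume_above_threshold(self):
        # counting oracle: element volumes sum to 100; 10 units exceed
        ps = make_principal(20)
        ps[:2, 2] = 150.0  # two elements, volume 5 each -> 10%
        vols = np.full(20, 5.0)
        assert failed_volume(ps, vols, THR, "tension") == pytest.approx(10.0)

    def test_union_at_least_each_single_mode(self):
        rngl = np.random.default_rng(3)
        ps = np.sort(rngl.normal(0, 200, (50, 3)), axis=1)
        vols = rngl.uniform(0.5, 2.0, 50)
        t = failed_volume(ps, vols, THR, "tension")
        c = failed_volume(ps, vols, THR, "compression")
        u = failed_volume(ps, vols, THR, "either")
        assert u >= max(t, c) - 1e-12
        assert u <= t + c + 1e-12

    def test_percentages_non_decreasing_as_thresholds_decrease(self):
        rngl = np.random.default_rng(4)
        ps = np.sort(rngl.normal(0, 120, (100, 3)), axis=1)
        vols = np.ones(100)
        loose = failed_volume(ps, vols, DamageThresholds(200.0, 500.0))
        tight = failed_volume(ps, vols, DamageThresholds(50.0, 100.0))
        assert tight >= loose

    def test_empty_scaffold_set_rejected(self):
        with pytest.raises(ValueError):
            failed_volume(np.zeros((0, 3)), np.zeros(0), THR)


class TestTrabecularDamage:
    def test_zero_strain_gives_zero(self):
        assert damaged_trabecular_volume(np.zeros((5, 3)), np.ones(5)) == 0.0

    def test_uniform_compressive_strain_beyond_limit_gives_100(self):
        ps = make_principal(8, smin=-0.01)
        assert damaged_trabecular_volume(ps, np.ones(8)) == 100.0

    def test_constructed_quarter_exceedance(self):
        ps = make_principal(8)
        ps[:2, 0] = -0.02  # 2 of 8 equal-volume elements
        assert damaged_trabecular_volume(ps, np.ones(8)) == pytest.approx(25.0)


class _FakeMesh:
    def __init__(self, cents, vols):
        self._c = cents
        self._v = vols

    def centroids(self):
        return self._c

    def volumes(self):
        return self._v


class _FakeResult:
    def __init__(self, stress, strain):
        self.stress = stress
        self.strain = strain


class TestFixationMetrics:
    def _two_rods(self, sigma_zz):
        # two vertical rods of 10 elements each, unit volumes
        z = np.tile(np.arange(10, dtype=float), 2)
        x = np.r_[np.full(10, -1.0), np.full(10, 1.0)]
        cents = np.c_[x, np.zeros(20), z]
        mesh = _FakeMesh(cents, np.ones(20))
        stress = np.zeros((20, 6))
        stress[:, 2] = sigma_zz
        strain = np.zeros((20, 6))
        strain[:, 2] = sigma_zz / 110e3
        res = _FakeResult(stress, strain)
        sets = {"left": np.arange(10), "right": np.arange(10, 20)}
        return mesh, res, sets

    def test_unloaded_model_reports_capped_yield_ratio(self):
        mesh, res, sets = self._two_rods(0.0)
        out = fixation_metrics(mesh, res, sets, applied_axial=500.0)
        assert out["yield_ratio"] == 1e6
        assert out["load_share_pct"] == 0.0

    def test_symmetric_rods_carry_equal_shares(self):
        mesh, res, sets = self._two_rods(-10.0)
        out = fixation_metrics(mesh, res, sets, applied_axial=500.0)
        fl = out["per_rod"]["left"]["axial_force_N"]
        fr = out["per_rod"]["right"]["axial_force_N"]
        assert fl == pytest.approx(fr)
        assert out["load_share_pct"] > 0

    def test_missing_rod_set_rejected(self):
        mesh, res, sets = self._two_rods(-1.0)
        with pytest.raises(ValueError):
            fixation_metrics(mesh, res, {}, 500.0)
        with pytest.raises(ValueError):
            fixation_metrics(mesh, res, {"left": np.array([], int)}, 500.0)


class TestMacroscopicResponse:
    def test_linear_spring_surrogate_recovers_stiffness(self):
        class R:
            rp_u = np.array([0.0, 0.0, -0.05])
            rp_theta = np.array([0.0, 0.0, 0.0])

        class L:
            axial_force = 500.0

        out = macroscopic_response(R(), L())
        assert out["stiffness_kN_mm"] == pytest.approx(10.0)
        assert out["rotation_deg"] == 0.0

    def test_zero_displacement_rejected(self):
        class R:
            rp_u = np.array([0.0, 0.0, 0.0])
            rp_theta = np.zeros(3)

        class L:
            axial_force = 500.0

        with pytest.raises(ValueError):
            macroscopic_response(R(), L())


def test_von_mises_of_hydrostatic_state_is_zero():
    s = np.array([[50.0, 50.0, 50.0, 0, 0, 0]])
    assert von_mises(s)[0] == pytest.approx(0.0)


def test_homogenized_thresholds_follow_strength_law():
    thr = DamageThresholds.homogenized(0.75)
    assert thr.tension == pytest.approx(1.890625)
    assert thr.compression == pytest.approx(6.6171875)


def test_report_percentage_validation_and_io(tmp_path):
    with pytest.raises(ValueError):
        DamageReport(failed_volume_pct=120.0)
    rep = DamageReport(failed_volume_pct=1.0, stiffness_kN_mm=10.0)
    rep.to_json(tmp_path / "r.json")
    rep.to_csv(tmp_path / "r.csv")
    import json

    back = json.loads((tmp_path / "r.json").read_text())
    assert back["failed_volume_pct"] == 1.0
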