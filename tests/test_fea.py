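import numpy as np
import pytest

from spinecage.fea import (
    LoadCase,
    assemble_stiffness,
    element_B,
    principal_values,
    solve_linear_static,
)
from spinecage.tetmesh import mesh_from_labels
from spinecage.voigt import isotropic_stiffness

E, NU = 1000.0, 0.3
C_ISO = isotropic_stiffness(E, NU)


def test_patch_test_constant_strain_reproduced_exactly():
    """Affine displacement fields produce the exact constant strain/stress."""
    mesh = mesh_from_labels(np.ones((2, 2, 2), np.uint8), (0.7, 0.9, 1.1))
    Em = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4], [0.0, 1e-4, 3e-4]])
    u = mesh.nodes @ Em.T
    B, _ = element_B(mesh)
    ue = u[mesh.elements].reshape(-1, 12)
    strain = np.einsum("mab,mb->ma", B, ue)
    expect = np.array(
        [Em[0, 0], Em[1, 1], Em[2, 2], 2 * Em[1, 2], 2 * Em[0, 2], 2 * Em[0, 1]]
    )
    assert np.abs(strain - expect).max() < 1e-10
    stress = C_ISO @ expect
    got = np.einsum("ij,mj->mi", C_ISO, strain)
    assert np.abs(got - stress).max() < 1e-10 * np.abs(stress).max()


def test_isotropic_block_under_uniaxial_load_matches_closed_form():
    mesh = mesh_from_labels(np.ones((4, 4, 8), np.uint8), (1, 1, 1))
    zmax = mesh.nodes[:, 2].max()
    bottom = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].min()))[0]
    top = np.where(np.isclose(mesh.nodes[:, 2], zmax))[0]
    load = LoadCase("standing", axial_force=100.0, reference_point=(2, 2, zmax + 2))
    res = solve_linear_static(mesh, C_ISO, bottom, load, coupled_nodes=top)
    assert res.equilibrium_residual < 1e-6
    assert res.stress[:, 2].mean() == pytest.approx(-100.0 / 16.0, rel=1e-9)
    # interior lateral strain ratio approaches -nu (clamped ends perturb it)
    ratio = res.strain[:, 0].mean() / res.strain[:, 2].mean()
    assert ratio == pytest.approx(-NU, abs=0.08)


def test_cantilever_tip_deflection_within_10pct_of_euler_bernoulli():
    h, s, L = 0.25, 2.0, 20.0
    mesh = mesh_from_labels(np.ones((int(s / h), int(s / h), int(L / h)), np.uint8), (h, h, h))
    bottom = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].min()))[0]
    tip = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].max()))[0]
    f = np.zeros((mesh.n_nodes, 3))
    f[tip, 0] = 1.0 / len(tip)
    res = solve_linear_static(mesh, C_ISO, bottom, nodal_forces=f)
    tip_u = res.u[tip, 0].mean()
    euler = 1.0 * L**3 / (3 * E * (s**4 / 12))
    assert abs(tip_u - euler) / euler < 0.10


def test_sparse_assembly_matches_dense_reference(rng):
    """Oracle: dense per-element assembly on a small mesh (<500 elements)."""
    lab = (rng.random((3, 3, 4)) > 0.3).astype(np.uint8)
    lab[1, 1, 1] = 1
    mesh = mesh_from_labels(lab, (0.8, 1.0, 1.2))
    C = np.stack([isotropic_stiffness(100 + 50 * rng.random(), 0.3)
                  for _ in range(mesh.n_elements)])
    K = assemble_stiffness(mesh, C).toarray()
    B, vol = element_B(mesh)
    Kd = np.zeros_like(K)
    for e in range(mesh.n_elements):
        ke = B[e].T @ C[e] @ B[e] * vol[e]
        dofs = np.concatenate([3 * n + np.arange(3) for n in mesh.elements[e]])
        Kd[np.ix_(dofs, dofs)] += ke
    assert np.abs(K - Kd).max() < 1e-8 * np.abs(Kd).max()


def test_global_equilibrium_reactions_balance_applied_load():
    mesh = mesh_from_labels(np.ones((3, 3, 6), np.uint8), (1, 1, 1))
    bottom = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].min()))[0]
    top = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].max()))[0]
    load = LoadCase("standing", 250.0, reference_point=(1.5, 1.5, 8.0))
    res = solve_linear_static(mesh, C_ISO, bottom, load, coupled_nodes=top)
    K = assemble_stiffness(mesh, C_ISO)
    r = (K @ res.u.ravel()).reshape(-1, 3)
    reactions = r[bottom].sum(axis=0)
    assert np.allclose(reactions + load.force_vector(), 0.0, atol=1e-6 * 250)


def test_doubling_load_doubles_displacement():
    mesh = mesh_from_labels(np.ones((3, 3, 5), np.uint8), (1, 1, 1))
    bottom = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].min()))[0]
    top = np.where(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].max()))[0]
    res1 = solve_linear_static(
        mesh, C_ISO, bottom,
        LoadCase("a", 100.0, reference_point=(1.5, 1.5, 7)), coupled_nodes=top,
    )
    res2 = solve_linear_static(
        mesh, C_ISO, bottom,
        LoadCase("b", 200.0, reference_point=(1.5, 1.5, 7)), coupled_nodes=top,
    )
    assert np.allclose(res2.u, 2 * res1.u, atol=1e-10)


def test_unconstrained_model_reports_singularity():
    mesh = mesh_from_labels(np.ones((2, 2, 2), np.uint8), (1, 1, 1))
    with pytest.raises(RuntimeError, match="singular|converge"):
        f = np.zeros((mesh.n_nodes, 3))
        f[0, 2] = 1.0
        solve_linear_static(mesh, C_ISO, np.array([], int), nodal_forces=f)


def test_principal_values_match_eigendecomposition(rng):
    v = rng.standard_normal((20, 6))
    ps = principal_values(v, engineering=False)
    for k in range(20):
        t = np.array(
            [
                [v[k, 0], v[k, 5], v[k, 4]],
                [v[k, 5], v[k, 1], v[k, 3]],
                [v[k, 4], v[k, 3], v[k, 2]],
            ]
        )
        assert np.allclose(np.sort(np.linalg.eigvalsh(t)), ps[k])


def test_flexion_load_case_moment_magnitude_and_direction():
    lc = LoadCase.flexion((0, 0, 10))
    assert lc.axial_force == 1175.0
    assert np.allclose(lc.moment_vector(), [-7500.0, 0.0, 0.0])
    assert np.allclose(LoadCase.standing((0, 0, 1)).force_vector(), [0, 0, -500.0])
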