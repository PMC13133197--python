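"""Voigt-notation elasticity helpers.

Every 6x6 stiffness matrix in this package uses the Voigt convention
(11, 22, 33, 23, 13, 12) with engineering shear strains, so that
``sigma = C @ [e11, e22, e33, 2*e23, 2*e13, 2*e12]``.  Internally,
fourth-order tensor algebra (rotation, Eshelby/Mori-Tanaka products) is done
in the orthonormal Mandel basis where matrix products equal tensor
double-contractions; conversion happens only at module boundaries.
"""

from __future__ import annotations

import numpy as np

VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))

_SQRT2 = np.sqrt(2.0)
# Mandel scaling: factors sqrt(2) on shear rows/columns of the Voigt matrix.
_MANDEL_SCALE = np.diag([1.0, 1.0, 1.0, _SQRT2, _SQRT2, _SQRT2])


def check_voigt(C: np.ndarray, *, tol: float = 1e-9, name: str = "C") -> np.ndarray:
    """Validate a 6x6 Voigt stiffness: shape, finiteness, symmetry."""
    C = np.asarray(C, dtype=float)
    if C.shape != (6, 6):
        raise ValueError(f"{name} must be 6x6, got {C.shape}")
    if not np.all(np.isfinite(C)):
        raise ValueError(f"{name} contains non-finite entries")
    scale = max(1.0, np.abs(C).max())
    if np.abs(C - C.T).max() > tol * scale:
        raise ValueError(f"{name} is not symmetric within {tol}")
    return 0.5 * (C + C.T)


def voigt_to_mandel(C: np.ndarray) -> np.ndarray:
    return _MANDEL_SCALE @ np.asarray(C, float) @ _MANDEL_SCALE


def mandel_to_voigt(M: np.ndarray) -> np.ndarray:
    inv = np.diag(1.0 / np.diag(_MANDEL_SCALE))
    return inv @ np.asarray(M, float) @ inv


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic stiffness from Young's modulus and Poisson's ratio."""
    if E <= 0:
        raise ValueError("E must be positive")
    if not -1.0 < nu < 0.5:
        raise ValueError("nu must lie in (-1, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def isotropic_from_KG(K: float, G: float) -> np.ndarray:
    """Isotropic stiffness from bulk and shear moduli (G may be 0, e.g. water)."""
    lam = K - 2.0 * G / 3.0
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * G
    C[3, 3] = C[4, 4] = C[5, 5] = G
    return C


def transversely_isotropic_stiffness(
    E_axial: float,
    E_trans: float,
    nu_axial: float,
    nu_trans: float,
    G_axial: float,
    axis: int = 2,
) -> np.ndarray:
    """Transversely isotropic stiffness from engineering constants.

    ``E_axial`` acts along ``axis`` (default z); ``nu_axial`` couples the axis
    with the transverse plane (nu_31 in the z-axis convention: transverse
    strain per axial strain), ``nu_trans`` is the in-plane ratio and
    ``G_axial`` the out-of-plane shear modulus.  Built by inverting the
    compliance matrix, then permuted so the symmetry axis lands on ``axis``.
    """
    for v, n in ((E_axial, "E_axial"), (E_trans, "E_trans"), (G_axial, "G_axial")):
        if v <= 0:
            raise ValueError(f"{n} must be positive")
    Ea, Et = float(E_axial), float(E_trans)
    S = np.zeros((6, 6))
    # symmetry axis = 3 while building
    S[0, 0] = S[1, 1] = 1 / Et
    S[2, 2] = 1 / Ea
    S[0, 1] = S[1, 0] = -nu_trans / Et
    S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -nu_axial / Ea
    S[3, 3] = S[4, 4] = 1 / G_axial
    S[5, 5] = 2 * (1 + nu_trans) / Et
    C = np.linalg.inv(S)
    if axis == 2:
        return C
    perm = {0: (2, 1, 0), 1: (0, 2, 1)}[axis]
    Q = np.zeros((3, 3))
    for i, j in enumerate(perm):
        Q[i, j] = 1.0
    return rotate_stiffness(C, Q.T)


def rotation_matrix_voigt(Q: np.ndarray) -> np.ndarray:
    """6x6 Mandel-basis rotation operator for a 3x3 rotation ``Q``.

    ``Q`` maps local-frame components to world-frame components
    (columns of Q = local basis vectors expressed in world coordinates).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (3, 3):
        raise ValueError("Q must be 3x3")
    if np.abs(Q @ Q.T - np.eye(3)).max() > 1e-6:
        raise ValueError("basis is not orthonormal within 1e-6")
    R = np.zeros((6, 6))
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            if a < 3 and b < 3:
                R[a, b] = Q[i, k] * Q[j, l]
            elif a < 3:  # b is a shear pair
                R[a, b] = _SQRT2 * Q[i, k] * Q[i, l]
            elif b < 3:  # a is a shear pair
                R[a, b] = _SQRT2 * Q[i, k] * Q[j, k]
            else:
                R[a, b] = Q[i, k] * Q[j, l] + Q[i, l] * Q[j, k]
    return R


def rotate_stiffness(C_local: np.ndarray, eigvecs: np.ndarray) -> np.ndarray:
    """Rotate a Voigt stiffness from a local frame into world axes.

    ``eigvecs`` columns are the local basis vectors in world coordinates.
    Symmetry and positive-definiteness are preserved exactly (orthogonal
    conjugation in the Mandel basis).
    """
    C = check_voigt(C_local, name="C_local")
    R = rotation_matrix_voigt(eigvecs)
    M = voigt_to_mandel(C)
    return mandel_to_voigt(R @ M @ R.T)


def is_positive_definite(C: np.ndarray, tol: float = 0.0) -> bool:
    w = np.linalg.eigvalsh(voigt_to_mandel(0.5 * (C + C.T)))
    return bool(w.min() > tol)
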