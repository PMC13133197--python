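"""Voxel-level micromechanics: cortical inclusion models and material mapping.

Cortical bone is modelled as a stiff isotropic mineralized matrix containing
water-filled inclusions: infinite circular cylinders (Haversian canals) for
voxels with a reliable stiffness direction, spheres for voxels flagged
isotropic.  Both use the Mori-Tanaka mean-field scheme built on the Eshelby
interior-point tensor of the inclusion shape; the water phase has a finite
bulk modulus and zero shear modulus.

Trabecular voxels use the anisotropic Kelvin-cell foam model (see
``spinecage.kelvin``).  Mapping onto tetrahedral meshes follows the nearest
voxel strategy: each element inherits the stiffness of the voxel whose centre
is closest to the element centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .voigt import (
    VOIGT_PAIRS,
    check_voigt,
    isotropic_from_KG,
    isotropic_stiffness,
    mandel_to_voigt,
    rotate_stiffness,
    transversely_isotropic_stiffness,
    voigt_to_mandel,
)

log = logging.getLogger(__name__)

WATER_BULK_GPA = 2.3  # bulk modulus of water, GPa


@dataclass
class CorticalModelParams:
    """Matrix and inclusion description for the cortical model (GPa units)."""

    matrix_E: float = 20.0  # GPa
    matrix_nu: float = 0.3
    inclusion_bulk: float = WATER_BULK_GPA  # GPa (water; zero shear)
    phi_max: float = 0.5

    def __post_init__(self) -> None:
        if self.matrix_E <= 0:
            raise ValueError("matrix_E must be positive")
        if not 0 < self.matrix_nu < 0.5:
            raise ValueError("matrix_nu must lie in (0, 0.5)")


def _eshelby_tensor(shape: str, nu: float) -> np.ndarray:
    """Interior Eshelby tensor (Mandel 6x6) for sphere / infinite cylinder.

    The cylinder axis is the local 3-axis.  Components are the classical
    isotropic-matrix results; minor symmetries hold, major symmetry does not.
    """
    S = np.zeros((3, 3, 3, 3))

    def set_(i, j, k, l, v):
        S[i, j, k, l] = v
        S[j, i, k, l] = v
        S[i, j, l, k] = v
        S[j, i, l, k] = v

    if shape == "sphere":
        a = (7 - 5 * nu) / (15 * (1 - nu))
        b = (5 * nu - 1) / (15 * (1 - nu))
        c = (4 - 5 * nu) / (15 * (1 - nu))
        for i in range(3):
            set_(i, i, i, i, a)
        for i in range(3):
            for j in range(3):
                if i != j:
                    set_(i, i, j, j, b)
        set_(0, 1, 0, 1, c)
        set_(0, 2, 0, 2, c)
        set_(1, 2, 1, 2, c)
    elif shape == "cylinder":
        d = 8 * (1 - nu)
        set_(0, 0, 0, 0, (5 - 4 * nu) / d)
        set_(1, 1, 1, 1, (5 - 4 * nu) / d)
        set_(0, 0, 1, 1, (4 * nu - 1) / d)
        set_(1, 1, 0, 0, (4 * nu - 1) / d)
        set_(0, 0, 2, 2, nu / (2 * (1 - nu)))
        set_(1, 1, 2, 2, nu / (2 * (1 - nu)))
        # S_33kl = 0 (plane strain along the cylinder axis)
        set_(0, 1, 0, 1, (3 - 4 * nu) / d)
        set_(0, 2, 0, 2, 0.25)
        set_(1, 2, 1, 2, 0.25)
    else:
        raise ValueError(f"unknown inclusion shape {shape!r}")

    sq2 = np.sqrt(2.0)
    M = np.zeros((6, 6))
    for a_, (i, j) in enumerate(VOIGT_PAIRS):
        for b_, (k, l) in enumerate(VOIGT_PAIRS):
            f = (sq2 if a_ >= 3 else 1.0) * (sq2 if b_ >= 3 else 1.0)
            M[a_, b_] = f * S[i, j, k, l]
    return M


def mori_tanaka(
    C_matrix: np.ndarray,
    C_inclusion: np.ndarray,
    volume_fraction: float,
    shape: str,
    matrix_nu: float,
) -> np.ndarray:
    """Mori-Tanaka effective stiffness (Voigt in/out, aligned inclusions)."""
    f = float(volume_fraction)
    if not 0 <= f < 1:
        raise ValueError("volume fraction must lie in [0, 1)")
    Cm = voigt_to_mandel(check_voigt(C_matrix, name="C_matrix"))
    Ci = voigt_to_mandel(check_voigt(C_inclusion, name="C_inclusion"))
    if f == 0:
        return mandel_to_voigt(Cm)
    S = _eshelby_tensor(shape, matrix_nu)
    I = np.eye(6)
    dC = Ci - Cm
    A_dil = np.linalg.inv(I + S @ np.linalg.solve(Cm, dC))
    B = np.linalg.inv((1 - f) * I + f * A_dil)
    C_eff = Cm + f * dC @ A_dil @ B
    return mandel_to_voigt(0.5 * (C_eff + C_eff.T))


def dilute_estimate(
    C_matrix: np.ndarray,
    C_inclusion: np.ndarray,
    volume_fraction: float,
    shape: str,
    matrix_nu: float,
) -> np.ndarray:
    """First-order (dilute) Eshelby estimate — oracle for the MT small-f limit."""
    Cm = voigt_to_mandel(check_voigt(C_matrix))
    Ci = voigt_to_mandel(check_voigt(C_inclusion))
    S = _eshelby_tensor(shape, matrix_nu)
    dC = Ci - Cm
    A_dil = np.linalg.inv(np.eye(6) + S @ np.linalg.solve(Cm, dC))
    C = Cm + volume_fraction * dC @ A_dil
    return mandel_to_voigt(0.5 * (C + C.T))


def _water_stiffness(params: CorticalModelParams) -> np.ndarray:
    return isotropic_from_KG(params.inclusion_bulk, 0.0)


def cortical_stiffness(
    porosity: float, params: CorticalModelParams | None = None
) -> np.ndarray:
    """Cortical stiffness (GPa, local frame, cylinder axis = local 3-axis).

    Mori-Tanaka with aligned infinite-cylinder water inclusions in an
    isotropic mineralized matrix; transversely isotropic about the canal
    axis, which downstream is aligned with the voxel's stiffest direction.
    Porosity above the calibrated cortical maximum is clamped (and logged).
    """
    params = params or CorticalModelParams()
    p = float(porosity)
    if p < 0:
        raise ValueError("porosity must be non-negative")
    if p > params.phi_max:
        log.info("cortical porosity %.3f clamped to %.2f", p, params.phi_max)
        p = params.phi_max
    Cm = isotropic_stiffness(params.matrix_E, params.matrix_nu)
    return mori_tanaka(Cm, _water_stiffness(params), p, "cylinder", params.matrix_nu)


def isotropic_fallback_stiffness(
    porosity: float, params: CorticalModelParams | None = None
) -> np.ndarray:
    """Isotropic stiffness for flagged voxels: spherical water inclusions.

    Mori-Tanaka, spherical pores filled with water in the same isotropic
    matrix; used where no reliable stiffness direction exists.
    """
    params = params or CorticalModelParams()
    p = float(porosity)
    if not 0 <= p < 1:
        raise ValueError("porosity must lie in [0, 1)")
    Cm = isotropic_stiffness(params.matrix_E, params.matrix_nu)
    return mori_tanaka(Cm, _water_stiffness(params), p, "sphere", params.matrix_nu)


@dataclass
class ElasticityField:
    """Per-voxel 6x6 stiffness (Voigt, MPa, world axes) on labelled voxels."""

    voxel_indices: np.ndarray  # (n, 3) int
    stiffness: np.ndarray  # (n, 6, 6) MPa
    symmetry_class: np.ndarray  # (n,) of {"isotropic","transversely_isotropic"}
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def voxel_centers(self) -> np.ndarray:
        return self.voxel_indices * np.asarray(self.spacing) + np.asarray(self.origin)

    def linear_indices(self) -> np.ndarray:
        nx, ny, nz = self.shape
        i = self.voxel_indices
        return (i[:, 0] * ny + i[:, 1]) * nz + i[:, 2]


def _stiff_axis_basis(eigvecs: np.ndarray) -> np.ndarray:
    """Right-handed world basis whose third column is the stiff axis e1.

    Batched: ``eigvecs[..., :, i]`` are GST eigenvectors; the minimum-gradient
    vector e1 becomes the local 3-axis so transversely isotropic stiffness
    (symmetry axis 3) rotates onto it.
    """
    e1 = eigvecs[..., :, 0]
    e2 = eigvecs[..., :, 1]
    e3 = eigvecs[..., :, 2]
    Q = np.stack([e2, e3, e1], axis=-1)
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1.0
    return Q


def rotation_operators(Q: np.ndarray) -> np.ndarray:
    """Batched Mandel-basis rotation operators for (n, 3, 3) rotations."""
    sq2 = np.sqrt(2.0)
    n = Q.shape[0]
    R = np.empty((n, 6, 6))
    for a_, (i, j) in enumerate(VOIGT_PAIRS):
        for b_, (k, l) in enumerate(VOIGT_PAIRS):
            if a_ < 3 and b_ < 3:
                R[:, a_, b_] = Q[:, i, k] * Q[:, j, l]
            elif a_ < 3:
                R[:, a_, b_] = sq2 * Q[:, i, k] * Q[:, i, l]
            elif b_ < 3:
                R[:, a_, b_] = sq2 * Q[:, i, k] * Q[:, j, k]
            else:
                R[:, a_, b_] = Q[:, i, k] * Q[:, j, l] + Q[:, i, l] * Q[:, j, k]
    return R


def rotate_stiffness_batch(C_local: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotate (n, 6, 6) Voigt stiffness by (n, 3, 3) bases into world axes."""
    D = np.diag([1.0, 1.0, 1.0, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
    Dinv = np.diag(1.0 / np.diag(D))
    M = np.einsum("ab,nbc,cd->nad", D, C_local, D)
    R = rotation_operators(Q)
    out = np.einsum("nab,nbc,ndc->nad", R, M, R)
    return np.einsum("ab,nbc,cd->nad", Dinv, out, Dinv)


def nearest_voxel_assign(mesh, fld: ElasticityField, default: np.ndarray | None = None):
    """Nearest voxel strategy: per-element material from the closest voxel.

    Each tet element receives the stiffness of the labelled voxel whose centre
    is nearest to the element centroid (exact ties broken by the lowest
    linear voxel index).  Returns ``(stiffness (m,6,6), assigned_voxel (m,),
    outside (m,) bool)``; ``outside`` marks elements farther than one voxel
    diagonal from any labelled voxel, which receive ``default`` when given.
    """
    if len(fld.voxel_indices) == 0:
        raise ValueError("elasticity field is empty")
    centers = fld.voxel_centers()
    tree = cKDTree(centers)
    centroids = mesh.centroids()
    dist, idx = tree.query(centroids, k=2)
    tie = np.isclose(dist[:, 0], dist[:, 1], rtol=0.0, atol=1e-12)
    lin = fld.linear_indices()
    pick = np.where(
        tie & (lin[idx[:, 1]] < lin[idx[:, 0]]), idx[:, 1], idx[:, 0]
    )
    diag = float(np.linalg.norm(fld.spacing))
    outside = dist[:, 0] > diag
    C = fld.stiffness[pick].copy()
    if outside.any():
        n = int(outside.sum())
        log.info("%d elements lie outside the labelled region", n)
        if default is not None:
            C[outside] = default
    return C, pick, outside


def bone_voxel_stiffness(
    porosity: np.ndarray,
    tissue_is_cortical: np.ndarray,
    flagged: np.ndarray,
    R: np.ndarray,
    eigvecs: np.ndarray,
    E0_trab_GPa: float = 13.0,
    cortical_params: CorticalModelParams | None = None,
    n_phi_bins: int = 48,
    n_R_bins: int = 24,
) -> np.ndarray:
    """Per-voxel 6x6 stiffness (MPa, world axes) for a batch of bone voxels.

    Porosity and aspect ratio are quantized to a small grid so the expensive
    micromechanical evaluations are cached; local frames are applied by a
    vectorized Voigt rotation.  Flagged voxels get the isotropic fallback
    (spherical-pore cortical model, equiaxed Kelvin cell for trabecular).
    """
    from .kelvin import trabecular_stiffness

    cp = cortical_params or CorticalModelParams()
    n = len(porosity)
    out = np.empty((n, 6, 6))

    phi_b = np.round(np.clip(porosity, 0.0, 0.98) * n_phi_bins).astype(int)
    R_b = np.round(np.clip(R, 1.0, 10.0) * n_R_bins).astype(int)

    cache: dict = {}
    local = np.empty((n, 6, 6))
    for i in range(n):
        cort = bool(tissue_is_cortical[i])
        flag = bool(flagged[i])
        key = (cort, flag, phi_b[i], R_b[i] if not cort else 0)
        C = cache.get(key)
        if C is None:
            phi = phi_b[i] / n_phi_bins
            if cort:
                phi_c = min(phi, cp.phi_max)
                C = (
                    isotropic_fallback_stiffness(phi_c, cp)
                    if flag
                    else cortical_stiffness(phi_c, cp)
                )
            else:
                phi_t = float(np.clip(phi, 0.55, 0.97))
                Rv = 1.0 if flag else max(R_b[i] / n_R_bins, 1.0)
                C = trabecular_stiffness(Rv, phi_t, E0_trab_GPa)
            cache[key] = C
        local[i] = C
    local *= 1000.0  # GPa -> MPa

    need_rot = ~np.asarray(flagged, bool)
    out[~need_rot] = local[~need_rot]
    if need_rot.any():
        Q = _stiff_axis_basis(eigvecs[need_rot])
        out[need_rot] = rotate_stiffness_batch(local[need_rot], Q)
    return out


def assign_voxel_stiffness(
    porosity_field,
    fabric_trab,
    fabric_cort,
    spacing,
    origin=(0.0, 0.0, 0.0),
    E0_trab_GPa: float = 13.0,
    cortical_params: CorticalModelParams | None = None,
) -> ElasticityField:
    """Build the full per-voxel stiffness field for a labelled volume.

    Intended for desk-scale volumes (the field stores a dense (n, 6, 6)
    array for every labelled voxel); the meshing pipeline instead computes
    stiffness lazily for the voxels the nearest-voxel mapping selects.
    """
    from .ctprep import CORTICAL, OUTSIDE

    tissue = porosity_field.tissue
    idx = np.argwhere(tissue != OUTSIDE)
    vidx = tuple(idx.T)
    is_cort = tissue[vidx] == CORTICAL
    flagged = np.where(
        is_cort, fabric_cort.isotropic[vidx], fabric_trab.isotropic[vidx]
    )
    R = np.where(is_cort, fabric_cort.R[vidx], fabric_trab.R[vidx])
    evec = np.where(
        is_cort[:, None, None],
        fabric_cort.eigenvectors[vidx],
        fabric_trab.eigenvectors[vidx],
    )
    C = bone_voxel_stiffness(
        porosity_field.porosity[vidx], is_cort, flagged, R, evec,
        E0_trab_GPa, cortical_params,
    )
    sym = np.where(flagged, "isotropic", "transversely_isotropic")
    return ElasticityField(
        voxel_indices=idx,
        stiffness=C,
        symmetry_class=sym,
        shape=tissue.shape,
        spacing=tuple(spacing),
        origin=tuple(origin),
    )
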