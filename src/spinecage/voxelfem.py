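"""Voxel-based periodic FE homogenization of lattice unit cells.

The unit cell is discretized into cubic voxels; solid voxels become 8-node
trilinear hexahedra (2x2x2 Gauss integration).  Periodic boundary conditions
are imposed by construction: node indices wrap modulo the grid, and the
displacement field is the sum of an affine part E.x (evaluated with each
element's own unwrapped coordinates) and a periodic correction solved for.
The effective stiffness follows from mutual energies of the six unit
macroscopic strains — the standard first-order computational-homogenization
scheme.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu, cg, LinearOperator, spilu

from .voigt import mandel_to_voigt

log = logging.getLogger(__name__)


def hex_stiffness(E: float, nu: float, h: float, incompatible: bool = True) -> np.ndarray:
    """24x24 stiffness of a cubic 8-node hexahedron with edge ``h``.

    With ``incompatible`` (default) the Wilson incompatible bending modes
    (1-xi^2 bubbles, 9 internal DOFs, statically condensed) are added; plain
    trilinear hexes lock in bending and grossly overstiffen strut lattices.
    """
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    # node order: (dx, dy, dz) bit pattern (z fastest), matching assembly
    corners = np.array(
        [[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)], dtype=float
    )
    gp = np.array([-1, 1]) / np.sqrt(3)
    nE = 33 if incompatible else 24
    K = np.zeros((nE, nE))
    jac = 2.0 / h
    for gx in gp:
        for gy in gp:
            for gz in gp:
                xi = np.array([gx, gy, gz])
                dN = np.zeros((8, 3))
                for a, c in enumerate(corners):
                    sgn = 2 * c - 1  # -1/+1 per axis
                    for d in range(3):
                        dN[a, d] = (
                            0.125
                            * sgn[d]
                            * np.prod([1 + sgn[e] * xi[e] for e in range(3) if e != d])
                        )
                dN = dN * jac
                B = np.zeros((6, nE))
                for a in range(8):
                    bx, by, bz = dN[a]
                    B[0, 3 * a] = bx
                    B[1, 3 * a + 1] = by
                    B[2, 3 * a + 2] = bz
                    B[3, 3 * a + 1] = bz
                    B[3, 3 * a + 2] = by
                    B[4, 3 * a] = bz
                    B[4, 3 * a + 2] = bx
                    B[5, 3 * a] = by
                    B[5, 3 * a + 1] = bx
                if incompatible:
                    # modes P_d = 1 - xi_d^2, gradient -2 xi_d along axis d
                    dP = np.diag(-2 * xi) * jac  # (mode, axis)
                    for m in range(3):
                        for comp in range(3):
                            col = 24 + 3 * m + comp
                            g = np.zeros(3)
                            g[m] = dP[m, m]
                            # displacement component `comp` with gradient g
                            B[0, col] += g[0] if comp == 0 else 0.0
                            B[1, col] += g[1] if comp == 1 else 0.0
                            B[2, col] += g[2] if comp == 2 else 0.0
                            if comp == 1:
                                B[3, col] += g[2]
                            if comp == 2:
                                B[3, col] += g[1]
                            if comp == 0:
                                B[4, col] += g[2]
                                B[5, col] += g[1]
                            if comp == 2:
                                B[4, col] += g[0]
                            if comp == 1:
                                B[5, col] += g[0]
                K += B.T @ D @ B * (h / 2) ** 3
    if incompatible:
        Kuu = K[:24, :24]
        Kua = K[:24, 24:]
        Kaa = K[24:, 24:]
        K = Kuu - Kua @ np.linalg.solve(Kaa, Kua.T)
    return K


def homogenize_periodic(
    solid: np.ndarray,
    E0: float,
    nu0: float,
    cell_size: float = 1.0,
    solver: str = "auto",
    tol: float = 1e-8,
    density_cutoff: float = 0.003,
) -> np.ndarray:
    """Effective 6x6 Voigt stiffness of a periodic voxel microstructure.

    ``solid`` is an (n, n, n) occupancy grid — boolean, or float densities in
    [0, 1] from partial-volume voxelization (element stiffness scales
    linearly with density; entries below ``density_cutoff`` are dropped).
    The cell is periodic in all directions.  Raises if the structure is empty or completely full-empty
    degenerate.  Disconnected floating clusters make the problem singular;
    lattice cells handled here are connected through the periodic boundary.
    """
    dens = np.asarray(solid, float)
    if dens.ndim != 3 or len(set(dens.shape)) != 1:
        raise ValueError("solid must be a cubic 3-D (boolean or density) grid")
    n = dens.shape[0]
    mask = dens > density_cutoff
    if not mask.any():
        raise ValueError("empty cell: porosity 1 is outside (0,1)")
    h = cell_size / n

    ke = hex_stiffness(E0, nu0, h)
    vox = np.argwhere(mask)
    chi = dens[mask]
    # periodic node ids on the n^3 wrapped grid
    offs = np.array([[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)])
    corner_idx = (vox[:, None, :] + offs[None, :, :]) % n  # (m, 8, 3)
    nid = (corner_idx[..., 0] * n + corner_idx[..., 1]) * n + corner_idx[..., 2]
    used, nid_c = np.unique(nid, return_inverse=True)
    nid_c = nid_c.reshape(nid.shape)
    nn = len(used)
    ndof = 3 * nn
    edof = (3 * nid_c[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    edof32 = edof.astype(np.int32)
    # assemble in chunks to bound peak memory
    K = sparse.csr_matrix((ndof, ndof))
    chunk = 20000
    for s in range(0, len(vox), chunk):
        e = edof32[s : s + chunk]
        rows = np.repeat(e, 24, axis=1).ravel()
        cols = np.tile(e, (1, 24)).ravel()
        data = np.einsum("m,kl->mkl", chi[s : s + chunk], ke).ravel()
        K = K + sparse.coo_matrix(
            (data, (rows, cols)), shape=(ndof, ndof)
        ).tocsr()
    K = K.tocsc()

    # unwrapped element corner coordinates for the affine field
    xyz = (vox[:, None, :] + offs[None, :, :]) * h  # (m, 8, 3)

    pairs = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))
    sq2 = np.sqrt(2.0)
    strains = []
    for a in range(6):
        Em = np.zeros((3, 3))
        i, j = pairs[a]
        if a < 3:
            Em[i, j] = 1.0
        else:
            Em[i, j] = Em[j, i] = 1 / sq2
        strains.append(Em)

    pin = [0, 1, 2]
    keep = np.setdiff1d(np.arange(ndof), pin)
    Kff = K[keep][:, keep]

    use_direct = solver == "direct" or (solver == "auto" and ndof <= 60_000)
    lu = None
    if use_direct:
        try:
            lu = splu(Kff.tocsc())
        except Exception as exc:  # memory or singularity -> iterative
            log.warning("direct factorization failed (%s); falling back to CG", exc)
    M = None
    if lu is None:
        d = Kff.diagonal()
        d[d <= 0] = 1.0
        M = LinearOperator(Kff.shape, matvec=lambda x: x / d)

    sols = []
    qaffs = []
    for Em in strains:
        qa = np.einsum("ab,mkb->mka", Em, xyz).reshape(-1, 24)
        f = np.zeros(ndof)
        fe = (qa @ ke.T) * chi[:, None]
        np.add.at(f, edof.ravel(), -fe.ravel())
        w = np.zeros(ndof)
        if lu is not None:
            w[keep] = lu.solve(f[keep])
        else:
            sol, info = cg(Kff, f[keep], rtol=tol, maxiter=20000, M=M)
            if info != 0:
                raise RuntimeError(f"CG did not converge (info={info})")
            w[keep] = sol
        qfull = qa + w[edof]
        sols.append(qfull)
        qaffs.append(qa)

    V = cell_size**3
    C_m = np.zeros((6, 6))
    for a in range(6):
        ka = (sols[a] @ ke) * chi[:, None]
        for b in range(a, 6):
            C_m[a, b] = C_m[b, a] = np.einsum("mk,mk->", ka, sols[b]) / V
    return mandel_to_voigt(C_m)
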