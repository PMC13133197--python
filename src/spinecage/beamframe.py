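"""Periodic beam-frame homogenization of the anisotropic Kelvin cell.

The tetrakaidecahedral strut network is represented exactly: 12 unique
vertices and 24 struts per periodic cell, each strut a single 3-D
Euler-Bernoulli beam element (exact within beam theory for end-loaded
members), with periodic corrections on top of an affine displacement field.
Anisotropy R = H/D is produced by stretching the regular network along z, so
the strut inclination satisfies tan(theta) = R.

This is the numerical oracle used to cross-validate the closed-form foam
constants in ``spinecage.kelvin``; the two share only the cell geometry
definition, not the mechanics code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .voigt import mandel_to_voigt


def _raw_vertices() -> np.ndarray:
    """The 24 vertices of the truncated octahedron centred at the origin."""
    verts = set()
    for perm in permutations((0, 1, 2)):
        for s1 in (1, -1):
            for s2 in (1, -1):
                coords = (0.0, 0.25 * s1, 0.5 * s2)
                v = [0.0, 0.0, 0.0]
                for axis, c in zip(perm, coords):
                    v[axis] = c
                verts.add(tuple(round(x, 9) for x in v))
    out = np.array(sorted(verts))
    assert len(out) == 24
    return out


def kelvin_network() -> tuple[np.ndarray, list[tuple[int, int, np.ndarray]]]:
    """Unique nodes (fractional cell coords) and periodic edges of the network.

    Returns ``(nodes (12,3), edges)`` with each edge ``(i, j, shift)`` meaning
    a strut from node i to node j translated by integer cell ``shift``.
    """
    raw = _raw_vertices()
    all_pts = np.vstack([raw, raw + 0.5])  # corner + body-centre cells
    # unique node classes mod 1
    frac = np.round(np.mod(np.round(all_pts, 9), 1.0), 9) % 1.0
    nodes, inv = np.unique(frac, axis=0, return_inverse=True)
    assert len(nodes) == 12, len(nodes)

    edge_len2 = 0.125  # (sqrt(2)/4)^2
    seen = {}
    edges: list[tuple[int, int, np.ndarray]] = []
    n_raw = len(all_pts)
    for p in range(n_raw):
        for q in range(p + 1, n_raw):
            d = all_pts[q] - all_pts[p]
            if abs(d @ d - edge_len2) > 1e-9:
                continue
            mid = np.round(np.mod(np.round((all_pts[p] + all_pts[q]) / 2, 9), 1.0), 9) % 1.0
            key = tuple(mid)
            if key in seen:
                continue
            seen[key] = True
            i, j = int(inv[p]), int(inv[q])
            shift_i = np.round(all_pts[p] - nodes[i]).astype(int)
            shift_j = np.round(all_pts[q] - nodes[j]).astype(int)
            # express the strut relative to node i's home image
            edges.append((i, j, shift_j - shift_i))
    assert len(edges) == 24, len(edges)
    return nodes, edges


def _beam_stiffness(E0, G0, A, Iy, J, L, phi_s=0.0) -> np.ndarray:
    """12x12 local-frame stiffness of a 3-D beam (Euler; phi_s adds shear)."""
    k = np.zeros((12, 12))
    ax = E0 * A / L
    t = G0 * J / L
    b = E0 * Iy / ((1 + phi_s) * L**3)
    # axial (u_x1, u_x2)
    for s1, i in ((1, 0), (-1, 6)):
        for s2, j in ((1, 0), (-1, 6)):
            k[i, j] += s1 * s2 * ax
            k[i + 3, j + 3] += s1 * s2 * t  # torsion on theta_x
    # bending in x-y plane: DOFs (uy1, thz1, uy2, thz2) = (1, 5, 7, 11)
    # bending in x-z plane: DOFs (uz1, thy1, uz2, thy2) = (2, 4, 8, 10), sign flip
    kb = np.array(
        [
            [12, 6 * L, -12, 6 * L],
            [6 * L, (4 + phi_s) * L**2, -6 * L, (2 - phi_s) * L**2],
            [-12, -6 * L, 12, -6 * L],
            [6 * L, (2 - phi_s) * L**2, -6 * L, (4 + phi_s) * L**2],
        ]
    ) * b
    idx_y = [1, 5, 7, 11]
    sgn_y = [1, 1, 1, 1]
    idx_z = [2, 4, 8, 10]
    sgn_z = [1, -1, 1, -1]
    for idx, sgn in ((idx_y, sgn_y), (idx_z, sgn_z)):
        for a_, (ia, sa) in enumerate(zip(idx, sgn)):
            for b_, (ib, sb) in enumerate(zip(idx, sgn)):
                k[ia, ib] += sa * sb * kb[a_, b_]
    return k


def _local_frame(axis: np.ndarray) -> np.ndarray:
    x = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(x[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    y = np.cross(ref, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.stack([x, y, z])  # rows: local axes in global coords


@dataclass
class KelvinFrameResult:
    C_eff: np.ndarray  # 6x6 Voigt, units of E0
    engineering: dict


def fcc_network() -> tuple[np.ndarray, list[tuple[int, int, np.ndarray]]]:
    """Unique nodes and periodic corner-to-face-centre struts of the FCC cell.

    Four node classes per cell (one corner, three face centres) and twelve
    unique struts of length sqrt(2)/2.
    """
    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.5, 0.5],
            [0.5, 0.0, 0.5],
            [0.5, 0.5, 0.0],
        ]
    )
    edges = []
    for fc in (1, 2, 3):
        c = nodes[fc]
        inplane = [a for a in range(3) if c[a] == 0.5]
        for s1 in (-0.5, 0.5):
            for s2 in (-0.5, 0.5):
                p = c.copy()
                p[inplane[0]] += s1
                p[inplane[1]] += s2
                # p is a corner image with integer coordinates
                shift = np.round(p).astype(int)
                edges.append((fc, 0, shift))
    assert len(edges) == 12, len(edges)
    return nodes, edges


def homogenize_beam_network(
    nodes: np.ndarray,
    edges: list,
    stretch: np.ndarray,
    A: float,
    Iy: float,
    J: float,
    E0: float,
    nu0: float,
    shear_deformation: bool = False,
) -> np.ndarray:
    """Effective 6x6 Voigt stiffness of an arbitrary periodic strut network.

    ``nodes`` are fractional cell coordinates, ``edges`` are
    ``(i, j, shift)`` periodic struts, ``stretch`` the physical cell edge
    lengths.  Euler-Bernoulli beams (optionally Timoshenko), periodic
    corrections on top of six unit macroscopic strains, mutual-energy
    assembly.
    """
    stretch = np.asarray(stretch, float)
    X = nodes * stretch
    V = float(np.prod(stretch))
    G0 = E0 / (2 * (1 + nu0))
    nn = len(nodes)
    ndof = nn * 6
    K = np.zeros((ndof, ndof))
    elems = []
    for i, j, shift in edges:
        P1 = X[i]
        P2 = (nodes[j] + shift) * stretch
        d = P2 - P1
        L = np.linalg.norm(d)
        Rf = _local_frame(d)
        if shear_deformation:
            As = A * 6 * (1 + nu0) / (7 + 6 * nu0)
            phi_s = 12 * E0 * Iy / (G0 * As * L**2)
        else:
            phi_s = 0.0
        k_loc = _beam_stiffness(E0, G0, A, Iy, J, L, phi_s)
        T = np.zeros((12, 12))
        for blk in range(4):
            T[3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = Rf
        k_glob = T.T @ k_loc @ T
        dofs = np.r_[6 * i + np.arange(6), 6 * j + np.arange(6)]
        K[np.ix_(dofs, dofs)] += k_glob
        elems.append((i, j, P1, P2, k_glob, dofs))

    # pin node-0 translations to remove the rigid-translation kernel
    pinned = [0, 1, 2]
    free = np.setdiff1d(np.arange(ndof), pinned)

    sq2 = np.sqrt(2.0)
    mandel_strains = []
    for a_ in range(6):
        Em = np.zeros((3, 3))
        pairs = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))
        i_, j_ = pairs[a_]
        if a_ < 3:
            Em[i_, j_] = 1.0
        else:
            Em[i_, j_] = Em[j_, i_] = 1.0 / sq2
        mandel_strains.append(Em)

    def affine_q(Em):
        q = np.zeros((len(elems), 12))
        for e_, (i, j, P1, P2, k_glob, dofs) in enumerate(elems):
            q[e_, 0:3] = Em @ P1
            q[e_, 6:9] = Em @ P2
        return q

    sols = []
    for Em in mandel_strains:
        qa = affine_q(Em)
        f = np.zeros(ndof)
        for e_, (i, j, P1, P2, k_glob, dofs) in enumerate(elems):
            f[dofs] -= k_glob @ qa[e_]
        w = np.zeros(ndof)
        w[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
        qfull = qa.copy()
        for e_, (i, j, P1, P2, k_glob, dofs) in enumerate(elems):
            qfull[e_] += w[dofs]
        sols.append(qfull)

    C_m = np.zeros((6, 6))
    for a_ in range(6):
        for b_ in range(a_, 6):
            u = 0.0
            for e_, (i, j, P1, P2, k_glob, dofs) in enumerate(elems):
                u += sols[a_][e_] @ k_glob @ sols[b_][e_]
            C_m[a_, b_] = C_m[b_, a_] = u / V
    return mandel_to_voigt(C_m)


def homogenize_kelvin_frame(
    R: float,
    r_over_L: float,
    E0: float = 1.0,
    nu0: float = 0.3,
    shear_deformation: bool = False,
) -> KelvinFrameResult:
    """Effective stiffness of the stretched Kelvin strut lattice.

    ``R`` = cell aspect ratio (tan of the strut inclination), ``r_over_L`` =
    strut radius over oblique strut length.
    """
    if R < 1 - 1e-9:
        raise ValueError("R must be >= 1")
    R = max(float(R), 1.0)
    if not 0 < r_over_L < 0.5:
        raise ValueError("r_over_L must lie in (0, 0.5); beam theory breaks above")
    nodes, edges = kelvin_network()
    L_obl = 0.25 * np.sqrt(1.0 + R**2)
    r = r_over_L * L_obl
    A = np.pi * r**2
    Iy = np.pi * r**4 / 4
    J = np.pi * r**4 / 2
    C = homogenize_beam_network(
        nodes,
        edges,
        np.array([1.0, 1.0, R]),
        A,
        Iy,
        J,
        E0,
        nu0,
        shear_deformation,
    )
    S = np.linalg.inv(C)
    eng = {
        "E_axial": 1.0 / S[2, 2],
        "E_trans": 1.0 / S[0, 0],
        "nu_axial": -S[0, 2] / S[2, 2],
        "nu_trans": -S[0, 1] / S[0, 0],
        "G_axial": 1.0 / S[3, 3],
        "G_trans": 1.0 / S[5, 5],
    }
    return KelvinFrameResult(C_eff=C, engineering=eng)


def fcc_beam_modulus(
    porosity: float, E0: float = 1.0, nu0: float = 0.3,
    shear_deformation: bool = False,
) -> float:
    """Beam-model axial modulus of the FCC strut lattice at a porosity.

    Thin-strut relative density: 12 struts of length sqrt(2)/2 per unit
    cell, so rho = 6 sqrt(2) pi r^2.
    """
    r = float(np.sqrt((1 - porosity) / (6 * np.sqrt(2) * np.pi)))
    nodes, edges = fcc_network()
    A = np.pi * r**2
    C = homogenize_beam_network(
        nodes, edges, np.ones(3), A, np.pi * r**4 / 4, np.pi * r**4 / 2,
        E0, nu0, shear_deformation,
    )
    S = np.linalg.inv(C)
    return float((1.0 / np.diag(S)[:3]).mean())


def beam_frame_unit_cell_oracle(params) -> dict:
    """Engineering constants for a KelvinCellParams-like object (see kelvin)."""
    R = np.tan(params.theta)
    res = homogenize_kelvin_frame(R, params.r / params.L, E0=params.E0)
    return res.engineering
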