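"""Anisotropic Kelvin-cell (tetrakaidecahedron) foam model for trabecular bone.

The unit cell is the regular Kelvin cell stretched along its rise axis: the
cell aspect ratio R = H/D equals tan(theta), where theta is the inclination
of the oblique struts, and the horizontal strut length obeys the geometric
restriction b = sqrt(2) L cos(theta) (which reduces the cell shape to the
single parameter theta and recovers the regular cell at theta = 45 deg).
Struts have a circular cross-section of radius r, so A = pi r^2,
I = pi r^4 / 4, J = pi r^4 / 2.

With cell width D = 1 the oblique strut length is L = sqrt(1+R^2)/4 and the
relative density of the thin-strut skeleton is

    rho = 1 - phi = pi (r/L)^2 (sqrt(2) cos(theta) + 2) / (8 cos^2(theta) sin(theta)),

which reduces to the classic 3 pi r^2 / (2 sqrt(2) L^2) at R = 1.  Effective
elastic constants come from closed forms obtained by exact symbolic energy
minimization of the periodic Euler-beam frame (see ``_kelvin_forms``); the
rise-direction modulus reduces to the guided-strut expression

    E_axial/E0 = sin(theta) / ( 4 sin^2 t cos^2 t / (pi (r/L)^2)
                                + (4/3) cos^4 t / (pi (r/L)^4) ),

the classic Kelvin-foam result at theta = 45 deg.  The independent numerical
beam-frame oracle lives in ``spinecage.beamframe``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kelvin_forms import tetragonal_stiffness_entries
from .voigt import transversely_isotropic_stiffness

R_OVER_L_MAX = 0.5  # beam theory (and the thin-strut density) break above
E0_TRABECULAR_GPA = 13.0  # tissue-level solid modulus of trabecular struts


@dataclass
class KelvinCellParams:
    """Geometry + material of one stretched Kelvin cell (cell width D = 1)."""

    theta: float  # strut inclination, rad; tan(theta) = R
    L: float  # oblique strut length
    b: float  # horizontal strut length
    r: float  # strut cross-section radius
    E0: float  # solid modulus
    nu0: float = 0.3
    relative_density: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.theta < np.pi / 2:
            raise ValueError("theta must lie in (0, pi/2)")
        if not 0 < self.relative_density < 1:
            raise ValueError("relative_density must lie in (0,1)")

    @property
    def H(self) -> float:
        return 4 * self.L * np.sin(self.theta)

    @property
    def D(self) -> float:
        return 4 * self.L * np.cos(self.theta)

    @property
    def R(self) -> float:
        return float(np.tan(self.theta))

    @property
    def A(self) -> float:
        return float(np.pi * self.r**2)

    @property
    def I(self) -> float:
        return float(np.pi * self.r**4 / 4)

    @property
    def J(self) -> float:
        return float(np.pi * self.r**4 / 2)


def relative_density(theta: float, r_over_L: float) -> float:
    """Thin-strut relative density of the stretched Kelvin skeleton."""
    c, s = np.cos(theta), np.sin(theta)
    return float(np.pi * r_over_L**2 * (np.sqrt(2) * c + 2) / (8 * c * c * s))


def solve_strut_radius(theta: float, porosity: float) -> float:
    """r/L giving the requested porosity; errors when beams get too stubby."""
    if not 0 < porosity < 1:
        raise ValueError("porosity must lie in (0, 1)")
    c, s = np.cos(theta), np.sin(theta)
    t2 = (1 - porosity) * 8 * c * c * s / (np.pi * (np.sqrt(2) * c + 2))
    t = float(np.sqrt(t2))
    if t > R_OVER_L_MAX:
        raise ValueError(
            f"porosity {porosity:.3f} needs r/L = {t:.3f} > {R_OVER_L_MAX}; "
            "the slender-strut cell model does not apply"
        )
    return t


def kelvin_cell_params(
    R: float, porosity: float, E0: float = E0_TRABECULAR_GPA, nu0: float = 0.3
) -> KelvinCellParams:
    """Fully determined cell (width D = 1) for aspect ratio R and porosity."""
    if R < 1:
        raise ValueError("R must be >= 1")
    theta = float(np.arctan(R))
    L = np.sqrt(1 + R * R) / 4
    t = solve_strut_radius(theta, porosity)
    return KelvinCellParams(
        theta=theta,
        L=L,
        b=np.sqrt(2) * L * np.cos(theta),
        r=t * L,
        E0=E0,
        nu0=nu0,
        relative_density=1 - porosity,
    )


def kelvin_cell_constants(
    R: float, porosity: float, E0: float = E0_TRABECULAR_GPA, nu0: float = 0.3
) -> dict:
    """Transversely isotropic engineering constants of the foam cell.

    Closed-form evaluation (see module docstring); returns E_axial (rise
    direction), E_trans, nu_axial (transverse strain per rise strain),
    nu_trans, G_axial, plus the underlying cell parameters.  Moduli scale
    linearly with ``E0``.
    """
    p = kelvin_cell_params(R, porosity, E0, nu0)
    G0 = E0 / (2 * (1 + nu0))
    C11, C33, C12, C13, C44, C66 = tetragonal_stiffness_entries(
        p.R, E0, G0, p.A, p.I, p.J
    )
    C = np.array(
        [
            [C11, C12, C13, 0, 0, 0],
            [C12, C11, C13, 0, 0, 0],
            [C13, C13, C33, 0, 0, 0],
            [0, 0, 0, C44, 0, 0],
            [0, 0, 0, 0, C44, 0],
            [0, 0, 0, 0, 0, C66],
        ]
    )
    S = np.linalg.inv(C)
    return {
        "E_axial": 1.0 / S[2, 2],
        "E_trans": 1.0 / S[0, 0],
        "nu_axial": -S[0, 2] / S[2, 2],
        "nu_trans": -S[0, 1] / S[0, 0],
        "G_axial": 1.0 / S[3, 3],
        "C_tetragonal": C,
        "params": p,
    }


def trabecular_stiffness(
    R: float, porosity: float, E0: float = E0_TRABECULAR_GPA, nu0: float = 0.3
) -> np.ndarray:
    """6x6 transversely isotropic stiffness (local frame, rise axis = 3).

    Built from the five engineering constants; the in-plane shear modulus
    follows the transverse-isotropy relation G_t = E_t / (2 (1 + nu_t)),
    which replaces the cell's (slightly different) tetragonal C66.
    """
    k = kelvin_cell_constants(R, porosity, E0, nu0)
    return transversely_isotropic_stiffness(
        k["E_axial"], k["E_trans"], k["nu_axial"], k["nu_trans"], k["G_axial"]
    )


def axial_modulus_guided_strut(theta: float, r_over_L: float, E0: float = 1.0) -> float:
    """Independent compact form of the rise-direction modulus (see docstring)."""
    t2 = r_over_L**2
    c, s = np.cos(theta), np.sin(theta)
    denom = 4 * s * s * c * c / (np.pi * t2) + (4.0 / 3.0) * c**4 / (np.pi * t2 * t2)
    return float(E0 * s / denom)
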