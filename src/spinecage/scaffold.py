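"""Interbody-cage scaffolds: lattice microstructures, porosity, strength.

The cage macro-geometry is an elliptical plate (27 x 32 mm footprint, 9 mm
thick by default) filled with one of three strut microstructures — FCC cells,
Kelvin cells, or a Voronoi network — at 75% uniform porosity, optionally with
a radial porosity gradient (90% at the axis to 60% at the rim) realized by
grading the Voronoi seed density.  A solid Ti6Al4V ring of 3.8 mm mean wall
thickness serves as the conventional-device comparator.

Geometry is represented on a voxel grid (solid = voxel centre within the
strut radius of the strut skeleton); surfaces are extracted by marching
cubes into ``trimesh`` for STL export and watertightness/volume checks.
The macroscopic strength of a porous ceramic follows the cubic scaling law
sigma = 1.21 (1 - phi)^3 sigma0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .beamframe import kelvin_network
from .voxelfem import homogenize_periodic

log = logging.getLogger(__name__)

SIGMA0_TENSION_MPA = 100.0  # dense hydroxyapatite, tension
SIGMA0_COMPRESSION_MPA = 350.0  # dense hydroxyapatite, compression
HAP_E0_GPA = 100.0  # dense hydroxyapatite Young's modulus


@dataclass
class CageFootprint:
    """Elliptical cage footprint; axes are full diameters in mm."""

    ellipse_axes: tuple[float, float] = (27.0, 32.0)
    thickness: float = 9.0

    def __post_init__(self) -> None:
        if min(self.ellipse_axes) <= 0 or self.thickness <= 0:
            raise ValueError("footprint dimensions must be positive")

    @property
    def semi_axes(self) -> tuple[float, float]:
        return (self.ellipse_axes[0] / 2, self.ellipse_axes[1] / 2)


@dataclass
class LatticeSpec:
    """Microstructure request for a cage."""

    family: str = "fcc"  # fcc | kelvin | voronoi | ti_ring
    cell_size: float = 2.5  # mm (FCC/Kelvin); mean seed spacing scale (Voronoi)
    strut_radius: float | None = None  # mm; solved from target_porosity if None
    target_porosity: float = 0.75
    gradient: tuple[float, float] | None = None  # (inner, outer) porosity
    seed: int = 0
    resolution: float = 0.15  # mm voxel pitch of the device grid

    def __post_init__(self) -> None:
        fam = self.family.lower()
        if fam not in {"fcc", "kelvin", "voronoi", "ti_ring"}:
            raise ValueError(f"unknown lattice family {self.family!r}")
        self.family = fam
        if not 0 < self.target_porosity < 1:
            raise ValueError("target_porosity must lie in (0,1)")
        if self.gradient is not None:
            inner, outer = self.gradient
            if not inner > outer:
                raise ValueError("gradient requires inner porosity > outer porosity")


@dataclass
class ScaffoldModel:
    """Voxelized scaffold with lazy triangulated surface."""

    solid: np.ndarray  # (nx, ny, nz) bool
    envelope: np.ndarray  # (nx, ny, nz) bool: the footprint region
    spacing: float  # mm (cubic voxels)
    origin: tuple[float, float, float]
    family: str
    strut_radius: float | None = None
    metadata: dict = field(default_factory=dict)
    _surface: trimesh.Trimesh | None = None

    @property
    def porosity(self) -> float:
        return float(1.0 - self.solid.sum() / max(self.envelope.sum(), 1))

    def surface(self) -> trimesh.Trimesh:
        if self._surface is None:
            pad = np.pad(self.solid, 1).astype(float)
            verts, faces, _, _ = measure.marching_cubes(pad, level=0.5)
            verts = (verts - 1.0) * self.spacing + np.asarray(self.origin)
            surf = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
            if surf.volume < 0:
                surf.invert()
            self._surface = surf
        return self._surface

    def export_stl(self, path) -> None:
        self.surface().export(path)

    def solid_volume(self) -> float:
        return float(self.solid.sum()) * self.spacing**3


# ---------------------------------------------------------------------------
# unit-cell strut skeletons (fractional cell coordinates)
# ---------------------------------------------------------------------------

def _fcc_segments() -> np.ndarray:
    """Corner-to-face-centre struts of the FCC cell: 24 segments (n, 2, 3)."""
    segs = []
    corners = [np.array([x, y, z]) for x in (0, 1) for y in (0, 1) for z in (0, 1)]
    centers = []
    for ax in range(3):
        for v in (0.0, 1.0):
            c = np.full(3, 0.5)
            c[ax] = v
            centers.append(c)
    for c in centers:
        for p in corners:
            if np.isclose(np.abs(p - c).max(), 0.5):
                segs.append((p.astype(float), c))
    return np.array(segs)


def _kelvin_segments() -> np.ndarray:
    nodes, edges = kelvin_network()
    segs = []
    for i, j, shift in edges:
        segs.append((nodes[i], nodes[j] + shift))
    return np.array(segs)


_UNIT_SEGMENTS = {"fcc": _fcc_segments, "kelvin": _kelvin_segments}


def _point_segment_distance_grid(
    centers_x, centers_y, centers_z, p0: np.ndarray, p1: np.ndarray, r: float, out
):
    """Mark grid voxels within ``r`` of segment p0-p1 (bbox-restricted)."""
    lo = np.minimum(p0, p1) - r
    hi = np.maximum(p0, p1) + r
    ix = np.searchsorted(centers_x, [lo[0], hi[0]])
    iy = np.searchsorted(centers_y, [lo[1], hi[1]])
    iz = np.searchsorted(centers_z, [lo[2], hi[2]])
    if ix[0] >= ix[1] or iy[0] >= iy[1] or iz[0] >= iz[1]:
        return
    X = centers_x[ix[0] : ix[1]][:, None, None]
    Y = centers_y[iy[0] : iy[1]][None, :, None]
    Z = centers_z[iz[0] : iz[1]][None, None, :]
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        t = 0.0
        px, py, pz = p0
        dist2 = (X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2
    else:
        t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (
            (p0[0] + t * d[0] - X) ** 2
            + (p0[1] + t * d[1] - Y) ** 2
            + (p0[2] + t * d[2] - Z) ** 2
        )
    out[ix[0] : ix[1], iy[0] : iy[1], iz[0] : iz[1]] |= dist2 <= r * r


def _voxelize_segments(segments, r, centers) -> np.ndarray:
    cx, cy, cz = centers
    out = np.zeros((len(cx), len(cy), len(cz)), bool)
    for p0, p1 in segments:
        _point_segment_distance_grid(cx, cy, cz, np.asarray(p0), np.asarray(p1), r, out)
    return out


def unit_cell_occupancy(
    family: str, r_over_cell: float, n: int = 64, supersample: int = 4
) -> np.ndarray:
    """Periodic (n,n,n) solid fraction of one FCC/Kelvin cell.

    Partial-volume voxelization: each voxel carries the fraction of its
    ``supersample``^3 subsamples lying within the strut radius, which makes
    the cell porosity continuous in the radius and reduces the stair-step
    overstiffness of boolean voxelizations.
    """
    try:
        segs = _UNIT_SEGMENTS[family]() if isinstance(family, str) else family
    except KeyError:
        raise ValueError(f"family {family!r} has no periodic unit cell")
    # tile +-1 to wrap the periodic boundary
    tiled = []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                off = np.array([sx, sy, sz], float)
                tiled.append(segs + off[None, None, :])
    tiled = np.concatenate(tiled, axis=0)
    m = n * supersample
    c = (np.arange(m) + 0.5) / m
    fine = _voxelize_segments(tiled, r_over_cell, (c, c, c))
    if supersample == 1:
        return fine.astype(float)
    s = supersample
    return (
        fine.reshape(n, s, n, s, n, s).mean(axis=(1, 3, 5)).astype(float)
    )


def solve_unit_cell_radius(
    family: str,
    target_porosity: float,
    n: int = 64,
    tol: float = 2e-4,
    supersample: int = 4,
) -> float:
    """Strut radius (cell units) hitting the target porosity, by bisection."""
    lo, hi = 1e-3, 0.49
    n_eval = min(n, 48)  # porosity is resolution-insensitive with supersampling
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        phi = 1.0 - unit_cell_occupancy(family, mid, n_eval, supersample).mean()
        if abs(phi - target_porosity) < tol:
            return mid
        if phi > target_porosity:  # too porous -> thicker struts
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# device-scale generation
# ---------------------------------------------------------------------------

def _device_grid(footprint: CageFootprint, h: float):
    a, b = footprint.semi_axes
    t = footprint.thickness
    nx = int(np.ceil(2 * a / h)) + 2
    ny = int(np.ceil(2 * b / h)) + 2
    nz = int(np.ceil(t / h)) + 2
    origin = (-(nx * h) / 2, -(ny * h) / 2, -(nz * h) / 2)
    cx = origin[0] + (np.arange(nx) + 0.5) * h
    cy = origin[1] + (np.arange(ny) + 0.5) * h
    cz = origin[2] + (np.arange(nz) + 0.5) * h
    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]
    envelope = (
        ((X / a) ** 2 + (Y / b) ** 2 <= 1.0)
        & (np.abs(Z) <= t / 2)
        & np.ones((1, 1, nz), bool)
    )
    return (cx, cy, cz), origin, np.broadcast_to(envelope, (nx, ny, nz)).copy()


# generic lattice phase relative to the device: avoids degenerate alignment
# of lattice planes with voxel-centre planes (which quantizes the porosity)
_LATTICE_PHASE = np.array([0.2137, 0.3719, 0.1327])


def _device_segments(family: str, cell: float, footprint: CageFootprint):
    a, b = footprint.semi_axes
    t = footprint.thickness
    segs = _UNIT_SEGMENTS[family]() + _LATTICE_PHASE[None, None, :]
    nx = int(np.ceil(2 * a / cell)) + 1
    ny = int(np.ceil(2 * b / cell)) + 1
    nz = int(np.ceil(t / cell)) + 1
    out = []
    for i in range(-nx // 2 - 1, nx // 2 + 1):
        for j in range(-ny // 2 - 1, ny // 2 + 1):
            for k in range(-nz // 2 - 1, nz // 2 + 1):
                off = np.array([i, j, k], float)
                out.append((segs + off[None, None, :]) * cell)
    return np.concatenate(out, axis=0)


def _voronoi_segments(
    footprint: CageFootprint,
    spec: LatticeSpec,
    density_fn,
) -> np.ndarray:
    """Strut skeleton from the Voronoi diagram of (optionally graded) seeds."""
    from scipy.spatial import Voronoi

    rng = np.random.default_rng(spec.seed)
    a, b = footprint.semi_axes
    t = footprint.thickness
    pad = spec.cell_size
    box_lo = np.array([-a - pad, -b - pad, -t / 2 - pad])
    box_hi = np.array([a + pad, b + pad, t / 2 + pad])
    vol = np.prod(box_hi - box_lo)
    lam_max = max(density_fn(0.0), density_fn(1.0), density_fn(1.2))
    n_cand = rng.poisson(lam_max * vol)
    pts = box_lo + rng.random((n_cand, 3)) * (box_hi - box_lo)
    rho = np.sqrt((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2)
    accept = rng.random(n_cand) < np.array([density_fn(r) for r in rho]) / lam_max
    pts = pts[accept]
    if len(pts) < 8:
        raise ValueError("too few Voronoi seeds; increase density or seed box")
    vor = Voronoi(pts)
    segs = []
    lim_lo = box_lo - pad
    lim_hi = box_hi + pad
    for ridge in vor.ridge_vertices:
        if -1 in ridge:
            continue
        verts = vor.vertices[ridge]
        for u, v in zip(ridge, np.roll(ridge, -1)):
            p0, p1 = vor.vertices[u], vor.vertices[v]
            if np.all(p0 > lim_lo) and np.all(p0 < lim_hi) and np.all(
                p1 > lim_lo
            ) and np.all(p1 < lim_hi):
                segs.append((p0, p1))
    uniq = {}
    for p0, p1 in segs:
        key = tuple(np.round(np.minimum(p0, p1), 6)) + tuple(
            np.round(np.maximum(p0, p1), 6)
        )
        uniq[key] = (p0, p1)
    return np.array(list(uniq.values()))


def generate_lattice(footprint: CageFootprint, spec: LatticeSpec) -> ScaffoldModel:
    """Voxelized lattice scaffold clipped to the elliptical footprint.

    For FCC/Kelvin the strut radius is solved by bisection on the unit cell
    so the device porosity lands on ``target_porosity``; for Voronoi the
    seed-density / radius calibration is iterated on the device itself.
    Deterministic for a fixed ``spec.seed``.
    """
    if spec.family == "ti_ring":
        return generate_ti_ring(footprint, resolution=spec.resolution)
    centers, origin, envelope = _device_grid(footprint, spec.resolution)
    if spec.family in ("fcc", "kelvin"):
        if spec.strut_radius is None:
            r_cell = solve_unit_cell_radius(spec.family, spec.target_porosity)
            r = r_cell * spec.cell_size
        else:
            r = spec.strut_radius
        segs = _device_segments(spec.family, spec.cell_size, footprint)
        solid = _voxelize_segments(segs, r, centers) & envelope
        if spec.strut_radius is None:
            # correct for rim-clipped cells: bisect r on the device porosity
            phi = 1.0 - solid.sum() / envelope.sum()
            if abs(phi - spec.target_porosity) >= 0.003:
                lo, hi = 0.3 * r, 2.0 * r
                for _ in range(12):
                    r = 0.5 * (lo + hi)
                    solid = _voxelize_segments(segs, r, centers) & envelope
                    phi = 1.0 - solid.sum() / envelope.sum()
                    if abs(phi - spec.target_porosity) < 0.003:
                        break
                    if phi > spec.target_porosity:
                        lo = r
                    else:
                        hi = r
        model = ScaffoldModel(
            solid, envelope, spec.resolution, origin, spec.family, r,
            metadata={"cell_size": spec.cell_size, "target": spec.target_porosity},
        )
        return model
    # Voronoi
    return _generate_voronoi(footprint, spec, centers, origin, envelope)


def _radial_rho(centers, footprint):
    a, b = footprint.semi_axes
    X = centers[0][:, None, None]
    Y = centers[1][None, :, None]
    return np.sqrt((X / a) ** 2 + (Y / b) ** 2)


def _generate_voronoi(footprint, spec, centers, origin, envelope):
    a, b = footprint.semi_axes
    mean_cell = spec.cell_size * 1.6  # Voronoi cells are effectively smaller
    lam0 = 1.0 / mean_cell**3
    r = spec.strut_radius if spec.strut_radius is not None else 0.25

    if spec.gradient is None:
        lam_in = lam_out = lam0
        targets = (spec.target_porosity, spec.target_porosity)
    else:
        lam_in, lam_out = lam0, lam0
        targets = spec.gradient  # (inner, outer)

    rho_grid = None
    model = None
    graded = spec.gradient is not None
    for it in range(6):
        def density(rho, li=lam_in, lo=lam_out):
            if not graded:
                return li
            # power-law profile keeps the sparse core wide enough that the
            # denser rim's ridges do not flood it
            w = np.clip(rho, 0.0, 1.0) ** 2.5
            return li * (lo / li) ** w

        segs = _voronoi_segments(footprint, spec, density)
        solid = _voxelize_segments(segs, r, centers) & envelope
        if rho_grid is None:
            rho_grid = np.broadcast_to(
                _radial_rho(centers, footprint), envelope.shape
            )
        inner = envelope & (rho_grid < 0.2)
        outer = envelope & (rho_grid > 0.8)
        phi_in = 1 - solid[inner].mean()
        phi_out = 1 - solid[outer].mean()
        phi_whole = 1 - solid[envelope].mean()
        model = ScaffoldModel(
            solid, envelope, spec.resolution, origin, "voronoi", r,
            metadata={
                "seed": spec.seed,
                "phi_inner": float(phi_in),
                "phi_outer": float(phi_out),
                "lam_inner": float(lam_in),
                "lam_outer": float(lam_out),
            },
        )
        if graded:
            done = abs(phi_in - targets[0]) < 0.01 and abs(phi_out - targets[1]) < 0.01
        else:
            done = abs(phi_whole - targets[0]) < 0.005
        if done:
            break
        # solid fraction of a Poisson-Voronoi skeleton scales ~ lam^(2/3)
        if graded:
            adj_in = ((1 - targets[0]) / max(1 - phi_in, 1e-6)) ** 1.5
            adj_out = ((1 - targets[1]) / max(1 - phi_out, 1e-6)) ** 1.5
            lam_in *= np.clip(adj_in, 0.1, 8.0)
            lam_out *= np.clip(adj_out, 0.1, 8.0)
        else:
            adj = ((1 - targets[0]) / max(1 - phi_whole, 1e-6)) ** 1.5
            lam_in = lam_out = lam_in * np.clip(adj, 0.1, 8.0)
    return model


def generate_ti_ring(
    footprint: CageFootprint, wall_mm: float = 3.8, resolution: float = 0.15
) -> ScaffoldModel:
    """Solid elliptical ring comparator (mean wall thickness ~12% of the
    maximum diameter for the default geometry)."""
    a, b = footprint.semi_axes
    if wall_mm >= min(a, b):
        raise ValueError("wall thickness must be below the semi-minor axis")
    centers, origin, envelope = _device_grid(footprint, resolution)
    depth = ndimage.distance_transform_edt(envelope, sampling=(resolution,) * 3)
    # in-plane wall: measure depth on a single slice (thickness is axial-invariant)
    mid = envelope.shape[2] // 2
    depth2d = ndimage.distance_transform_edt(
        envelope[:, :, mid], sampling=(resolution,) * 2
    )
    ring2d = envelope[:, :, mid] & (depth2d <= wall_mm)
    solid = envelope & ring2d[:, :, None]
    return ScaffoldModel(
        solid, envelope, resolution, origin, "ti_ring", None,
        metadata={"wall_mm": wall_mm},
    )


def measure_porosity(
    model: ScaffoldModel,
    region: str = "whole",
    n_bins: int = 5,
    method: str = "voxel",
    n_samples: int = 200_000,
    seed: int = 0,
):
    """Porosity of a scaffold: whole-device scalar or radial-bin profile.

    ``voxel`` counts grid voxels (exact on the model's own discretization);
    ``montecarlo`` samples uniform random points in the envelope and reports
    the binomial standard error alongside.
    """
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        idx = np.argwhere(model.envelope)
        take = rng.integers(0, len(idx), n_samples)
        hits = model.solid[tuple(idx[take].T)]
        phi = 1.0 - hits.mean()
        se = float(np.sqrt(phi * (1 - phi) / n_samples))
        if region == "whole":
            return phi, se
        raise ValueError("montecarlo supports region='whole'")
    if region == "whole":
        return model.porosity
    if region == "radial_bins":
        nx, ny, nz = model.solid.shape
        h = model.spacing
        cx = model.origin[0] + (np.arange(nx) + 0.5) * h
        cy = model.origin[1] + (np.arange(ny) + 0.5) * h
        # normalized elliptical radius from the envelope's bounding ellipse
        ii, jj = np.where(model.envelope.any(axis=2))
        a = (cx[ii].max() - cx[ii].min()) / 2
        b = (cy[jj].max() - cy[jj].min()) / 2
        X = cx[:, None, None]
        Y = cy[None, :, None]
        rho = np.sqrt((X / a) ** 2 + (Y / b) ** 2)
        rho = np.broadcast_to(rho, model.solid.shape)
        edges = np.linspace(0, 1, n_bins + 1)
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = model.envelope & (rho >= lo) & (rho < hi)
            out.append(1.0 - model.solid[m].mean() if m.any() else np.nan)
        return np.array(out)
    raise ValueError(f"unknown region {region!r}")


def homogenize_unit_cell(
    family: str,
    strut_radius: float | None = None,
    cell_size: float = 1.0,
    E0: float = HAP_E0_GPA,
    nu0: float = 0.3,
    target_porosity: float | None = 0.75,
    n: int = 64,
) -> dict:
    """Periodic FE homogenization of one FCC/Kelvin cell.

    Returns the effective 6x6 stiffness (same units as ``E0``), the measured
    cell porosity, and the cubic-symmetry engineering modulus E = 1/S11.
    ``strut_radius`` is in mm (with ``cell_size`` in mm); if omitted it is
    solved from ``target_porosity``.
    """
    if family not in _UNIT_SEGMENTS:
        raise ValueError("homogenization requires a periodic cell (fcc/kelvin)")
    if strut_radius is None:
        if target_porosity is None:
            raise ValueError("give strut_radius or target_porosity")
        r_cell = solve_unit_cell_radius(family, target_porosity, n=n)
    else:
        r_cell = strut_radius / cell_size
    occ = unit_cell_occupancy(family, r_cell, n=n)
    phi = 1.0 - occ.mean()
    if not 0 <= phi < 1:
        raise ValueError(f"degenerate cell porosity {phi}")
    C = homogenize_periodic(occ, E0, nu0, cell_size=1.0)
    S = np.linalg.inv(C)
    # cubic symmetry check: the three axial moduli should agree
    E_axes = 1.0 / np.diag(S)[:3]
    spread = float(E_axes.max() - E_axes.min()) / E_axes.mean()
    if spread > 0.05:
        log.warning("unit cell deviates from cubic symmetry by %.1f%%", 100 * spread)
    return {
        "C_eff": C,
        "porosity": float(phi),
        "E_eff": float(E_axes.mean()),
        "E_axes": E_axes,
        "r_over_cell": float(r_cell),
        "n": n,
    }


def macroscopic_strength(sigma0: float, phi: float) -> float:
    """Porosity-scaled macroscopic strength: sigma = 1.21 (1-phi)^3 sigma0."""
    if not 0 <= phi < 1:
        raise ValueError("phi must lie in [0, 1)")
    return 1.21 * (1.0 - phi) ** 3 * sigma0


@dataclass
class StrengthModel:
    """Tension/compression strength thresholds for a scaffold porosity."""

    sigma0_tension: float = SIGMA0_TENSION_MPA
    sigma0_compression: float = SIGMA0_COMPRESSION_MPA
    phi: float = 0.75

    @property
    def tension(self) -> float:
        return macroscopic_strength(self.sigma0_tension, self.phi)

    @property
    def compression(self) -> float:
        return macroscopic_strength(self.sigma0_compression, self.phi)
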