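"""End-to-end fusion-construct assembly on synthetic two-vertebra scenes.

Pipeline: phantom CT scene -> isotropic resampling -> tissue calibration and
porosity -> gradient-structure-tensor fabric -> voxel micromechanics
(Mori-Tanaka cortical / Kelvin-cell trabecular, rotated into the voxel's
stiffness directions) -> tetrahedral mesh -> nearest-voxel material mapping
-> interbody scaffold + posterior fixation -> linear-static solve of the
standing / flexion load cases -> damage report.

Anatomical axes: x = left-right, y = posterior(-y) to anterior(+y), z = up.
Flexion applies the axial force plus a sagittal moment about -x, loading the
anterior half of the disc space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import ctprep
from .anisotropy import gradient_structure_tensor
from .ctprep import CalibrationParams
from .damage import (
    DamageReport,
    DamageThresholds,
    damaged_trabecular_volume,
    failed_volume,
    fixation_metrics,
    macroscopic_response,
)
from .fea import FixationSpec, LoadCase, solve_linear_static
from .micromech import CorticalModelParams, bone_voxel_stiffness
from .phantom import PhantomSpec, make_two_vertebra_scene
from .tetmesh import make_tet_mesh
from .volume import ImageVolume

log = logging.getLogger(__name__)

# scene element labels
TRAB_LOW, CORT_LOW, TRAB_UP, CORT_UP = 1, 2, 11, 12
SCAFFOLD, SCREW, ROD = 20, 30, 31
BONE_LABELS = (TRAB_LOW, CORT_LOW, TRAB_UP, CORT_UP)


@dataclass
class SceneModel:
    mesh: object
    materials: np.ndarray  # (m, 6, 6) MPa
    fixed_nodes: np.ndarray
    coupled_nodes: np.ndarray
    reference_point: tuple[float, float, float]
    element_sets: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)


def _cylinder_mask(centers, p0, p1, radius):
    cx, cy, cz = centers
    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dist2 = (
        (p0[0] + t * d[0] - X) ** 2
        + (p0[1] + t * d[1] - Y) ** 2
        + (p0[2] + t * d[2] - Z) ** 2
    )
    return dist2 <= radius**2


def build_fusion_scene(
    phantom_spec: PhantomSpec | None = None,
    scaffold: str = "fcc",
    gap_mm: float = 9.0,
    iso_mm: float | None = None,
    mesh_edge_mm: float = 1.6,
    scaffold_fit: float = 0.8,
    scaffold_porosity: float = 0.75,
    hap_E0_GPa: float = 100.0,
    fixation: FixationSpec | None = None,
    E0_trab_GPa: float = 13.0,
    homogenization_n: int = 32,
) -> SceneModel:
    """Assemble the meshed two-vertebra + cage + fixation model.

    ``scaffold``: "fcc" or "kelvin" (homogenized lattice stiffness from the
    periodic voxel FE at ``homogenization_n``^3) or "ti_ring" (solid Ti ring).
    The cage footprint is the vertebral footprint scaled by ``scaffold_fit``
    and fills the disc-space gap.  Ti6Al4V fixation: two pedicle screws per
    vertebra joined by two posterior vertical rods.
    """
    spec = phantom_spec or PhantomSpec()
    fix = fixation or FixationSpec()
    iso = iso_mm or spec.spacing[0]

    vol, truth = make_two_vertebra_scene(spec, gap_mm)
    iso_vol = ctprep.resample_isotropic(vol, iso)
    lab_iso = ctprep.resample_isotropic(
        ImageVolume(truth.labels.astype(float), vol.spacing, vol.origin),
        iso,
        spline_degree=0,
    )
    labels = np.round(lab_iso.values).astype(np.int16)

    # extend the grid posteriorly (-y) so the fixation rods fit inside it
    pad_mm = fix.rod_diameter + 4.0
    pad_vox = int(np.ceil(pad_mm / iso))
    labels = np.pad(labels, ((0, 0), (pad_vox, 0), (0, 0)))
    values = np.pad(iso_vol.values, ((0, 0), (pad_vox, 0), (0, 0)))
    iso_vol = ImageVolume(
        values,
        iso_vol.spacing,
        (iso_vol.origin[0], iso_vol.origin[1] - pad_vox * iso, iso_vol.origin[2]),
    )
    trab = (labels == TRAB_LOW) | (labels == TRAB_UP)
    cort = (labels == CORT_LOW) | (labels == CORT_UP)

    cal = ctprep.calibrate(iso_vol, trab, cort)
    poro = ctprep.porosity_field(iso_vol, trab, cort, cal)
    fab_t = gradient_structure_tensor(iso_vol, trab)
    fab_c = gradient_structure_tensor(iso_vol, cort)

    # --- implant geometry on the isotropic grid ---
    cx, cy, cz = iso_vol.voxel_centers()
    centers = (cx, cy, cz)
    a, b, _ = spec.body_half_axes
    z1, z2 = truth.gap_z
    sa, sb = scaffold_fit * a, scaffold_fit * b
    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]
    in_ellipse = (X / sa) ** 2 + (Y / sb) ** 2 <= 1.0
    # snug fit: fill each (x, y) column from the lower body's surface to the
    # upper body's surface, so cage and endplates share mesh nodes (tied)
    kidx = np.arange(len(cz))[None, None, :]
    lower_body = (labels == TRAB_LOW) | (labels == CORT_LOW)
    upper_body = (labels == TRAB_UP) | (labels == CORT_UP)
    ktop_low = np.where(
        lower_body.any(axis=2), np.max(np.where(lower_body, kidx, -1), axis=2), -1
    )
    big = len(cz) + 1
    kbot_up = np.where(
        upper_body.any(axis=2), np.min(np.where(upper_body, kidx, big), axis=2), big
    )
    in_gap = (
        (kidx > ktop_low[:, :, None])
        & (kidx < kbot_up[:, :, None])
        & (ktop_low[:, :, None] >= 0)
        & (kbot_up[:, :, None] < big)
        & (Z > z1 - 3.0)
        & (Z < z2 + 3.0)
    )
    if scaffold == "ti_ring":
        wall = 3.8
        inner = (X / max(sa - wall, 1e-6)) ** 2 + (Y / max(sb - wall, 1e-6)) ** 2 <= 1.0
        cage = in_ellipse & ~inner & in_gap
    else:
        cage = in_ellipse & in_gap
    scene_lab = labels.copy()
    scene_lab[cage & (scene_lab == 0)] = SCAFFOLD

    # fixation: screws along y into each body, rods vertical at the posterior
    rs = fix.screw_diameter / 2
    rr_ = fix.rod_diameter / 2
    x_off = 0.45 * a
    y_rod = -(b + 2.0 + rr_)
    z_low = 0.5 * (cz.min() + z1) + 0.25 * (z1 - cz.min())
    z_up = z2 + 0.55 * (cz.max() - z2) * 0.5
    zc_low = z1 - 0.45 * (z1 - cz.min())
    zc_up = z2 + 0.45 * (cz.max() - z2)
    screw_mask = np.zeros(scene_lab.shape, bool)
    for xs in (-x_off, x_off):
        for zc in (zc_low, zc_up):
            screw_mask |= _cylinder_mask(
                centers, (xs, y_rod, zc), (xs, 0.4 * b, zc), rs
            )
    rod_mask = np.zeros(scene_lab.shape, bool)
    for xs in (-x_off, x_off):
        rod_mask |= _cylinder_mask(
            centers, (xs, y_rod, zc_low), (xs, y_rod, zc_up), rr_
        )
    scene_lab[screw_mask] = SCREW
    scene_lab[rod_mask & (scene_lab != SCREW)] = ROD

    # --- mesh and materials ---
    mesh = make_tet_mesh(
        scene_lab, mesh_edge_mm, spacing=(iso,) * 3, origin=iso_vol.origin
    )
    mat_label = mesh.element_material
    m = mesh.n_elements
    materials = np.zeros((m, 6, 6))

    from .voigt import isotropic_stiffness

    ti = isotropic_stiffness(fix.E, fix.nu)
    for lab_id in (SCREW, ROD):
        materials[mat_label == lab_id] = ti

    if scaffold == "ti_ring":
        materials[mat_label == SCAFFOLD] = ti
        thresholds = None
        scaffold_meta = {"kind": "ti_ring"}
    else:
        from .scaffold import homogenize_unit_cell

        hom = homogenize_unit_cell(
            scaffold, E0=hap_E0_GPa, target_porosity=scaffold_porosity,
            n=homogenization_n,
        )
        materials[mat_label == SCAFFOLD] = hom["C_eff"] * 1000.0  # GPa -> MPa
        thresholds = DamageThresholds.homogenized(scaffold_porosity)
        scaffold_meta = {
            "kind": scaffold,
            "E_eff_GPa": hom["E_eff"],
            "porosity": hom["porosity"],
        }

    # bone: nearest-voxel mapping then micromechanics on the used voxels
    bone_el = np.isin(mat_label, BONE_LABELS)
    bone_vox = np.argwhere(trab | cort)
    vox_xyz = bone_vox * iso + np.asarray(iso_vol.origin)
    tree = cKDTree(vox_xyz)
    _, pick = tree.query(mesh.centroids()[bone_el], k=1)
    vi = bone_vox[pick]
    vidx = tuple(vi.T)
    is_cort = cort[vidx]
    flag_t = fab_t.isotropic[vidx]
    flag_c = fab_c.isotropic[vidx]
    flagged = np.where(is_cort, flag_c, flag_t)
    Rvox = np.where(is_cort, fab_c.R[vidx], fab_t.R[vidx])
    evec = np.where(
        is_cort[:, None, None], fab_c.eigenvectors[vidx], fab_t.eigenvectors[vidx]
    )
    materials[bone_el] = bone_voxel_stiffness(
        poro.porosity[vidx], is_cort, flagged, Rvox, evec, E0_trab_GPa
    )

    # --- boundary conditions ---
    zmin, zmax = mesh.nodes[:, 2].min(), mesh.nodes[:, 2].max()
    fixed = np.where(mesh.nodes[:, 2] <= zmin + 1.01 * mesh_edge_mm)[0]
    coupled = np.where(mesh.nodes[:, 2] >= zmax - 1.01 * mesh_edge_mm)[0]
    rp = (0.0, 0.0, float(zmax) + 5.0)

    esets = {
        "scaffold": np.where(mat_label == SCAFFOLD)[0],
        "trabecular": np.where((mat_label == TRAB_LOW) | (mat_label == TRAB_UP))[0],
        "cortical": np.where((mat_label == CORT_LOW) | (mat_label == CORT_UP))[0],
        "screws": np.where(mat_label == SCREW)[0],
        "rod_left": np.where(
            (mat_label == ROD) & (mesh.centroids()[:, 0] < 0)
        )[0],
        "rod_right": np.where(
            (mat_label == ROD) & (mesh.centroids()[:, 0] >= 0)
        )[0],
    }
    return SceneModel(
        mesh=mesh,
        materials=materials,
        fixed_nodes=fixed,
        coupled_nodes=coupled,
        reference_point=rp,
        element_sets=esets,
        metadata={
            "scaffold": scaffold_meta,
            "thresholds": thresholds,
            "calibration": cal,
            "iso_mm": iso,
            "mesh_edge_mm": mesh_edge_mm,
            "n_elements": mesh.n_elements,
        },
    )


def run_load_case(scene: SceneModel, case: str = "standing", moment_Nm: float = 7.5):
    """Solve one physiological load case on an assembled scene."""
    if case == "standing":
        load = LoadCase.standing(scene.reference_point)
    elif case == "flexion":
        load = LoadCase.flexion(scene.reference_point, moment_Nm)
        load.name = "flexion"
    else:
        raise ValueError(f"unknown load case {case!r}")
    res = solve_linear_static(
        scene.mesh,
        scene.materials,
        scene.fixed_nodes,
        load,
        coupled_nodes=scene.coupled_nodes,
    )
    return res, load


def evaluate_scene(
    scene: SceneModel,
    res,
    load,
    thresholds: DamageThresholds | None = None,
) -> DamageReport:
    """Full damage report for one solved load case."""
    mesh = scene.mesh
    vols = mesh.volumes()
    sc = scene.element_sets["scaffold"]
    thr = thresholds or scene.metadata.get("thresholds") or DamageThresholds()
    if len(sc):
        fv = failed_volume(res.principal_stress[sc], vols[sc], thr, "either")
        ft = failed_volume(res.principal_stress[sc], vols[sc], thr, "tension")
        fc = failed_volume(res.principal_stress[sc], vols[sc], thr, "compression")
    else:
        fv = ft = fc = 0.0
    tr = scene.element_sets["trabecular"]
    dmg_trab = damaged_trabecular_volume(res.principal_strain[tr], vols[tr])
    rods = {
        "left": scene.element_sets["rod_left"],
        "right": scene.element_sets["rod_right"],
    }
    fx = fixation_metrics(mesh, res, rods, load.axial_force)
    macro = macroscopic_response(res, load)
    return DamageReport(
        failed_volume_pct=fv,
        failed_tension_pct=ft,
        failed_compression_pct=fc,
        damaged_trabecular_pct=dmg_trab,
        fixation_yield_ratio=fx["yield_ratio"],
        rod_microstrain={
            k: (v["min_microstrain"], v["max_microstrain"])
            for k, v in fx["per_rod"].items()
        },
        load_share_pct=fx["load_share_pct"],
        stiffness_kN_mm=macro["stiffness_kN_mm"],
        rotation_deg=macro["rotation_deg"],
    )


def anterior_posterior_failed(scene: SceneModel, res, thresholds=None) -> dict:
    """Failed scaffold volume split into anterior (+y) and posterior halves."""
    mesh = scene.mesh
    vols = mesh.volumes()
    sc = scene.element_sets["scaffold"]
    thr = thresholds or scene.metadata.get("thresholds") or DamageThresholds()
    ys = mesh.centroids()[sc, 1]
    ant = sc[ys > np.median(ys)]
    post = sc[ys <= np.median(ys)]
    out = {}
    for name, els in (("anterior", ant), ("posterior", post)):
        out[name] = failed_volume(res.principal_stress[els], vols[els], thr, "either")
    return out
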