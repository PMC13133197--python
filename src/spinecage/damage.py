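"""Damage and performance metrics extracted from FE results.

All volume percentages are volume-weighted (element volumes, not counts).
Scaffold failure compares principal stresses against tension/compression
thresholds — dense-ceramic limits for microstructured devices, the
porosity-scaled law for homogenized ones.  Trabecular damage counts volume
whose minimum principal strain exceeds the vertebral trabecular compressive
limit (0.84% magnitude).  Fixation metrics report the yield-stress ratio,
axial microstrains and the load share carried by the posterior rods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

TRABECULAR_STRAIN_LIMIT = 0.0084  # compressive principal strain magnitude


@dataclass
class DamageThresholds:
    """Stress thresholds (MPa) for scaffold failure evaluation."""

    tension: float = 100.0
    compression: float = 350.0

    @classmethod
    def homogenized(cls, phi: float, sigma0_t: float = 100.0, sigma0_c: float = 350.0):
        from .scaffold import macroscopic_strength

        return cls(
            tension=macroscopic_strength(sigma0_t, phi),
            compression=macroscopic_strength(sigma0_c, phi),
        )


@dataclass
class DamageReport:
    """Aggregate post-processing results for one load case / device."""

    failed_volume_pct: float = 0.0
    failed_tension_pct: float = 0.0
    failed_compression_pct: float = 0.0
    damaged_trabecular_pct: float = 0.0
    fixation_yield_ratio: float = float("inf")
    rod_microstrain: dict = field(default_factory=dict)
    load_share_pct: float = 0.0
    stiffness_kN_mm: float = 0.0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        for v in (
            self.failed_volume_pct,
            self.failed_tension_pct,
            self.failed_compression_pct,
            self.damaged_trabecular_pct,
        ):
            if not 0 <= v <= 100:
                raise ValueError("percentages must lie in [0, 100]")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["fixation_yield_ratio"] = (
            None
            if not np.isfinite(self.fixation_yield_ratio)
            else self.fixation_yield_ratio
        )
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    def to_csv(self, path) -> None:
        d = asdict(self)
        d.pop("rod_microstrain")
        with open(path, "w") as fh:
            fh.write(",".join(d.keys()) + "\n")
            fh.write(",".join(f"{v}" for v in d.values()) + "\n")


def failed_volume(
    principal_stress: np.ndarray,
    volumes: np.ndarray,
    thresholds: DamageThresholds,
    mode: str = "either",
) -> float:
    """Volume percentage of elements beyond the stress thresholds.

    ``tension``: max principal stress above the tensile limit;
    ``compression``: |min principal stress| above the compressive limit;
    ``either``: union of the two.
    """
    if len(principal_stress) == 0:
        raise ValueError("empty element set")
    smax = principal_stress[:, -1]
    smin = principal_stress[:, 0]
    tens = smax > thresholds.tension
    comp = -smin > thresholds.compression
    sel = {"tension": tens, "compression": comp, "either": tens | comp}.get(mode)
    if sel is None:
        raise ValueError(f"unknown mode {mode!r}")
    return float(100.0 * volumes[sel].sum() / volumes.sum())


def damaged_trabecular_volume(
    principal_strain: np.ndarray,
    volumes: np.ndarray,
    limit: float = TRABECULAR_STRAIN_LIMIT,
) -> float:
    """Volume percentage with minimum principal strain below -limit."""
    if len(principal_strain) == 0:
        return 0.0
    sel = principal_strain[:, 0] < -abs(limit)
    return float(100.0 * volumes[sel].sum() / volumes.sum())


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    s = np.asarray(stress_voigt, float)
    return np.sqrt(
        0.5
        * (
            (s[:, 0] - s[:, 1]) ** 2
            + (s[:, 1] - s[:, 2]) ** 2
            + (s[:, 2] - s[:, 0]) ** 2
        )
        + 3.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
    )


def fixation_metrics(
    mesh,
    result,
    rod_sets: dict[str, np.ndarray],
    applied_axial: float,
    sigma_yield: float = 795.0,
    central_fraction: float = 0.5,
    cap: float = 1e6,
) -> dict:
    """Yield ratio, axial microstrains and load share of the fixation rods.

    The yield ratio is sigma_yield over the maximum von Mises stress in the
    central portion of each rod (capped for unloaded models).  The load
    share integrates sigma_zz over a mid-rod planar band:
    F_z = sum(sigma_zz * V_e) / band_thickness, reported as a percentage of
    the applied axial force.
    """
    if not rod_sets:
        raise ValueError("no rod element sets given")
    vols = mesh.volumes()
    cents = mesh.centroids()
    out = {"per_rod": {}}
    total_force = 0.0
    smax_all = 0.0
    for name, els in rod_sets.items():
        els = np.asarray(els, int)
        if len(els) == 0:
            raise ValueError(f"rod set {name!r} is empty")
        z = cents[els, 2]
        zmid = 0.5 * (z.min() + z.max())
        half = central_fraction * 0.5 * (z.max() - z.min())
        central = els[np.abs(z - zmid) <= max(half, 1e-9)]
        vm = von_mises(result.stress[central])
        smax = float(vm.max()) if len(central) else 0.0
        smax_all = max(smax_all, smax)
        ezz = result.strain[central, 2] * 1e6  # microstrain
        band = max(2.0 * (vols[central].mean()) ** (1 / 3), 1e-9)
        inband = els[np.abs(z - zmid) <= band / 2]
        Fz = float(
            (result.stress[inband, 2] * vols[inband]).sum() / band
        )
        total_force += Fz
        out["per_rod"][name] = {
            "max_von_mises_MPa": smax,
            "min_microstrain": float(ezz.min()) if len(central) else 0.0,
            "max_microstrain": float(ezz.max()) if len(central) else 0.0,
            "axial_force_N": Fz,
        }
    out["yield_ratio"] = float(min(sigma_yield / smax_all, cap)) if smax_all > 0 else cap
    out["load_share_pct"] = float(100.0 * abs(total_force) / max(abs(applied_axial), 1e-12))
    return out


def macroscopic_response(result, load) -> dict:
    """System stiffness (kN/mm) and reference-point rotation (deg)."""
    if result.rp_u is None:
        raise ValueError("solve had no reference point")
    uz = float(result.rp_u[2])
    if uz == 0:
        raise ValueError("zero reference-point displacement")
    k = abs(load.axial_force / uz) / 1000.0  # kN/mm
    rot = float(np.degrees(np.linalg.norm(result.rp_theta)))
    return {"stiffness_kN_mm": k, "rotation_deg": rot}
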