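"""Synthetic vertebra phantoms with known porosity and texture orientation.

The phantom body is an ellipsoid-cylinder (elliptical cross-section, flat
superellipsoid caps) with a thin high-HU cortical shell and a trabecular core
carrying an oriented texture.  Texture synthesis filters white Gaussian noise
with an anisotropic Gaussian kernel whose correlation length is longest along
``texture_direction``: for such a field the gradient-structure-tensor
eigenvalue along the long axis scales as 1/sigma_par^2, giving an analytic
handle on the degree of anisotropy,

    DA = 1 - (sigma_perp / sigma_par)^2   =>   sigma_par = sigma_perp / sqrt(1 - DA),

so the requested ``texture_anisotropy`` is dialled in directly.  Every output
is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import ctprep
from .ctprep import OUTSIDE, TRABECULAR, CORTICAL, CalibrationParams
from .volume import ImageVolume, write_volume


@dataclass
class PhantomSpec:
    """Generation parameters for a single synthetic vertebral body."""

    body_half_axes: tuple[float, float, float] = (18.0, 14.0, 12.5)  # mm
    cortical_thickness: float = 1.0  # mm (may dip to ~1 voxel locally)
    spacing: tuple[float, float, float] = (0.326, 0.326, 0.6)  # mm
    hu_cortical_range: tuple[float, float] = (700.0, 1400.0)
    hu_trabecular_mode: float = 220.0
    hu_trabecular_spread: float = 70.0
    texture_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    texture_anisotropy: float = 0.4  # target DA in [0, 1)
    noise_sd: float = 5.0  # additive white HU noise
    sigma_perp: float = 0.35  # base correlation length, mm (~trabecular spacing)
    tail_strength: float = 0.6  # high-HU tail of the trabecular histogram
    margin_mm: float = 3.0  # air margin around the body
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.body_half_axes):
            raise ValueError("degenerate body half-axes: all must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0 <= self.texture_anisotropy < 1:
            raise ValueError("texture_anisotropy must lie in [0, 1)")
        if not self.hu_cortical_range[0] > self.hu_trabecular_mode:
            raise ValueError("cortical HU range must sit above the trabecular mode")
        if self.cortical_thickness <= 0:
            raise ValueError("cortical_thickness must be positive")
        n = np.linalg.norm(self.texture_direction)
        if n == 0:
            raise ValueError("texture_direction must be a non-zero vector")
        self.texture_direction = tuple(np.asarray(self.texture_direction) / n)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = tuple(float(x) for x in v)
            elif isinstance(v, (np.floating, np.integer)):
                d[k] = float(v)
        return d


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    porosity_truth: np.ndarray
    direction_truth: np.ndarray  # (nx, ny, nz, 3); zero where undefined
    labels: np.ndarray  # OUTSIDE / TRABECULAR / CORTICAL (per body: +10*(body-1))
    calibration: CalibrationParams | None = None
    gap_z: tuple[float, float] | None = None  # world z of the disc-space gap
    footprint: dict | None = None  # elliptical footprint of the gap surfaces


def _oriented_noise(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    direction: np.ndarray,
    sigma_perp: float,
    sigma_par: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian field with an anisotropic Gaussian spectrum."""
    noise = rng.standard_normal(shape)
    spec = np.fft.rfftn(noise)
    ks = [np.fft.fftfreq(shape[a], d=spacing[a]) for a in range(2)]
    ks.append(np.fft.rfftfreq(shape[2], d=spacing[2]))
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    kpar = kx * direction[0] + ky * direction[1] + kz * direction[2]
    two_pi2 = 2.0 * np.pi**2
    # isotropic sigma_perp plus extra smoothing along the texture direction
    filt = np.exp(
        -two_pi2 * (sigma_perp**2 * k2 + (sigma_par**2 - sigma_perp**2) * kpar**2)
    )
    out = np.fft.irfftn(spec * filt, s=shape, axes=(0, 1, 2))
    sd = out.std()
    return out / (sd if sd > 0 else 1.0)


def _body_mask(spec: PhantomSpec, shape, origin) -> np.ndarray:
    a, b, c = spec.body_half_axes
    coords = [
        origin[i] + spec.spacing[i] * np.arange(shape[i]) for i in range(3)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    # elliptical cylinder with superellipsoid (flat-ish) endplates
    return (x / a) ** 2 + (y / b) ** 2 + np.abs(z / c) ** 8 <= 1.0


def _shell_split(mask: np.ndarray, spacing, thickness: float):
    from scipy import ndimage

    depth = ndimage.distance_transform_edt(mask, sampling=spacing)
    cortical = mask & (depth <= thickness + 1e-9)
    trabecular = mask & ~cortical
    return cortical, trabecular


def make_vertebra_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Generate a single-vertebra CT-like volume and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.body_half_axes
    m = spec.margin_mm
    shape = tuple(
        int(np.ceil(2 * (ax + m) / spec.spacing[i]))
        for i, ax in enumerate((a, b, c))
    )
    origin = tuple(-(ax + m) for ax in (a, b, c))
    mask = _body_mask(spec, shape, origin)
    if not mask.any():
        raise ValueError("degenerate half-axes: body contains no voxels")
    cortical, trabecular = _shell_split(mask, spec.spacing, spec.cortical_thickness)
    if not trabecular.any():
        raise ValueError("cortical shell swallowed the whole body")

    d = np.asarray(spec.texture_direction, float)
    da = spec.texture_anisotropy
    sigma_par = spec.sigma_perp / np.sqrt(1.0 - da) if da > 0 else spec.sigma_perp
    tex = _oriented_noise(shape, spec.spacing, d, spec.sigma_perp, sigma_par, rng)

    hu = np.zeros(shape)
    # trabecular: unimodal around the mode with a controllable high-HU tail
    trab_hu = (
        spec.hu_trabecular_mode
        + spec.hu_trabecular_spread * tex
        + spec.tail_strength * spec.hu_trabecular_spread * np.maximum(tex, 0.0) ** 2
    )
    hu[trabecular] = trab_hu[trabecular]
    lo, hi = spec.hu_cortical_range
    from scipy import ndimage

    depth = ndimage.distance_transform_edt(mask, sampling=spec.spacing)
    ramp = np.clip(depth / max(spec.cortical_thickness, 1e-9), 0.0, 1.0)
    hu[cortical] = (hi - (hi - lo) * 0.5 * ramp[cortical]) - 0.1 * (hi - lo) * np.abs(
        tex[cortical]
    )
    hu += spec.noise_sd * rng.standard_normal(shape)
    np.clip(hu, -200.0, hi + 200.0, out=hu)

    labels = np.full(shape, OUTSIDE, dtype=np.uint8)
    labels[trabecular] = TRABECULAR
    labels[cortical] = CORTICAL
    vol = ImageVolume(hu, spec.spacing, origin)

    cal = CalibrationParams(
        hu_mode_trab=spec.hu_trabecular_mode,
        hu_min_trab=float(hu[trabecular].min()),
        hu_threshold=float(np.quantile(hu[mask], 0.98)),
        hu_min_cort=float(hu[cortical].min()),
    )
    porosity = np.zeros(shape)
    porosity[trabecular] = ctprep.hu_to_porosity_trabecular(hu[trabecular], cal)
    porosity[cortical] = ctprep.hu_to_porosity_cortical(hu[cortical], cal)
    direction = np.zeros(shape + (3,))
    direction[trabecular] = d
    truth = PhantomTruth(
        porosity_truth=porosity,
        direction_truth=direction,
        labels=labels,
        calibration=cal,
    )
    return vol, truth


def make_two_vertebra_scene(
    spec: PhantomSpec, gap_mm: float
) -> tuple[ImageVolume, PhantomTruth]:
    """Two stacked vertebral bodies separated by a disc-space gap.

    The lower body occupies labels {1, 2}, the upper {11, 12}
    (trabecular/cortical + 10*(body-1)).  The gap's bounding planes and the
    elliptical footprint of the facing endplates are reported for scaffold
    fitting.
    """
    if gap_mm <= 0:
        raise ValueError("gap_mm must be positive (bodies would overlap)")
    vol1, truth1 = make_vertebra_phantom(spec)
    spec2 = PhantomSpec(**{**spec.to_dict(), "seed": spec.seed + 1})
    vol2, truth2 = make_vertebra_phantom(spec2)

    sz = spec.spacing[2]
    gap_vox = max(1, int(round(gap_mm / sz)))

    # crop the axial air margins so the surface-to-surface gap equals gap_mm
    def _crop_z(vol, truth, keep_low, keep_high):
        ks = np.where((truth.labels != OUTSIDE).any(axis=(0, 1)))[0]
        k0 = 0 if keep_low else int(ks.min())
        k1 = vol.shape[2] if keep_high else int(ks.max()) + 1
        v = ImageVolume(
            vol.values[:, :, k0:k1],
            vol.spacing,
            (vol.origin[0], vol.origin[1], vol.origin[2] + k0 * sz),
        )
        t = PhantomTruth(
            porosity_truth=truth.porosity_truth[:, :, k0:k1],
            direction_truth=truth.direction_truth[:, :, k0:k1],
            labels=truth.labels[:, :, k0:k1],
            calibration=truth.calibration,
        )
        return v, t

    vol1, truth1 = _crop_z(vol1, truth1, keep_low=True, keep_high=False)
    vol2, truth2 = _crop_z(vol2, truth2, keep_low=False, keep_high=True)
    nz1 = vol1.shape[2]
    shape = vol1.shape[:2] + (nz1 + gap_vox + vol2.shape[2],)
    hu = np.full(shape, 0.0)
    rng = np.random.default_rng(spec.seed + 2)
    hu += spec.noise_sd * rng.standard_normal(shape)
    labels = np.zeros(shape, np.uint8)
    porosity = np.zeros(shape)
    direction = np.zeros(shape + (3,))

    hu[:, :, :nz1] = vol1.values
    labels[:, :, :nz1] = truth1.labels
    porosity[:, :, :nz1] = truth1.porosity_truth
    direction[:, :, :nz1] = truth1.direction_truth
    z2 = nz1 + gap_vox
    hu[:, :, z2:] = vol2.values
    up = truth2.labels != OUTSIDE
    lab2 = truth2.labels.astype(np.uint8).copy()
    lab2[up] += 10
    labels[:, :, z2:] = lab2
    porosity[:, :, z2:] = truth2.porosity_truth
    direction[:, :, z2:] = truth2.direction_truth

    origin = (vol1.origin[0], vol1.origin[1], vol1.origin[2])
    vol = ImageVolume(hu, spec.spacing, origin)
    # world z of the top of the lower body / bottom of the upper body
    z_top_lower = origin[2] + (nz1 - 0.5) * sz
    z_bot_upper = origin[2] + (z2 - 0.5) * sz
    a, b, _ = spec.body_half_axes
    truth = PhantomTruth(
        porosity_truth=porosity,
        direction_truth=direction,
        labels=labels,
        calibration=truth1.calibration,
        gap_z=(z_top_lower, z_bot_upper),
        footprint={"half_axes_mm": (a, b), "center_xy_mm": (0.0, 0.0)},
    )
    return vol, truth


def dump_provenance(spec: PhantomSpec, path: str | Path) -> None:
    """Persist all generation parameters as YAML for provenance."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)


def export_phantom(
    vol: ImageVolume,
    truth: PhantomTruth,
    spec: PhantomSpec,
    outdir: str | Path,
    fmt: str = "nii.gz",
) -> dict[str, Path]:
    """Write volume, labels and truth fields (NIfTI/NRRD) plus YAML config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    items = {
        f"hu.{fmt}": vol,
        "labels.nrrd": ImageVolume(
            truth.labels.astype(np.int16), vol.spacing, vol.origin
        ),
        "porosity_truth.nrrd": ImageVolume(
            truth.porosity_truth, vol.spacing, vol.origin
        ),
    }
    for name, v in items.items():
        p = outdir / name
        write_volume(v, p)
        paths[name] = p
    dump_provenance(spec, outdir / "phantom.yaml")
    paths["phantom.yaml"] = outdir / "phantom.yaml"
    return paths
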