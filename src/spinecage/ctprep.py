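"""CT preparation: isotropic resampling, threshold segmentation, HU→porosity.

The porosity mapping uses two split linear laws calibrated on the scan's own
HU statistics.  Trabecular voxels interpolate between a modal porosity at the
modal HU value and a maximum porosity at the lowest trabecular HU; cortical
voxels interpolate between zero porosity at the dense-bone HU threshold (the
98th percentile of the fitted HU distribution) and a maximum cortical
porosity at the lowest cortical HU.  Both maps clamp to their physical range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, stats

from .volume import ImageVolume, from_sitk, to_sitk

log = logging.getLogger(__name__)

# tissue-class codes used throughout the package
OUTSIDE, TRABECULAR, CORTICAL = 0, 1, 2


@dataclass
class CalibrationParams:
    """Parameters of the split linear HU→porosity laws."""

    hu_mode_trab: float
    hu_min_trab: float
    hu_threshold: float
    hu_min_cort: float
    phi_max_trab: float = 0.92
    phi_mode_trab: float = 0.85
    phi_max_cort: float = 0.5
    cdf_level: float = 0.98
    distribution_family: str = "skewnorm"

    def __post_init__(self) -> None:
        if not self.hu_min_trab < self.hu_mode_trab:
            raise ValueError("hu_min_trab must be below hu_mode_trab")
        if not self.hu_min_cort < self.hu_threshold:
            raise ValueError("hu_min_cort must be below hu_threshold")
        if not 0 < self.phi_mode_trab < self.phi_max_trab <= 1:
            raise ValueError("need 0 < phi_mode_trab < phi_max_trab <= 1")
        if not 0 < self.phi_max_cort < 1:
            raise ValueError("phi_max_cort must lie in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PorosityField:
    """Per-voxel porosity in [0,1] plus tissue-class labels."""

    porosity: np.ndarray
    tissue: np.ndarray  # OUTSIDE / TRABECULAR / CORTICAL

    def __post_init__(self) -> None:
        inside = self.tissue != OUTSIDE
        p = self.porosity[inside]
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("porosity must lie in [0,1] inside tissue")


def resample_isotropic(
    vol: ImageVolume, target_mm: float, spline_degree: int = 3
) -> ImageVolume:
    """Resample to isotropic spacing with B-spline interpolation.

    The physical extent is preserved to within one voxel; the new grid keeps
    the original origin.  ``spline_degree`` 0 gives nearest-neighbour (for
    label volumes), 1 trilinear, 3 cubic B-spline.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if np.issubdtype(vol.values.dtype, np.floating) and not np.all(
        np.isfinite(vol.values)
    ):
        raise ValueError("input volume contains non-finite values")
    img = to_sitk(ImageVolume(np.asarray(vol.values, float), vol.spacing, vol.origin))
    new_size = [
        max(1, int(round(vol.shape[a] * vol.spacing[a] / target_mm)))
        for a in range(3)
    ]
    interp = {
        0: sitk.sitkNearestNeighbor,
        1: sitk.sitkLinear,
        3: sitk.sitkBSpline,
    }.get(spline_degree)
    if interp is None:
        raise ValueError(f"unsupported spline degree {spline_degree}")
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_mm,) * 3,
        img.GetDirection(),
        float(np.min(vol.values)),
        sitk.sitkFloat64,
    )
    return from_sitk(res)


def segment_by_threshold(
    vol: ImageVolume,
    lo: float,
    hi: float,
    morphology_ops: Sequence[tuple[str, int]] = (),
) -> np.ndarray:
    """Binary segmentation by HU window, with optional morphology.

    ``morphology_ops`` is a sequence of ``(op, radius_voxels)`` with op in
    {"closing", "opening", "dilation", "erosion"}; closing is the one used to
    enforce continuity of thin cortical shells.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    mask = (vol.values >= lo) & (vol.values <= hi)
    for op, radius in morphology_ops:
        ball = _ball(radius)
        fn = {
            "closing": ndimage.binary_closing,
            "opening": ndimage.binary_opening,
            "dilation": ndimage.binary_dilation,
            "erosion": ndimage.binary_erosion,
        }.get(op)
        if fn is None:
            raise ValueError(f"unknown morphology op {op!r}")
        mask = fn(mask, structure=ball)
    if not mask.any():
        log.warning("threshold segmentation [%s, %s] selected no voxels", lo, hi)
    return mask


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


_FAMILIES = {
    "skewnorm": stats.skewnorm,
    "normal": stats.norm,
    "gamma": stats.gamma,
}


def fit_hu_threshold(
    hu_samples: np.ndarray,
    family: str = "skewnorm",
    cdf_level: float = 0.98,
) -> tuple[float, dict]:
    """HU value at a cumulative-frequency level of a fitted distribution.

    Fits the requested family by maximum likelihood and returns its quantile
    at ``cdf_level`` together with fit diagnostics (log-likelihood and a
    quantile-quantile RMS error).  If the fit fails or is grossly inadequate
    the empirical quantile is returned and flagged.
    """
    x = np.asarray(hu_samples, float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 samples to fit the HU distribution")
    if not 0 < cdf_level < 1:
        raise ValueError("cdf_level must lie in (0,1)")
    empirical = float(np.quantile(x, cdf_level))
    try:
        dist = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; options: {sorted(_FAMILIES)}")
    try:
        params = dist.fit(x)
        frozen = dist(*params)
        thr = float(frozen.ppf(cdf_level))
        ll = float(np.sum(frozen.logpdf(x)))
        q = np.linspace(0.01, 0.99, 50)
        qq_rmse = float(
            np.sqrt(np.mean((np.quantile(x, q) - frozen.ppf(q)) ** 2))
        )
        # adequacy by the KS *statistic* (scale-free); p-values reject any
        # parametric family at CT sample sizes
        ks = float(stats.kstest(x, frozen.cdf).statistic)
        ok = np.isfinite(thr) and ks < 0.1
    except Exception:  # non-convergence → empirical fallback
        ok = False
        thr, ll, qq_rmse, params = np.nan, np.nan, np.nan, None
    if not ok:
        log.info("HU distribution fit inadequate; empirical quantile used")
        return empirical, {"fallback": True, "family": family}
    diag = {
        "fallback": False,
        "family": family,
        "params": tuple(float(p) for p in params),
        "loglik": ll,
        "qq_rmse": qq_rmse,
        "empirical_quantile": empirical,
    }
    return thr, diag


def calibrate(
    vol: ImageVolume,
    trabecular: np.ndarray,
    cortical: np.ndarray,
    family: str = "skewnorm",
    cdf_level: float = 0.98,
    n_bins: int = 128,
) -> CalibrationParams:
    """Derive calibration parameters from a volume and its tissue labels.

    The modal trabecular HU comes from the histogram mode inside the
    trabecular label; HU minima are taken inside the respective labels; the
    dense-bone threshold is the fitted distribution's quantile at
    ``cdf_level`` over the full vertebral body (union of both labels).
    """
    trab_hu = vol.values[trabecular]
    cort_hu = vol.values[cortical]
    if trab_hu.size == 0 or cort_hu.size == 0:
        raise ValueError("labels must be non-empty")
    hist, edges = np.histogram(trab_hu, bins=n_bins)
    mode = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    body = np.concatenate([trab_hu, cort_hu])
    thr, _ = fit_hu_threshold(body, family=family, cdf_level=cdf_level)
    return CalibrationParams(
        hu_mode_trab=mode,
        hu_min_trab=float(trab_hu.min()),
        hu_threshold=thr,
        hu_min_cort=float(cort_hu.min()),
        distribution_family=family,
        cdf_level=cdf_level,
    )


def hu_to_porosity_trabecular(hu: np.ndarray | float, cal: CalibrationParams):
    """Linear trabecular HU→porosity law, clamped to [0, 1].

    Passes through (hu_mode_trab, phi_mode_trab) and (hu_min_trab,
    phi_max_trab); porosity decreases as HU increases.
    """
    hu = np.asarray(hu, float)
    phi = cal.phi_mode_trab + (hu - cal.hu_mode_trab) * (
        cal.phi_max_trab - cal.phi_mode_trab
    ) / (cal.hu_min_trab - cal.hu_mode_trab)
    clamped = np.clip(phi, 0.0, 1.0)
    frac = float(np.mean(clamped != phi))
    if frac > 0:
        log.info("trabecular porosity clamped on %.1f%% of voxels", 100 * frac)
    return clamped if clamped.ndim else float(clamped)


def hu_to_porosity_cortical(hu: np.ndarray | float, cal: CalibrationParams):
    """Linear cortical HU→porosity law, clamped to [0, phi_max_cort].

    Zero porosity at and above the dense-bone threshold; maximum cortical
    porosity at the lowest cortical HU.
    """
    hu = np.asarray(hu, float)
    phi = (cal.hu_threshold - hu) / (cal.hu_threshold - cal.hu_min_cort) * cal.phi_max_cort
    clamped = np.clip(phi, 0.0, cal.phi_max_cort)
    return clamped if clamped.ndim else float(clamped)


def porosity_field(
    vol: ImageVolume,
    trabecular: np.ndarray,
    cortical: np.ndarray,
    cal: CalibrationParams,
) -> PorosityField:
    """Apply the split laws per tissue label; outside voxels carry no porosity."""
    if trabecular.shape != vol.shape or cortical.shape != vol.shape:
        raise ValueError("label shapes must match the volume")
    overlap = trabecular & cortical
    if overlap.any():
        raise ValueError("trabecular and cortical labels overlap")
    tissue = np.full(vol.shape, OUTSIDE, dtype=np.uint8)
    tissue[trabecular] = TRABECULAR
    tissue[cortical] = CORTICAL
    poro = np.zeros(vol.shape, float)
    poro[trabecular] = hu_to_porosity_trabecular(vol.values[trabecular], cal)
    poro[cortical] = hu_to_porosity_cortical(vol.values[cortical], cal)
    return PorosityField(porosity=poro, tissue=tissue)
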