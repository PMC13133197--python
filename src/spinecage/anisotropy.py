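"""Gradient-structure-tensor (GST) fabric analysis.

For each voxel of a tissue label the GST is the boxcar-window average of the
outer product of the intensity gradient with itself, normalized by its trace.
Its eigenvalues (ascending, λ1 ≤ λ2 ≤ λ3) and eigenvectors encode local
texture orientation: intensity varies least along trabeculae, so the
minimum-gradient eigenvector e1 is taken as the stiffest material axis.

Degree of anisotropy DA = 1 − λ1/λ3 (0 isotropic, →1 strongly oriented) and
the Kelvin-cell aspect ratio R = λ3/λ1 ≥ 1 follow directly from the
eigenvalues.  Voxels whose analysis window contains more than a set fraction
of out-of-label voxels are flagged isotropic and carry no directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

R_MAX_DEFAULT = 10.0


@dataclass
class FabricField:
    """Per-voxel GST eigen-decomposition plus derived anisotropy measures.

    ``eigenvalues[..., i]`` ascending; ``eigenvectors[..., :, i]`` is the unit
    eigenvector e_{i+1} in world axes.  ``isotropic`` marks voxels without a
    reliable orientation (boundary windows or vanishing gradients); their DA
    is 0 and R is 1.
    """

    eigenvalues: np.ndarray  # (nx, ny, nz, 3)
    eigenvectors: np.ndarray  # (nx, ny, nz, 3, 3)
    isotropic: np.ndarray  # bool
    DA: np.ndarray
    R: np.ndarray
    label: np.ndarray  # bool: voxels the analysis covered


def pooled_fabric(fab: FabricField) -> dict:
    """Label-level fabric from the average of the per-voxel GSTs.

    Per-voxel eigenvalues from a 7x7x7 window carry a substantial upward DA
    sampling bias (few independent texture samples per window), so the
    region-level anisotropy is estimated from the tensor average over all
    unflagged voxels — an unbiased estimator of the expected GST.  Returns
    the pooled eigenvalues, eigenvectors (columns, ascending), DA and R.
    """
    act = fab.label & ~fab.isotropic
    if not act.any():
        return {
            "eigenvalues": np.array([1.0, 1.0, 1.0]) / 3,
            "eigenvectors": np.eye(3),
            "DA": 0.0,
            "R": 1.0,
            "n_voxels": 0,
        }
    evals = fab.eigenvalues[act]
    evecs = fab.eigenvectors[act]
    T = np.einsum("nik,nk,njk->ij", evecs, evals, evecs) / act.sum()
    w, v = np.linalg.eigh(T)
    w = np.clip(w, 0.0, None)
    da = float(morphologic_anisotropy(w[0], w[2]))
    return {
        "eigenvalues": w,
        "eigenvectors": v,
        "DA": da,
        "R": float(aspect_ratio(w[0], w[2])),
        "n_voxels": int(act.sum()),
    }


def boundary_flag(
    label: np.ndarray, window: int = 7, max_outside_fraction: float = 0.25
) -> np.ndarray:
    """Flag voxels whose window has more than ``max_outside_fraction`` outside.

    Windows are clipped at the volume border ('nearest' padding counts border
    voxels as themselves), so a voxel near the array edge is flagged only if
    the replicated window leaves the label.
    """
    outside = ndimage.uniform_filter(
        (~np.asarray(label, bool)).astype(float), size=window, mode="nearest"
    )
    return outside > max_outside_fraction + 1e-12


def morphologic_anisotropy(lam1, lam3):
    """DA = 1 − λ1/λ3 ∈ [0, 1]; undefined (returns 0) where λ3 = 0."""
    lam1 = np.asarray(lam1, float)
    lam3 = np.asarray(lam3, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        da = np.where(lam3 > 0, 1.0 - lam1 / np.where(lam3 > 0, lam3, 1.0), 0.0)
    return np.clip(da, 0.0, 1.0)


def aspect_ratio(lam1, lam3, r_max: float = R_MAX_DEFAULT):
    """Kelvin-cell aspect ratio R = λ3/λ1 ≥ 1, capped at ``r_max``.

    Interpreted as cell height over width, H/D = tan(θ); vertically elongated
    trabecular cells have R > 1.
    """
    lam1 = np.asarray(lam1, float)
    lam3 = np.asarray(lam3, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(lam1 > 0, lam3 / np.where(lam1 > 0, lam1, 1.0), np.inf)
    return np.clip(r, 1.0, r_max)


def gradient_structure_tensor(
    vol: ImageVolume,
    label: np.ndarray,
    window: int = 7,
    max_outside_fraction: float = 0.25,
    presmooth_sigma: float = 0.0,
    r_max: float = R_MAX_DEFAULT,
) -> FabricField:
    """Per-voxel normalized GST eigen-analysis restricted to one tissue label.

    Gradients use central differences on the (isotropic) grid, optionally
    after Gaussian pre-smoothing (``presmooth_sigma`` in voxels).  The window
    average runs over in-label voxels only, so neighbouring tissue does not
    leak into the tensor; voxels failing the outside-fraction rule are
    flagged isotropic, as are voxels with (numerically) zero tensor trace.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if any(window > s for s in vol.shape):
        raise ValueError("window larger than the volume")
    label = np.asarray(label, bool)
    if label.shape != vol.shape:
        raise ValueError("label shape must match volume")

    values = np.asarray(vol.values, float)
    if presmooth_sigma > 0:
        values = ndimage.gaussian_filter(values, presmooth_sigma, mode="nearest")
    grads = np.gradient(values, *vol.spacing, edge_order=1)

    mask = label.astype(float)
    wsum = ndimage.uniform_filter(mask, size=window, mode="nearest")
    comps = {}
    for a in range(3):
        for b in range(a, 3):
            num = ndimage.uniform_filter(
                grads[a] * grads[b] * mask, size=window, mode="nearest"
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                comps[(a, b)] = np.where(wsum > 0, num / np.maximum(wsum, 1e-300), 0.0)

    gst = np.zeros(vol.shape + (3, 3))
    for (a, b), v in comps.items():
        gst[..., a, b] = v
        gst[..., b, a] = v

    trace = gst[..., 0, 0] + gst[..., 1, 1] + gst[..., 2, 2]
    flagged = boundary_flag(label, window, max_outside_fraction)
    scale = np.abs(values[label]).max() if label.any() else 1.0
    tiny = (1e-12 * max(scale, 1.0) / max(min(vol.spacing), 1e-12)) ** 2
    degenerate = trace <= tiny
    isotropic = flagged | degenerate

    active = label & ~isotropic
    eigenvalues = np.zeros(vol.shape + (3,))
    eigenvectors = np.zeros(vol.shape + (3, 3))
    eigenvectors[..., :, :] = np.eye(3)
    if active.any():
        t = gst[active] / trace[active][:, None, None]
        w, v = np.linalg.eigh(t)  # ascending
        # deterministic sign: largest-|component| entry of each vector positive
        idx = np.argmax(np.abs(v), axis=1)
        signs = np.sign(
            np.take_along_axis(v, idx[:, None, :], axis=1).squeeze(1)
        )
        signs[signs == 0] = 1.0
        v = v * signs[:, None, :]
        eigenvalues[active] = np.clip(w, 0.0, None)
        eigenvectors[active] = v

    lam1 = eigenvalues[..., 0]
    lam3 = eigenvalues[..., 2]
    DA = np.where(active, morphologic_anisotropy(lam1, lam3), 0.0)
    R = np.where(active, aspect_ratio(lam1, lam3, r_max=r_max), 1.0)
    return FabricField(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        isotropic=isotropic & label,
        DA=DA,
        R=R,
        label=label,
    )
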