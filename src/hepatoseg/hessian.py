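"""Multi-scale Hessian eigenvalue analysis: vesselness and blobness maps.

Second derivatives are taken with Gaussian-derivative kernels at a set of
physical scales sigma (mm) and gamma-normalized by sigma^2 so responses are
comparable across scales; eigenvalues are sorted descending
(lambda1 >= lambda2 >= lambda3) at every voxel.

Two detectors are derived from the eigenvalues:

* vesselness — bright tubular structures (contrast-enhanced vessels): both
  smaller eigenvalues strongly negative, largest near zero;
* blobness — dark isotropic structures (hypodense tumors): all eigenvalues
  positive, response maximal at isotropy (lambda1 = lambda3).

Both responses are maximized over scales, and an energy map -ln(response)
(after min-max rescaling into (eps, 1]) is provided for use as a graph-cut
unary term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import Volume


@dataclass
class HessianEigenField:
    """Per-voxel, per-scale sorted Hessian eigenvalues.

    ``eigenvalues[s]`` has shape ``grid + (3,)`` with descending order
    lambda1 >= lambda2 >= lambda3 along the last axis.
    """

    eigenvalues: list[np.ndarray]
    scales: list[float]          # mm
    spacing: tuple[float, float, float]


@dataclass
class EnhancementMap:
    response: np.ndarray         # scale-maximized detector response
    best_scale: np.ndarray       # scale (mm) attaining the max, per voxel
    energy: np.ndarray           # -ln of min-max-rescaled response
    scales: list[float]
    kind: str = "vessel"

    ENERGY_EPS = 1e-6

    @staticmethod
    def energy_from_response(response: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        """-ln of the response after min-max rescaling into (eps, 1].

        Keeps energies finite where the raw detector is exactly zero.
        """
        r = np.asarray(response, dtype=np.float64)
        lo, hi = float(r.min()), float(r.max())
        if hi > lo:
            scaled = eps + (1.0 - eps) * (r - lo) / (hi - lo)
        else:
            scaled = np.full_like(r, eps)
        return -np.log(scaled)


#: a gamma=2-normalized tube response of radius R peaks at sigma = R/sqrt(2),
#: so scales are expressed as structure radii (mm) and mapped to Gaussian
#: sigma by this factor — the reported best scale then matches the radius.
SIGMA_PER_SCALE = 1.0 / np.sqrt(2.0)


def hessian_eigen(volume: Volume, scales,
                  sigma_per_scale: float = SIGMA_PER_SCALE) -> HessianEigenField:
    """Gamma-normalized Gaussian Hessian eigenvalues at each scale.

    Scales are physical structure radii (mm) and must not be below the
    smallest voxel spacing, otherwise the derivative kernel is unresolvable.
    The Gaussian aperture actually applied is ``sigma_per_scale * scale``.
    """
    scales = [float(s) for s in np.atleast_1d(scales)]
    if not scales:
        raise ValueError("need at least one scale")
    sp = np.asarray(volume.spacing, dtype=float)
    for s in scales:
        if s < sp.min():
            raise ValueError(f"scale {s} mm below voxel spacing {sp.min()} mm")
    # centring removes the small DC leakage of truncated derivative kernels
    # and makes the responses exactly invariant to additive offsets
    data = volume.data - volume.data.mean()
    fields = []
    for scale_mm in scales:
        sigma_mm = sigma_per_scale * scale_mm
        sig_vox = sigma_mm / sp
        H = np.empty(data.shape + (3, 3), dtype=np.float64)
        for i in range(3):
            for j in range(i, 3):
                order = [0, 0, 0]
                order[i] += 1
                order[j] += 1
                d2 = ndi.gaussian_filter(data, sig_vox, order=order, mode="nearest")
                # derivative is per voxel-index; convert to per-mm
                d2 = d2 / (sp[i] * sp[j])
                H[..., i, j] = d2
                H[..., j, i] = d2
        H *= sigma_mm**2  # gamma-normalization (gamma = 2) at the applied sigma
        w = np.linalg.eigvalsh(H)          # ascending
        fields.append(w[..., ::-1].copy()) # descending: l1 >= l2 >= l3
    return HessianEigenField(fields, scales, volume.spacing)


def _vessel_response(eig: np.ndarray, alpha: float) -> np.ndarray:
    """Bright-tube response from sorted eigenvalues (descending)."""
    l1 = eig[..., 0]
    l2 = eig[..., 1]
    v = np.abs(l2) * np.exp(-(l1**2) / (2.0 * (alpha * np.abs(l2)) ** 2 + 1e-300))
    v = np.where(l2 < 0, v, 0.0)
    return v


def _blob_response(eig: np.ndarray) -> np.ndarray:
    """Dark-blob response: all eigenvalues positive, maximal at isotropy."""
    l1 = eig[..., 0]
    l3 = eig[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(l3 > 0, l1 / l3, 2.0)   # ratio >= 1 where valid
    return np.where(l3 > 0, np.exp(1.0 - ratio), 0.0)


def _scale_max(per_scale: list[np.ndarray], scales: list[float]):
    stack = np.stack(per_scale, axis=0)
    idx = np.argmax(stack, axis=0)
    response = np.take_along_axis(stack, idx[None], axis=0)[0]
    best = np.asarray(scales, dtype=float)[idx]
    return response, best


def vesselness(field: HessianEigenField, alpha: float = 0.5) -> EnhancementMap:
    """Scale-maximized bright-tube response and its -ln energy.

    For lambda2 < 0 the response is |lambda2| * exp(-lambda1^2 /
    (2 (alpha |lambda2|)^2)); zero otherwise.  ``alpha`` controls how sharply
    a non-zero largest eigenvalue (plate/blob deviation) is penalized.
    """
    per_scale = [_vessel_response(e, alpha) for e in field.eigenvalues]
    response, best = _scale_max(per_scale, field.scales)
    energy = EnhancementMap.energy_from_response(response)
    return EnhancementMap(response, best, energy, field.scales, kind="vessel")


def blobness(field: HessianEigenField) -> EnhancementMap:
    """Scale-maximized dark-blob response and its -ln energy.

    w = exp(1 - lambda1/lambda3) where lambda3 > 0 (all eigenvalues
    positive), zero otherwise; w lies in (0, 1] and peaks when the local
    curvature is isotropic, i.e. at the center of a hypodense sphere.
    """
    per_scale = [_blob_response(e) for e in field.eigenvalues]
    response, best = _scale_max(per_scale, field.scales)
    energy = EnhancementMap.energy_from_response(response)
    return EnhancementMap(response, best, energy, field.scales, kind="blob")


DEFAULT_SCALES_MM = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]


def enhance(volume: Volume, scales=None, alpha: float = 0.5):
    """Convenience: compute both vesselness and blobness maps."""
    field = hessian_eigen(volume, scales or DEFAULT_SCALES_MM)
    return vesselness(field, alpha=alpha), blobness(field)
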