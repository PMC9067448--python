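"""Multiscale Jerman vessel enhancement from Hessian eigenvalues.

Tubular bright structures (arteries in time-of-flight MRA) produce a
characteristic Hessian eigenvalue signature: one small eigenvalue along the
vessel axis and two large negative ones across it.  The Jerman enhancement
turns that signature into a response in [0, 1] that is close to 1 across the
whole vessel lumen, using a regularized largest eigenvalue

    lambda_rho = lambda3                     if lambda3 >  tau * max lambda3
               = tau * max lambda3           if 0 < lambda3 <= tau * max lambda3
               = 0                           otherwise

and the ratio-based response

    V = 0                                        if lambda2 <= 0 or lambda_rho <= 0
    V = 1                                        if lambda2 >= lambda_rho / 2 > 0
    V = lambda2^2 (lambda_rho - lambda2) * (3 / (lambda2 + lambda_rho))^3   otherwise.

Eigenvalues here follow the bright-structure sign convention: for the default
``polarity='bright'`` the Hessian eigenvalues are sign-flipped before
evaluation, so vessel cross-sections give lambda2, lambda3 > 0.

The multiscale response is the pointwise maximum over a set of Gaussian
scales, with gamma = 2 scale normalization (multiplication by s^2) so
responses are comparable across scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume

#: Default analysis scales (mm), spanning facial-artery radii of ~0.5-1.5 mm.
DEFAULT_SCALES_MM = (0.5, 0.75, 1.0, 1.5, 2.0)

#: Default cutoff fraction tau for the regularized eigenvalue.
DEFAULT_TAU = 0.5

_TRUNCATE = 4.0  # Gaussian kernel truncation, in standard deviations


def _gaussian_derivative_kernel(
    sigma: float, order: int, truncate: float = _TRUNCATE
) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with zero DC response.

    The order-0 kernel is the unit-sum sampled Gaussian; derivative kernels
    are analytic derivatives of it.  Truncation leaves the second-derivative
    kernel with a small nonzero sum, which would make the Hessian of a
    constant image nonzero; subtracting the mean restores an exactly zero
    response to constants (and hence exact intensity-shift invariance).
    """
    lw = int(truncate * sigma + 0.5)
    x = np.arange(-lw, lw + 1, dtype=float)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -x / sigma**2 * phi  # antisymmetric: sums to zero exactly
        return k / -(x * k).sum()  # unit response to a ramp
    k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
    k = k - k.mean()
    return k / ((x**2 * k).sum() / 2.0)  # exact response 2 to x^2


@dataclass
class EigenvalueField:
    """Per-voxel Hessian eigenvalues at one Gaussian scale.

    Eigenvalues are sorted by magnitude: ``|lam1| <= |lam2| <= |lam3|`` at
    every voxel.  ``scale`` is the physical Gaussian standard deviation in mm.
    """

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    scale: float


@dataclass
class VesselnessMap:
    """Multiscale vesselness response in [0, 1] on a volume's grid."""

    response: np.ndarray
    scales_used: tuple[float, ...]
    tau: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def as_volume(self) -> ImageVolume:
        return ImageVolume(
            data=self.response, spacing=self.spacing, origin=self.origin
        )


def hessian_eigenvalues(volume: ImageVolume, scale_mm: float) -> EigenvalueField:
    """Scale-normalized Hessian eigenvalues of a volume at one scale.

    The Hessian is built from Gaussian second derivatives with a *physical*
    standard deviation of ``scale_mm`` on every axis: anisotropic voxel
    spacing is honoured by converting to per-axis voxel sigmas and dividing
    the derivative filters by the voxel size.  Each component is multiplied
    by ``scale_mm**2`` (gamma = 2 normalization).  Boundaries use reflect
    padding to avoid spurious edge responses.

    Parameters
    ----------
    volume : ImageVolume
    scale_mm : float
        Gaussian sigma in mm; must be positive and at least half the largest
        voxel spacing so the kernel is resolvable on the grid.
    """
    if scale_mm <= 0:
        raise ValueError(f"scale must be positive, got {scale_mm}")
    if scale_mm < max(volume.spacing) / 2:
        raise ValueError(
            f"scale {scale_mm} mm is below half the coarsest voxel spacing "
            f"{max(volume.spacing)} mm; the kernel cannot be resolved"
        )
    data = np.asarray(volume.data, dtype=float)
    sp = np.asarray(volume.spacing)
    sigmas_vox = scale_mm / sp

    H = np.empty(data.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = data
            for ax in range(3):
                d = ndimage.convolve1d(
                    d,
                    _gaussian_derivative_kernel(sigmas_vox[ax], order[ax]),
                    axis=ax,
                    mode="reflect",
                )
            # gaussian_filter differentiates w.r.t. voxel index; convert to mm
            d /= sp[i] * sp[j]
            H[..., i, j] = H[..., j, i] = d
    H *= scale_mm**2

    # kill pure floating-point noise so exactly-homogeneous regions give
    # exactly-zero eigenvalues (a constant volume must map to zero response)
    intensity_range = float(data.max() - data.min())
    if intensity_range == 0.0:
        H[:] = 0.0  # constant volume: all derivatives vanish identically
    else:
        floor = 1e-10 * intensity_range * scale_mm**2 / min(volume.spacing) ** 2
        H[np.abs(H) < floor] = 0.0

    lams = np.linalg.eigvalsh(H.reshape(-1, 3, 3))
    order = np.argsort(np.abs(lams), axis=1)
    lams = np.take_along_axis(lams, order, axis=1).reshape(data.shape + (3,))
    return EigenvalueField(
        lam1=lams[..., 0], lam2=lams[..., 1], lam3=lams[..., 2], scale=scale_mm
    )


def jerman_response(
    eigs: EigenvalueField, tau: float = DEFAULT_TAU, polarity: str = "bright"
) -> np.ndarray:
    """Single-scale Jerman response in [0, 1].

    ``polarity='bright'`` (default, TOF-MRA arteries) flips the eigenvalue
    signs before evaluation so bright tubes give positive lambda2, lambda3;
    ``'dark'`` evaluates them as-is.  ``tau`` in (0, 1] sets the cutoff
    fraction of the per-scale global maximum of lambda3 below which the
    regularized eigenvalue lambda_rho is clamped.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    sign = -1.0 if polarity == "bright" else 1.0
    lam2 = sign * eigs.lam2
    lam3 = sign * eigs.lam3
    return _jerman_formula(lam2, lam3, tau)


def _jerman_formula(lam2: np.ndarray, lam3: np.ndarray, tau: float) -> np.ndarray:
    """Evaluate the response from (already polarity-adjusted) lam2, lam3."""
    lam2 = np.asarray(lam2, dtype=float)
    lam3 = np.asarray(lam3, dtype=float)
    lam3_max = lam3.max() if lam3.size else 0.0
    cutoff = tau * lam3_max
    lam_rho = np.where(lam3 > cutoff, lam3, np.where(lam3 > 0, cutoff, 0.0))

    # core is evaluated everywhere and masked afterwards; the discarded
    # branches may divide by zero or overflow harmlessly
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        core = lam2**2 * (lam_rho - lam2) * (3.0 / (lam2 + lam_rho)) ** 3
    v = np.where(
        (lam2 <= 0) | (lam_rho <= 0),
        0.0,
        np.where(lam2 >= lam_rho / 2.0, 1.0, core),
    )
    return np.clip(v, 0.0, 1.0)


def multiscale_vesselness(
    volume: ImageVolume,
    scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM,
    tau: float = DEFAULT_TAU,
    polarity: str = "bright",
) -> VesselnessMap:
    """Pointwise maximum of the Jerman response over a set of scales.

    The regularizing global maximum of lambda3 is recomputed per scale over
    the whole volume, as the single-scale response does.
    """
    scales = tuple(float(s) for s in scales_mm)
    if not scales:
        raise ValueError("scale list must be non-empty")
    response = None
    for s in scales:
        eigs = hessian_eigenvalues(volume, s)
        v = jerman_response(eigs, tau=tau, polarity=polarity)
        response = v if response is None else np.maximum(response, v)
    return VesselnessMap(
        response=response,
        scales_used=scales,
        tau=tau,
        spacing=volume.spacing,
        origin=volume.origin,
    )
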