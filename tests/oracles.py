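"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths: explicit kernel
construction and direct convolution sums instead of separable ndimage
filters, per-voxel loops instead of vectorized algebra, scalar formula
evaluation instead of array branching.
"""

from __future__ import annotations

import numpy as np


def gaussian_kernel_1d(sigma: float, order: int, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian (or its exact derivative) on integer offsets.

    The order-0 kernel is normalized to unit sum; derivative kernels are the
    analytic derivatives of that normalized kernel, matching the standard
    discrete Gaussian-derivative convention.
    """
    lw = int(truncate * sigma + 0.5)
    x = np.arange(-lw, lw + 1, dtype=float)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -x / sigma**2 * phi
        return k / -(x * k).sum()
    if order == 2:
        # mean-subtracted (zero response to constants) and moment-normalized
        # (response exactly 2 to x^2), the same discrete-derivative
        # convention the library documents
        k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
        k = k - k.mean()
        return k / ((x**2 * k).sum() / 2.0)
    raise ValueError(order)


def reflect_pad_index(i: int, n: int) -> int:
    """Index into an array of length n under scipy's 'reflect' extension."""
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def convolve_axis(data: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Direct 1-D convolution along an axis with reflect boundary."""
    data = np.moveaxis(data, axis, 0)
    n = data.shape[0]
    lw = (len(kernel) - 1) // 2
    out = np.zeros_like(data, dtype=float)
    for i in range(n):
        acc = np.zeros(data.shape[1:], dtype=float)
        for j, w in enumerate(kernel):
            off = j - lw  # kernel offset
            src = reflect_pad_index(i - off, n)
            acc += w * data[src]
        out[i] = acc
    return np.moveaxis(out, 0, axis)


def dense_hessian_eigs(
    data: np.ndarray, spacing: tuple[float, float, float], scale_mm: float
) -> np.ndarray:
    """(nx, ny, nz, 3) magnitude-sorted eigenvalues by explicit convolution
    and a per-voxel dense eigensolver."""
    data = np.asarray(data, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    H = np.zeros(data.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            orders = [0, 0, 0]
            orders[i] += 1
            orders[j] += 1
            d = data.copy()
            for ax in range(3):
                d = convolve_axis(
                    d, gaussian_kernel_1d(scale_mm / sp[ax], orders[ax]), ax
                )
            d = d / (sp[i] * sp[j]) * scale_mm**2
            H[..., i, j] = H[..., j, i] = d
    out = np.zeros(data.shape + (3,))
    for idx in np.ndindex(data.shape):
        lams = np.linalg.eigvalsh(H[idx])
        out[idx] = lams[np.argsort(np.abs(lams))]
    return out


def jerman_scalar(lam2: float, lam3: float, lam3_max: float, tau: float) -> float:
    """Scalar Jerman response for one voxel (bright-adjusted eigenvalues)."""
    cutoff = tau * lam3_max
    if lam3 > cutoff:
        lam_rho = lam3
    elif lam3 > 0:
        lam_rho = cutoff
    else:
        lam_rho = 0.0
    if lam2 <= 0 or lam_rho <= 0:
        return 0.0
    if lam2 >= lam_rho / 2.0:
        return 1.0
    return lam2**2 * (lam_rho - lam2) * (3.0 / (lam2 + lam_rho)) ** 3


def dense_multiscale_vesselness(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    scales_mm,
    tau: float,
) -> np.ndarray:
    """Full bright-vessel multiscale response via the dense route."""
    best = np.zeros(np.asarray(data).shape)
    for s in scales_mm:
        eigs = dense_hessian_eigs(data, spacing, s)
        lam2 = -eigs[..., 1]
        lam3 = -eigs[..., 2]
        lam3_max = lam3.max()
        v = np.zeros_like(best)
        for idx in np.ndindex(v.shape):
            v[idx] = jerman_scalar(lam2[idx], lam3[idx], lam3_max, tau)
        best = np.maximum(best, v)
    return best


def point_in_region_fraction(points: np.ndarray, centroid, radius: float) -> float:
    """Loop-based fraction of points inside a sphere."""
    inside = 0
    for p in points:
        if np.sqrt(((np.asarray(p) - np.asarray(centroid)) ** 2).sum()) <= radius:
            inside += 1
    return inside / len(points)
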