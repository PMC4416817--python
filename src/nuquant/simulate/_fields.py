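"""Shared rendering helpers: grids, random fields, optics."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def grid_for_ellipsoid(
    semi_axes_um: Tuple[float, float, float],
    margin_um: float,
    voxel_dims_nm: Tuple[float, float, float],
) -> Tuple[Tuple[int, int, int], Tuple[float, float, float]]:
    """Grid shape and physical centre (um) containing ellipsoid + margin."""
    dims_um = tuple(d / 1000.0 for d in voxel_dims_nm)
    shape = tuple(
        int(np.ceil(2.0 * (a + margin_um) / d)) for a, d in zip(semi_axes_um, dims_um)
    )
    center = tuple((n - 1) * d / 2.0 for n, d in zip(shape, dims_um))
    return shape, center


def coordinate_axes(
    shape: Tuple[int, int, int],
    center_um: Tuple[float, float, float],
    voxel_dims_nm: Tuple[float, float, float],
):
    """Open-grid physical coordinates (um) relative to the centre."""
    dims_um = [d / 1000.0 for d in voxel_dims_nm]
    z = (np.arange(shape[0]) * dims_um[0] - center_um[0])[:, None, None]
    y = (np.arange(shape[1]) * dims_um[1] - center_um[1])[None, :, None]
    x = (np.arange(shape[2]) * dims_um[2] - center_um[2])[None, None, :]
    return z, y, x


def gaussian_random_field(
    shape: Tuple[int, int, int],
    sigma_nm: float,
    voxel_dims_nm: Tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance smoothed white noise with physical correlation length."""
    sig_vox = tuple(sigma_nm / d for d in voxel_dims_nm)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sig_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def ellipsoid_surface_area_um2(semi_axes_um: Tuple[float, float, float]) -> float:
    """Thomsen's approximation (exact for spheres, <1.1% error otherwise)."""
    c, b, a = sorted(semi_axes_um)
    p = 1.6075
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * np.pi * s ** (1.0 / p)


def sample_directions(
    rng: np.random.Generator, n: int, cos_min: float = -1.0, cos_max: float = 1.0
) -> np.ndarray:
    """Unit vectors (z, y, x) with direction cosine d_z ~ U(cos_min, cos_max).

    With the full range this is the uniform law on the sphere; restricting
    the range samples a polar cap (or band) of the matching area fraction.
    """
    cz = rng.uniform(cos_min, cos_max, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(np.clip(1.0 - cz * cz, 0.0, None))
    return np.stack([cz, s * np.sin(phi), s * np.cos(phi)], axis=1)


def surface_point(direction: np.ndarray, semi_axes_um) -> np.ndarray:
    """Ellipsoid surface point(s) along given direction(s) from the centre."""
    d = np.atleast_2d(direction)
    a = np.asarray(semi_axes_um)
    t = 1.0 / np.sqrt(np.sum((d / a) ** 2, axis=1))
    return t[:, None] * d


def paint_ball(
    img: np.ndarray,
    center_um: np.ndarray,
    radius_um: float,
    amplitude: float,
    origin_um: Tuple[float, float, float],
    voxel_dims_nm: Tuple[float, float, float],
) -> None:
    """Add a solid ball of intensity into ``img`` (physical units)."""
    dims = np.array(voxel_dims_nm) / 1000.0
    c = np.asarray(center_um) + np.asarray(origin_um)
    lo = np.maximum(np.floor((c - radius_um) / dims).astype(int), 0)
    hi = np.minimum(np.ceil((c + radius_um) / dims).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * dims[0] - c[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * dims[1] - c[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * dims[2] - c[2])[None, None, :]
    ball = zz ** 2 + yy ** 2 + xx ** 2 <= radius_um ** 2
    img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][ball] += amplitude


def paint_tube(
    img: np.ndarray,
    p0_um: np.ndarray,
    p1_um: np.ndarray,
    radius_um: float,
    amplitude: float,
    origin_um: Tuple[float, float, float],
    voxel_dims_nm: Tuple[float, float, float],
) -> None:
    """Add a capsule (cylinder with hemispherical caps) between two points."""
    dims = np.array(voxel_dims_nm) / 1000.0
    a = np.asarray(p0_um) + np.asarray(origin_um)
    b = np.asarray(p1_um) + np.asarray(origin_um)
    lo = np.maximum(np.floor((np.minimum(a, b) - radius_um) / dims).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(a, b) + radius_um) / dims).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * dims[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * dims[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * dims[2])[None, None, :]
    ab = b - a
    denom = float(np.dot(ab, ab))
    pz, py, px = zz - a[0], yy - a[1], xx - a[2]
    if denom == 0:
        d2 = pz ** 2 + py ** 2 + px ** 2
    else:
        t = np.clip((pz * ab[0] + py * ab[1] + px * ab[2]) / denom, 0.0, 1.0)
        d2 = (pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2
    tube = d2 <= radius_um ** 2
    img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][tube] += amplitude


def apply_optics(
    channels: Dict[str, np.ndarray],
    psf_fwhm_nm: Optional[Tuple[float, float]],
    noise: Optional[Tuple[float, float]],
    voxel_dims_nm: Tuple[float, float, float],
    rng_noise: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Blur with the anisotropic Gaussian PSF, then Poisson + read noise.

    Channels are processed in sorted-name order so the noise stream is
    reproducible regardless of dict insertion order.
    """
    out = {}
    for name in sorted(channels):
        img = channels[name].astype(np.float64)
        if psf_fwhm_nm is not None:
            lat, ax = psf_fwhm_nm
            sig = (
                ax * _FWHM_TO_SIGMA / voxel_dims_nm[0],
                lat * _FWHM_TO_SIGMA / voxel_dims_nm[1],
                lat * _FWHM_TO_SIGMA / voxel_dims_nm[2],
            )
            img = ndimage.gaussian_filter(img, sigma=sig)
        if noise is not None:
            scale, sd = noise
            if scale > 0:
                img = rng_noise.poisson(np.clip(img, 0, None) * scale) / scale
            if sd > 0:
                img = img + rng_noise.normal(0.0, sd, size=img.shape)
            img = np.clip(img, 0.0, None)
        out[name] = img.astype(np.float32)
    return out
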