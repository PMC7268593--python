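"""Brute-force direct-space quadrature of the first Born integral.

Independent numeric route for validating (and calibrating against) the
FFT-based Rytov/Born forward model in :mod:`spherepipe.models`.  The
scattered field of a plane wave ``u_0 = exp(i k_med z)`` hitting a
homogeneous sphere is integrated voxel by voxel with the free-space
Green's function::

    u_B(r) = integral  e^{i k |r - r'|} / (4 pi |r - r'|)
             * k_med^2 chi(r') * e^{i k_med z'}  dV'

with ``chi = (n / n_med)^2 - 1`` inside the sphere and 0 outside.  Rim
voxels carry fractional occupancy weights (subsampled), which keeps the
quadrature error of the peak-normalised field well below 1% at 64 voxels
per axis.

The detector plane must lie *outside* the sphere (``z_plane > r``), where
the integrand is regular.  For a centered sphere the lateral field is
axially symmetric, so :func:`born_field_direct_radial` integrates along a
single radial line; :func:`born_reference_qpi` interpolates the profile
onto a 2-D grid and back-propagates it to the in-focus plane with the
exact angular-spectrum factor, yielding reference phase images for the
rytov-sc calibration harness.
"""

from __future__ import annotations

import numpy as np

from .holo import QPImage
from .models import Grid, SphereParams

__all__ = ["sphere_voxels", "born_field_direct_radial", "born_reference_qpi"]


def sphere_voxels(r: float, n_voxels: int = 64, supersample: int = 3,
                  extent: float | None = None):
    """Voxelise a sphere of radius ``r`` centered in a cube.

    Returns ``(xv, yv, zv, w, h)``: flattened voxel-center coordinates [m]
    of all voxels with non-zero occupancy, their fractional occupancy
    weights (``supersample**3`` subsamples per voxel) and the voxel pitch
    ``h``.  ``extent`` is the cube edge length (default ``2 r``).
    """
    if extent is None:
        extent = 2.0 * r
    h = extent / n_voxels
    c = (np.arange(n_voxels) + 0.5) * h - extent / 2
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")

    s = supersample
    off = ((np.arange(s) + 0.5) / s - 0.5) * h
    w = np.zeros(X.shape)
    for ox in off:
        for oy in off:
            for oz in off:
                w += ((X + ox) ** 2 + (Y + oy) ** 2 + (Z + oz) ** 2
                      <= r ** 2)
    w /= s ** 3
    keep = w > 0
    return X[keep], Y[keep], Z[keep], w[keep], h


def born_field_direct_radial(p: SphereParams, g: Grid, z_plane: float,
                             radii: np.ndarray, n_voxels: int = 64,
                             supersample: int = 3,
                             chunk: int = 128) -> np.ndarray:
    """Scattered Born field at lateral distances ``radii`` [m] from the
    sphere axis, on the plane ``z_plane`` [m] beyond the sphere centre.

    Direct summation over the voxelised sphere; no Fourier transforms are
    involved, which makes this an independent oracle for the FFT route.
    """
    if z_plane <= p.r:
        raise ValueError("detector plane must lie outside the sphere "
                         "(z_plane > r)")
    km = g.k_med
    chi = (p.n / g.medium_index) ** 2 - 1.0
    xv, yv, zv, w, h = sphere_voxels(p.r, n_voxels, supersample)
    src = (w * h ** 3 * km ** 2 * chi / (4 * np.pi)) * np.exp(1j * km * zv)

    radii = np.asarray(radii, dtype=float)
    out = np.empty(radii.shape, dtype=complex)
    for i0 in range(0, radii.size, chunk):
        rho = radii[i0:i0 + chunk, None]
        R = np.sqrt((rho - xv[None, :]) ** 2 + yv[None, :] ** 2
                    + (z_plane - zv[None, :]) ** 2)
        out[i0:i0 + chunk] = np.sum(np.exp(1j * km * R) / R * src[None, :],
                                    axis=1)
    return out


def _backpropagate(field: np.ndarray, g: Grid, dz: float,
                   pad_factor: int = 2) -> np.ndarray:
    """Exact angular-spectrum propagation of a sampled 2-D field by
    ``dz`` (negative: towards the source); evanescent components dropped."""
    H, W = field.shape
    Hp, Wp = pad_factor * H, pad_factor * W
    padded = np.zeros((Hp, Wp), dtype=complex)
    oy, ox = (Hp - H) // 2, (Wp - W) // 2
    padded[oy:oy + H, ox:ox + W] = field
    kx = 2 * np.pi * np.fft.fftfreq(Wp, d=g.pixel_size)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(Hp, d=g.pixel_size)[:, None]
    km = g.k_med
    k_perp2 = kx ** 2 + ky ** 2
    prop = k_perp2 < km ** 2
    kz = np.sqrt(np.where(prop, km ** 2 - k_perp2, 0.0))
    kernel = np.where(prop, np.exp(1j * kz * dz), 0.0)
    out = np.fft.ifft2(np.fft.fft2(padded) * kernel)
    return out[oy:oy + H, ox:ox + W]


def born_reference_qpi(p: SphereParams, g: Grid, n_voxels: int = 64,
                       supersample: int = 3, z_margin: float = 3e-6,
                       n_radii: int = 400) -> QPImage:
    """In-focus Rytov reference image from the direct-space Born route.

    The Born field is integrated on an exterior plane ``z = r + z_margin``
    along a radial line (exact for the axially symmetric geometry),
    interpolated onto the 2-D grid, back-propagated to the sphere-centre
    plane, and converted to the Rytov exponent ``psi = u_B``:
    ``phase = Im(psi)``, ``amplitude = exp(Re(psi))``.
    """
    H, W = g.shape
    z_d = p.r + z_margin
    # radii out to the grid corner, slightly padded for interpolation
    r_max = np.hypot(max(p.cy, H - 1 - p.cy) + 1,
                     max(p.cx, W - 1 - p.cx) + 1) * g.pixel_size
    radii = np.linspace(0.0, r_max, n_radii)
    prof = born_field_direct_radial(p, g, z_d, radii, n_voxels, supersample)

    rho = g.radius_map(p.cx, p.cy)
    u_exterior = (np.interp(rho.ravel(), radii, prof.real)
                  + 1j * np.interp(rho.ravel(), radii, prof.imag)
                  ).reshape(rho.shape)
    # back-propagate the scattered spectrum to the centre plane, where
    # u_0 = 1 and the Rytov exponent is the scattered field itself
    psi = _backpropagate(u_exterior, g, -z_d)
    phase = psi.imag + p.phase_offset
    amplitude = np.exp(psi.real)
    return QPImage(phase=phase, amplitude=amplitude,
                   wavelength=g.wavelength, pixel_size=g.pixel_size,
                   medium_index=g.medium_index,
                   identifier="born-direct-reference")
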