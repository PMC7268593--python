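"""Calibration harness for the rytov-sc correction coefficients.

The "systematically corrected Rytov" model applies an affine mapping to
the refractive-index contrast ``x = n / n_med - 1`` and radius of a
Rytov-model fit.  The published coefficient values belong to an external
reference implementation and are not reproduced here; instead this
harness determines default coefficients from first principles within the
repository:

1. reference phase images are generated by the brute-force direct-space
   Born integration (:mod:`spherepipe.born_direct`) — an independent
   numeric route that shares no Fourier forward-model code with the
   fitter — over a grid of true contrasts and radii;
2. the FFT-route Rytov model is fitted to each reference image;
3. ``x_true`` is regressed on ``x_fit`` and ``r_true / r_fit`` on
   ``x_fit`` (ordinary least squares), giving the four affine
   coefficients.

Because the reference route implements the same first-order scattering
physics, the resulting defaults are near-identity: they compensate the
numeric bias of the fitting pipeline (discretisation, rim handling,
padding), not the Rytov-vs-exact-scattering physics bias, which would
require an exact Mie reference (out of scope; coefficients from such a
reference can be supplied via ``[sphere] rytov_sc_coeffs``).  The frozen
defaults live in :mod:`spherepipe._constants`.
"""

from __future__ import annotations

import numpy as np

from .born_direct import born_reference_qpi
from .fit import SphereModel
from .models import Grid, RytovSCCoeffs, SphereParams

__all__ = ["calibrate_rytov_sc"]


def calibrate_rytov_sc(x_grid=(0.005, 0.02, 0.035, 0.05),
                       r_grid=(2e-6, 4.5e-6, 7e-6),
                       wavelength: float = 550e-9,
                       medium_index: float = 1.335,
                       pixels_per_radius: float = 12.0,
                       n_voxels: int = 64,
                       verbose: bool = False):
    """Regress the affine rytov-sc coefficients on a (contrast, radius)
    calibration grid.

    Returns ``(RytovSCCoeffs, records)`` where ``records`` is a list of
    dicts with the true and fitted parameters per grid point.
    """
    records = []
    for r_true in r_grid:
        px = r_true / pixels_per_radius
        half = int(np.ceil(2.2 * r_true / px))
        shape = (2 * half, 2 * half)
        g = Grid(shape=shape, pixel_size=px, wavelength=wavelength,
                 medium_index=medium_index)
        cx = cy = half - 0.5
        for x_true in x_grid:
            n_true = medium_index * (1.0 + x_true)
            p = SphereParams(n=n_true, r=r_true, cx=cx, cy=cy)
            ref = born_reference_qpi(p, g, n_voxels=n_voxels)
            init = SphereParams(n=n_true, r=r_true, cx=cx, cy=cy)
            res = SphereModel(ref, model="rytov", init=init).fit()
            records.append({
                "x_true": x_true, "r_true": r_true,
                "x_fit": res.params.n / medium_index - 1.0,
                "r_fit": res.params.r,
                "converged": res.converged,
            })
            if verbose:
                rec = records[-1]
                print(f"x={x_true:.3f} r={r_true * 1e6:.1f}um -> "
                      f"x_fit={rec['x_fit']:.5f} "
                      f"r_fit={rec['r_fit'] * 1e6:.4f}um")

    ok = [rec for rec in records if rec["converged"]]
    if len(ok) < 2:
        raise RuntimeError("calibration failed: too few converged fits")
    x_fit = np.array([rec["x_fit"] for rec in ok])
    x_true = np.array([rec["x_true"] for rec in ok])
    r_ratio = np.array([rec["r_true"] / rec["r_fit"] for rec in ok])
    A = np.column_stack([np.ones_like(x_fit), x_fit])
    (c_n0, c_n1), *_ = np.linalg.lstsq(A, x_true, rcond=None)
    (c_r0, c_r1), *_ = np.linalg.lstsq(A, r_ratio, rcond=None)
    coeffs = RytovSCCoeffs(c_n0=float(c_n0), c_n1=float(c_n1),
                           c_r0=float(c_r0), c_r1=float(c_r1))
    return coeffs, records
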