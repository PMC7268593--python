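"""Sphere-model fits to phase images, dry mass, and result tables.

The central objects follow the model/results pattern:
:class:`SphereModel` is built from a background-corrected phase image
(a :class:`~spherepipe.holo.QPImage` of one ROI) and a forward-model name;
its :meth:`~SphereModel.fit` returns a :class:`SphereFitResults` carrying
the fitted parameters, the corrected (rytov-sc) parameters where
applicable, the residual image, convergence diagnostics, a
:meth:`~SphereFitResults.summary` table and the derived dry mass.

Dry mass follows the Barer relation ``n = n_med + alpha * c`` with
refraction increment ``alpha`` (conventionally 0.18 mL/g for protein):
integrating the concentration over a homogeneous sphere gives

    m = (4/3) pi r^3 (n - n_med) / alpha

and, equivalently, integrating the measured phase over the image gives

    m = lambda * px^2 * sum(phi) / (2 pi alpha).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .holo import QPImage
from .models import (Grid, RytovSCCoeffs, SphereParams, edge_estimate,
                     projection_phase, rytov_field, rytov_sc_correct)

__all__ = ["SphereModel", "SphereFitResults", "fit_sphere_image",
           "dry_mass_sphere", "dry_mass_phase", "summarize",
           "DEFAULT_ALPHA"]

#: default refraction increment [mL/g] (conventional value for protein)
DEFAULT_ALPHA = 0.18

_ML_PER_M3 = 1e6  # 1 m^3 = 1e6 mL


def dry_mass_sphere(n: float, r: float, n_med: float,
                    alpha: float = DEFAULT_ALPHA) -> float:
    """Dry mass [g] of a homogeneous sphere of index ``n`` and radius
    ``r`` [m] in a medium of index ``n_med``; ``alpha`` in mL/g.

    ``m = (4/3) pi r^3 (n - n_med) / alpha``.  A sphere less dense than
    the medium yields a negative mass (allowed).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    volume_ml = (4 / 3) * np.pi * r ** 3 * _ML_PER_M3
    return volume_ml * (n - n_med) / alpha


def dry_mass_phase(qpi: QPImage, alpha: float = DEFAULT_ALPHA) -> float:
    """Dry mass [g] from the integrated background-corrected phase:
    ``m = lambda * px^2 * sum(phi) / (2 pi alpha)``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    integral = float(np.sum(qpi.phase)) * qpi.pixel_size ** 2  # [m^2 rad]
    return qpi.wavelength * integral * _ML_PER_M3 / (2 * np.pi * alpha)


# ---------------------------------------------------------------------------

@dataclass
class SphereFitResults:
    """Results of a sphere-model fit to one phase image."""

    params: SphereParams
    model: str
    cost: float
    n_iterations: int
    converged: bool
    residual_image: np.ndarray
    medium_index: float
    wavelength: float
    pixel_size: float
    params_corrected: tuple[float, float] | None = None  # (n_sc, r_sc)
    message: str = ""
    identifier: str = ""
    time: float = 0.0
    model_phase: np.ndarray | None = None

    @property
    def n(self) -> float:
        """Reported refractive index (corrected when available)."""
        return (self.params_corrected[0] if self.params_corrected
                else self.params.n)

    @property
    def r(self) -> float:
        """Reported radius [m] (corrected when available)."""
        return (self.params_corrected[1] if self.params_corrected
                else self.params.r)

    def dry_mass(self, alpha: float = DEFAULT_ALPHA) -> float:
        """Dry mass [g] from the reported (n, r)."""
        return dry_mass_sphere(self.n, self.r, self.medium_index, alpha)

    def summary(self, alpha: float = DEFAULT_ALPHA) -> str:
        p = self.params
        lines = [
            f"Sphere fit ({self.model})"
            + (f"  [{self.identifier}]" if self.identifier else ""),
            "-" * 48,
            f"{'refractive index n':28s} {p.n:.6f}",
            f"{'radius r [um]':28s} {p.r * 1e6:.4f}",
            f"{'center (cx, cy) [px]':28s} ({p.cx:.2f}, {p.cy:.2f})",
            f"{'phase offset [rad]':28s} {p.phase_offset:.5f}",
        ]
        if self.params_corrected:
            n_sc, r_sc = self.params_corrected
            lines += [f"{'corrected n_sc':28s} {n_sc:.6f}",
                      f"{'corrected r_sc [um]':28s} {r_sc * 1e6:.4f}"]
        lines += [
            f"{'medium index n_med':28s} {self.medium_index:.6f}",
            f"{'dry mass [pg]':28s} {self.dry_mass(alpha) * 1e12:.3f}",
            f"{'residual cost [rad^2]':28s} {self.cost:.4g}",
            f"{'model evaluations':28s} {self.n_iterations}",
            f"{'converged':28s} {self.converged}",
        ]
        return "\n".join(lines)


class SphereModel:
    """A sphere scattering model to be fitted to one ROI phase image.

    Parameters
    ----------
    qpi:
        Background-corrected ROI image (phase in rad).
    model:
        ``"projection"``, ``"rytov"`` or ``"rytov-sc"`` (fits the rytov
        forward model, then applies the affine systematic correction).
    init:
        Initial :class:`SphereParams`; default from :func:`edge_estimate`.
    supersample:
        Model images are evaluated on a ``supersample``-times finer grid
        and bin-averaged, anti-aliasing the sphere rim (sub-pixel rim
        effects otherwise dominate the radius bias).
    """

    def __init__(self, qpi: QPImage, model: str = "projection",
                 init: SphereParams | None = None, supersample: int = 2,
                 sc_coeffs: RytovSCCoeffs | None = None):
        if model not in ("projection", "rytov", "rytov-sc"):
            raise ValueError(f"unknown sphere model {model!r}")
        self.qpi = qpi
        self.model = model
        self.supersample = int(supersample)
        self.sc_coeffs = sc_coeffs
        if init is None:
            init = edge_estimate(qpi)
        self.init = init
        self._n_eval = 0

    # forward model ---------------------------------------------------------
    def forward(self, p: SphereParams) -> np.ndarray:
        """Model phase image on the data grid (supersampled + binned)."""
        ss = self.supersample
        H, W = self.qpi.phase.shape
        g = Grid(shape=(H * ss, W * ss),
                 pixel_size=self.qpi.pixel_size / ss,
                 wavelength=self.qpi.wavelength,
                 medium_index=self.qpi.medium_index)
        # pixel (i, j) covers supersampled pixels [i*ss, (i+1)*ss); its
        # center c maps to (c + 0.5) * ss - 0.5 on the fine grid
        p_ss = SphereParams(n=p.n, r=p.r,
                            cx=(p.cx + 0.5) * ss - 0.5,
                            cy=(p.cy + 0.5) * ss - 0.5,
                            phase_offset=p.phase_offset)
        if self.model == "projection":
            fine = projection_phase(p_ss, g)
        else:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fine, _ = rytov_field(p_ss, g)
        self._n_eval += 1
        return fine.reshape(H, ss, W, ss).mean(axis=(1, 3))

    # fitting ---------------------------------------------------------------
    def fit(self, max_evals: int = 250, tol: float = 1e-9) -> SphereFitResults:
        """Bounded least-squares fit of (n, r, cx, cy, phase_offset).

        Bounds: ``n in [n_med - 0.05, n_med + 0.30]``,
        ``r in [0.3 r_init, 3 r_init]``, center within the ROI, offset
        free.  Terminates when the relative cost improvement falls below
        ``tol`` or after ``max_evals`` model evaluations per parameter.
        """
        data = self.qpi.phase
        H, W = data.shape
        n_med = self.qpi.medium_index
        init = self.init
        r0 = init.r
        x0 = np.array([
            np.clip(init.n, n_med - 0.05 + 1e-9, n_med + 0.30 - 1e-9),
            init.r, np.clip(init.cx, 0, W - 1), np.clip(init.cy, 0, H - 1),
            init.phase_offset])
        lb = [n_med - 0.05, 0.3 * r0, 0.0, 0.0, -np.inf]
        ub = [n_med + 0.30, 3.0 * r0, W - 1.0, H - 1.0, np.inf]
        x_scale = [1e-2, max(0.05 * r0, 1e-9), 1.0, 1.0, 0.05]

        def resid(x):
            p = SphereParams(n=x[0], r=x[1], cx=x[2], cy=x[3],
                             phase_offset=x[4])
            return (self.forward(p) - data).ravel()

        self._n_eval = 0
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                ftol=tol, xtol=1e-12, gtol=None,
                                x_scale=x_scale,
                                max_nfev=max_evals * len(x0))
            params = SphereParams(n=sol.x[0], r=sol.x[1], cx=sol.x[2],
                                  cy=sol.x[3], phase_offset=sol.x[4])
            cost = float(2 * sol.cost)  # least_squares cost = 0.5 sum r^2
            converged = bool(sol.status > 0) and np.isfinite(cost)
            message = sol.message
        except (ValueError, FloatingPointError) as err:
            params = init
            cost = float("nan")
            converged = False
            message = f"fit failed: {err}"

        model_phase = self.forward(params)
        residual = model_phase - data
        corrected = None
        if self.model == "rytov-sc" and converged:
            corrected = rytov_sc_correct(params.n, params.r, n_med,
                                         self.sc_coeffs)
        return SphereFitResults(
            params=params, model=self.model, cost=cost,
            n_iterations=self._n_eval, converged=converged,
            residual_image=residual, medium_index=n_med,
            wavelength=self.qpi.wavelength, pixel_size=self.qpi.pixel_size,
            params_corrected=corrected, message=message,
            identifier=self.qpi.identifier, time=self.qpi.time,
            model_phase=model_phase)


def fit_sphere_image(roi_qpi: QPImage, model: str = "projection",
                     init: SphereParams | None = None,
                     **opts) -> SphereFitResults:
    """Convenience wrapper: build a :class:`SphereModel` and fit it."""
    sc_coeffs = opts.pop("sc_coeffs", None)
    supersample = opts.pop("supersample", 2)
    return SphereModel(roi_qpi, model=model, init=init,
                       supersample=supersample,
                       sc_coeffs=sc_coeffs).fit(**opts)


# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["identifier", "time_s", "radius_um", "refractive_index",
                "dry_mass_pg", "medium_index", "model", "method", "converged"]


def summarize(results, alpha: float = DEFAULT_ALPHA,
              method: str = "image"):
    """Assemble one analysis record per ROI and the TSV export.

    Returns ``(DataFrame, tsv_text)``.  Corrected (rytov-sc) values are
    reported when present; non-converged fits are retained with
    ``converged=False`` (exclusion is the user's decision via ignore
    lists, never silent).
    """
    rows = []
    for res in results:
        rows.append({
            "identifier": res.identifier,
            "time_s": res.time,
            "radius_um": res.r * 1e6,
            "refractive_index": res.n,
            "dry_mass_pg": res.dry_mass(alpha) * 1e12,
            "medium_index": res.medium_index,
            "model": res.model,
            "method": method,
            "converged": res.converged,
        })
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    return df, buf.getvalue()
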