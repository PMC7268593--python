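"""Smooth background estimation and removal for phase (and amplitude) maps.

Digital holographic microscopy data commonly shows a skewed background
phase (tilt and curvature from the reference beam and optics).  The
background is estimated over a mask of object-free pixels — a frame border
around the image, a threshold rule, or both — by least squares with one of
three nested profiles: constant ``offset``, plane ``tilt`` or full
second-order polynomial ``poly2o``.  A measured reference image can be
used instead (``profile="image"``).

Phase backgrounds are subtracted; amplitude backgrounds are divided out
(so the corrected background amplitude is ~1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BackgroundSpec", "make_background_mask", "fit_background",
           "correct_qpi"]

_MIN_RANK = {"offset": 1, "tilt": 3, "poly2o": 6}


@dataclass
class BackgroundSpec:
    """How to build the background mask and which profile to remove."""

    profile: str = "poly2o"            # offset | tilt | poly2o | image
    border_px: int | None = 10         # None: caller-resolved default
    binary_threshold: float | None = None
    offset_mode: str = "mean"          # mean | median

    def __post_init__(self):
        if self.profile not in ("offset", "tilt", "poly2o", "image"):
            raise ValueError(f"unknown background profile {self.profile!r}")
        if self.offset_mode not in ("mean", "median"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")
        if (self.profile != "image" and self.border_px == 0
                and self.binary_threshold is None):
            raise ValueError("need border_px > 0 and/or binary_threshold")


def make_background_mask(shape, spec: BackgroundSpec,
                         phase: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of background pixels.

    Border mode selects the frame of width ``border_px``; threshold mode
    selects pixels with ``phase < binary_threshold``; when both are set
    the intersection is used.  An empty mask (e.g. a border wider than
    half the image) raises ``ValueError("no background pixels")``.
    """
    H, W = shape
    mask = np.ones(shape, dtype=bool)
    if spec.border_px:
        b = int(spec.border_px)
        if b >= min(H, W) / 2:
            raise ValueError("no background pixels")
        border = np.ones(shape, dtype=bool)
        border[b:H - b, b:W - b] = False
        mask &= border
    if spec.binary_threshold is not None:
        if phase is None:
            raise ValueError("threshold mask requires phase data")
        mask &= phase < spec.binary_threshold
    if not mask.any():
        raise ValueError("no background pixels")
    return mask


def _design_matrix(shape, profile: str):
    """Polynomial design matrix on coordinates centered and scaled to
    [-1, 1] per axis (conditioning; the returned surface is in pixel
    space regardless)."""
    H, W = shape
    y = (np.arange(H) - (H - 1) / 2) / max((H - 1) / 2, 1)
    x = (np.arange(W) - (W - 1) / 2) / max((W - 1) / 2, 1)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [np.ones(H * W)]
    if profile in ("tilt", "poly2o"):
        cols += [xx.ravel(), yy.ravel()]
    if profile == "poly2o":
        cols += [(xx ** 2).ravel(), (yy ** 2).ravel(), (xx * yy).ravel()]
    return np.column_stack(cols)


def fit_background(phase: np.ndarray, mask: np.ndarray,
                   profile: str = "poly2o",
                   offset_mode: str = "mean") -> np.ndarray:
    """Least-squares background surface of ``phase`` over ``mask``.

    ``offset`` returns a constant (mean or median per ``offset_mode``);
    ``tilt`` a plane; ``poly2o`` a full quadratic.  The fit is exact (to
    numerical precision) when the masked data is exactly of the model
    form.  A rank-deficient mask geometry (e.g. collinear pixels for
    poly2o) raises ``ValueError("degenerate background mask")``.
    """
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    npx = int(mask.sum())
    if npx == 0:
        raise ValueError("no background pixels")
    if profile == "offset":
        stat = np.mean if offset_mode == "mean" else np.median
        return np.full(phase.shape, float(stat(phase[mask])))
    if profile not in ("tilt", "poly2o"):
        raise ValueError(f"cannot fit profile {profile!r}")
    if npx < _MIN_RANK[profile]:
        raise ValueError("degenerate background mask")
    A = _design_matrix(phase.shape, profile)
    Am = A[mask.ravel()]
    coef, _, rank, _ = np.linalg.lstsq(Am, phase[mask], rcond=None)
    if rank < Am.shape[1]:
        raise ValueError("degenerate background mask")
    return (A @ coef).reshape(phase.shape)


def correct_qpi(qpi, spec: BackgroundSpec, reference=None,
                correct_amplitude: bool = True):
    """Background-correct a QPImage: phase minus fitted surface, amplitude
    divided by its own fitted surface (offset profile).

    ``profile="image"`` subtracts ``reference.phase`` and divides by
    ``reference.amplitude`` instead (no registration is attempted).
    """
    if spec.profile == "image":
        if reference is None:
            raise ValueError("profile 'image' requires a reference image")
        phase = qpi.phase - reference.phase
        amplitude = qpi.amplitude / np.where(
            reference.amplitude > 0, reference.amplitude, 1.0)
        return qpi.copy(phase=phase, amplitude=amplitude)

    mask = make_background_mask(qpi.phase.shape, spec, qpi.phase)
    surface = fit_background(qpi.phase, mask, spec.profile, spec.offset_mode)
    phase = qpi.phase - surface
    amplitude = qpi.amplitude
    if correct_amplitude:
        amp_surface = fit_background(qpi.amplitude, mask, "offset",
                                     spec.offset_mode)
        with np.errstate(divide="ignore", invalid="ignore"):
            amplitude = np.where(amp_surface > 0,
                                 qpi.amplitude / amp_surface, qpi.amplitude)
    return qpi.copy(phase=phase, amplitude=amplitude)
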