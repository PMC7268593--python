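"""Off-axis hologram reconstruction by Fourier sideband isolation.

An off-axis hologram is the interference pattern of an object beam with a
tilted reference; the tilt places a carrier-shifted copy of the object
spectrum (the *sideband*) away from DC.  Reconstruction isolates that
sideband with a frequency-domain filter, demodulates the carrier, and the
inverse transform yields the complex field whose (unwrapped) argument is
the quantitative phase and whose modulus is the amplitude.

All carrier math uses spectra indexed with DC at the array centre.  The
sideband is searched in the half-plane ``ky >= 0``; for a real-valued
hologram the two sidebands are complex conjugates, so the sign convention
is fixed such that an optically denser object (``n > n_med``) produces
positive phase (``invert_phase`` flips it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap_reliability

__all__ = ["CarrierSpec", "FilterSpec", "QPImage", "detect_sideband",
           "make_filter", "reconstruct_hologram", "unwrap_phase"]


@dataclass
class CarrierSpec:
    """Carrier spatial frequency in radians per pixel; ``mode`` records
    whether it was auto-detected or user-fixed."""

    kx: float
    ky: float
    mode: str = "auto"

    def __post_init__(self):
        k = np.hypot(self.kx, self.ky)
        if not 0 < k < np.pi:
            raise ValueError("carrier must satisfy 0 < |k| < pi rad/px")


@dataclass
class FilterSpec:
    """Sideband filter: shape and radius as a fraction of the carrier
    distance (default 1/3, the largest radius that cannot overlap DC for a
    carrier separation of three filter radii)."""

    name: str = "smooth disk"
    size_rel: float = 1 / 3

    def __post_init__(self):
        if self.name not in ("disk", "smooth disk", "gauss", "square"):
            raise ValueError(f"unknown filter {self.name!r}")
        if not 0 < self.size_rel <= 1:
            raise ValueError("size_rel must be in (0, 1]")


@dataclass
class QPImage:
    """Unwrapped phase [rad] + normalised amplitude with imaging metadata
    (wavelength and pixel size in meters, time in seconds)."""

    phase: np.ndarray
    amplitude: np.ndarray
    wavelength: float
    pixel_size: float
    medium_index: float
    time: float = 0.0
    identifier: str = ""

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase contains non-finite values")
        if not np.all(np.isfinite(self.amplitude)) or (self.amplitude < 0).any():
            raise ValueError("amplitude must be finite and >= 0")

    @property
    def shape(self):
        return self.phase.shape

    def copy(self, **updates) -> "QPImage":
        kw = dict(phase=self.phase.copy(), amplitude=self.amplitude.copy(),
                  wavelength=self.wavelength, pixel_size=self.pixel_size,
                  medium_index=self.medium_index, time=self.time,
                  identifier=self.identifier)
        kw.update(updates)
        return QPImage(**kw)


# ---------------------------------------------------------------------------

def _centered_freq_bins(shape):
    """(by, bx) integer-bin coordinate grids relative to the centered DC."""
    H, W = shape
    by = np.arange(H)[:, None] - H // 2
    bx = np.arange(W)[None, :] - W // 2
    return by, bx


def detect_sideband(hologram) -> CarrierSpec:
    """Locate the off-axis carrier as the spectral peak in the half-plane
    ``ky >= 0``, excluding a DC disk of radius ``max(3, N/20)`` bins, with
    sub-bin refinement by the centroid of the 3x3 peak neighbourhood.

    Raises ``ValueError("no sideband detected")`` when the peak is weaker
    than five times the median spectral magnitude outside the DC disk.
    """
    img = np.asarray(getattr(hologram, "pixels", hologram), dtype=float)
    H, W = img.shape
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean())))
    by, bx = _centered_freq_bins((H, W))
    dc_radius = max(3, min(H, W) / 20)
    outside_dc = np.hypot(by, bx) > dc_radius

    search = outside_dc & (by >= 0)
    med = np.median(mag[outside_dc])
    masked = np.where(search, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(masked), mag.shape)
    if mag[iy, ix] < 5 * max(med, 1e-300):
        raise ValueError("no sideband detected")

    # centroid refinement over the 3x3 neighbourhood
    ys = np.clip(np.arange(iy - 1, iy + 2), 0, H - 1)
    xs = np.clip(np.arange(ix - 1, ix + 2), 0, W - 1)
    patch = mag[np.ix_(ys, xs)]
    wsum = patch.sum()
    cy = float((patch.sum(axis=1) * ys).sum() / wsum)
    cx = float((patch.sum(axis=0) * xs).sum() / wsum)

    kx = 2 * np.pi * (cx - W // 2) / W
    ky = 2 * np.pi * (cy - H // 2) / H
    if ky < 0:  # refinement may nudge an on-axis peak below the half-plane
        kx, ky = -kx, -ky
    return CarrierSpec(kx=kx, ky=ky, mode="auto")


def _carrier_bins(shape, carrier: CarrierSpec):
    H, W = shape
    return carrier.ky * H / (2 * np.pi), carrier.kx * W / (2 * np.pi)


def make_filter(shape, carrier: CarrierSpec, spec: FilterSpec) -> np.ndarray:
    """Frequency-domain sideband filter (weights in [0, 1], centered on the
    carrier, DC-centered array indexing).

    disk
        indicator of distance <= R
    smooth disk
        disk convolved with a Gaussian of sigma = R/10
    gauss
        Gaussian with weight 0.5 at distance R
    square
        indicator of max(|dkx|, |dky|) <= R

    ``R = size_rel * |k_carrier|`` in frequency bins; R < 2 raises
    ``ValueError("filter too small")``.
    """
    H, W = shape
    cby, cbx = _carrier_bins(shape, carrier)
    R = spec.size_rel * float(np.hypot(cby, cbx))
    if R < 2:
        raise ValueError("filter too small")
    by, bx = _centered_freq_bins(shape)
    dy = by - cby
    dx = bx - cbx
    if spec.name == "disk":
        w = (np.hypot(dy, dx) <= R).astype(float)
    elif spec.name == "smooth disk":
        w = ndimage.gaussian_filter(
            (np.hypot(dy, dx) <= R).astype(float), sigma=R / 10)
    elif spec.name == "gauss":
        sigma = R / np.sqrt(2 * np.log(2))
        w = np.exp(-(dy ** 2 + dx ** 2) / (2 * sigma ** 2))
    else:  # square
        w = ((np.abs(dy) <= R) & (np.abs(dx) <= R)).astype(float)
    return np.clip(w, 0.0, 1.0)


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Two-dimensional phase unwrapping (reliability-sorting algorithm).

    The result is congruent to the input mod 2 pi at every pixel and is
    offset-normalised so the median over a 5-px border frame lies in
    (-pi, pi].
    """
    wrapped = np.asarray(wrapped, dtype=float)
    out = np.asarray(_unwrap_reliability(wrapped), dtype=float)
    b = min(5, min(out.shape) // 2)
    frame = np.ones(out.shape, dtype=bool)
    if b > 0:
        frame[b:-b, b:-b] = False
    med = np.median(out[frame])
    out = out - 2 * np.pi * np.ceil((med - np.pi) / (2 * np.pi))
    return out


def reconstruct_hologram(hologram, carrier: CarrierSpec | None = None,
                         filt: FilterSpec | None = None, *,
                         wavelength: float, pixel_size: float,
                         medium_index: float, time: float = 0.0,
                         identifier: str = "",
                         invert_phase: bool = False) -> QPImage:
    """Reconstruct phase and amplitude from an off-axis hologram.

    Pipeline: FFT -> sideband filter at the carrier -> demodulate the
    carrier to DC -> inverse FFT -> complex field ``b``;
    ``phase = unwrap(-arg b)`` (sign fixed so denser objects are positive;
    see ``invert_phase``), ``amplitude = |b|``.
    """
    img = np.asarray(getattr(hologram, "pixels", hologram), dtype=float)
    if carrier is None:
        carrier = detect_sideband(img)
    if filt is None:
        filt = FilterSpec()
    weights = make_filter(img.shape, carrier, filt)

    spec = np.fft.fftshift(np.fft.fft2(img))
    field = np.fft.ifft2(np.fft.ifftshift(spec * weights))
    # exact (sub-bin) carrier demodulation in the image domain
    H, W = img.shape
    yy, xx = np.indices((H, W), dtype=float)
    kx, ky = carrier.kx, carrier.ky
    demod = field * np.exp(-1j * (kx * xx + ky * yy))
    if carrier.mode == "auto":
        # the spectral-peak centroid is only bin-accurate; refine by the
        # median residual phase ramp of the demodulated field (robust
        # against a localized object)
        ang = np.angle(demod)
        for axis, k in ((1, "kx"), (0, "ky")):
            d = np.diff(ang, axis=axis)
            d = np.angle(np.exp(1j * d))  # wrap to (-pi, pi]
            resid = float(np.median(d))
            if k == "kx":
                kx += resid
            else:
                ky += resid
        demod = field * np.exp(-1j * (kx * xx + ky * yy))
    field = demod

    sign = 1.0 if invert_phase else -1.0
    phase = unwrap_phase(np.angle(field) * sign)
    amplitude = np.abs(field)
    tm = getattr(hologram, "time", time)
    return QPImage(phase=phase, amplitude=amplitude, wavelength=wavelength,
                   pixel_size=pixel_size, medium_index=medium_index,
                   time=tm, identifier=identifier)
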