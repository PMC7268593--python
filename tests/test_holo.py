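"""Sideband detection, filters, reconstruction and phase unwrapping."""

import numpy as np
import pytest

from spherepipe.holo import (CarrierSpec, FilterSpec, detect_sideband,
                             make_filter, reconstruct_hologram, unwrap_phase)
from spherepipe.models import Grid, SphereParams
from spherepipe.synth import PhantomSpec, gen_hologram, gen_sphere_qpi

WL, PX, NMED = 550e-9, 0.107e-6, 1.335


def _phantom(shape=(256, 256), carrier=(0.8, 0.6), noise=0.0, contrast=1.0,
             n=1.355, r=4e-6, seed=0):
    grid = Grid(shape=shape, pixel_size=PX, wavelength=WL, medium_index=NMED)
    sphere = SphereParams(n=n, r=r, cx=shape[1] / 2, cy=shape[0] / 2)
    spec = PhantomSpec(spheres=[sphere], grid=grid,
                       carrier=CarrierSpec(*carrier, mode="fixed"),
                       noise_sigma=noise, fringe_contrast=contrast, seed=seed)
    qpi, _ = gen_sphere_qpi(spec)
    return qpi, gen_hologram(qpi, spec), spec


class TestDetectSideband:
    def test_detects_known_carrier_within_one_bin(self):
        _, holo, _ = _phantom(carrier=(0.8, 0.6))
        det = detect_sideband(holo)
        assert abs(det.kx - 0.8) <= 2 * np.pi / 256
        assert abs(det.ky - 0.6) <= 2 * np.pi / 256

    def test_flat_field_has_no_sideband(self):
        with pytest.raises(ValueError, match="no sideband detected"):
            detect_sideband(np.ones((128, 128)))

    def test_negative_ky_carrier_detected_as_conjugate(self):
        """A real image's spectrum is conjugate-symmetric: the search in
        the half-plane ky >= 0 finds (-kx, +ky) for a (kx, -ky) carrier."""
        _, holo, _ = _phantom(carrier=(0.8, -0.6))
        det = detect_sideband(holo)
        assert abs(det.kx - (-0.8)) <= 2 * np.pi / 256
        assert abs(det.ky - 0.6) <= 2 * np.pi / 256

    def test_carrier_shift_equivariance(self):
        """Shifting the true carrier by whole bins shifts the detection
        identically."""
        bins = 2 * np.pi / 256
        d1 = detect_sideband(_phantom(carrier=(20 * bins, 14 * bins))[1])
        d2 = detect_sideband(_phantom(carrier=(23 * bins, 14 * bins))[1])
        assert d2.kx - d1.kx == pytest.approx(3 * bins, abs=0.2 * bins)
        assert d2.ky - d1.ky == pytest.approx(0, abs=0.2 * bins)


class TestMakeFilter:
    CARRIER = CarrierSpec(kx=0.8, ky=0.6, mode="fixed")

    def _grid_dist(self, shape, carrier):
        H, W = shape
        by = np.arange(H)[:, None] - H // 2 - carrier.ky * H / (2 * np.pi)
        bx = np.arange(W)[None, :] - W // 2 - carrier.kx * W / (2 * np.pi)
        return np.hypot(by, bx)

    @pytest.mark.parametrize("name", ["disk", "smooth disk", "gauss",
                                      "square"])
    def test_weights_bounded_and_one_at_carrier(self, name):
        w = make_filter((256, 256), self.CARRIER, FilterSpec(name=name))
        assert w.min() >= 0 and w.max() <= 1
        d = self._grid_dist((256, 256), self.CARRIER)
        assert w[np.unravel_index(np.argmin(d), d.shape)] > 0.99

    def test_disk_is_sharp_indicator(self):
        spec = FilterSpec(name="disk")
        w = make_filter((256, 256), self.CARRIER, spec)
        d = self._grid_dist((256, 256), self.CARRIER)
        R = spec.size_rel * np.hypot(0.8 * 256, 0.6 * 256) / (2 * np.pi)
        assert np.all(w[d <= 0.99 * R] == 1.0)
        assert np.all(w[d >= 1.01 * R] == 0.0)

    def test_gauss_half_weight_at_radius(self):
        spec = FilterSpec(name="gauss")
        R = spec.size_rel * np.hypot(0.8 * 256, 0.6 * 256) / (2 * np.pi)
        w = make_filter((256, 256), self.CARRIER, spec)
        d = self._grid_dist((256, 256), self.CARRIER)
        ring = np.abs(d - R) < 0.05
        assert np.allclose(w[ring], 0.5, atol=0.01)

    def test_smooth_disk_monotone_along_ray(self):
        w = make_filter((256, 256), self.CARRIER, FilterSpec("smooth disk"))
        d = self._grid_dist((256, 256), self.CARRIER)
        order = np.argsort(d.ravel())
        # binned means must be non-increasing with distance
        prof = w.ravel()[order]
        dist = d.ravel()[order]
        bins = np.linspace(0, dist.max() / 4, 60)
        means = [prof[(dist >= a) & (dist < b)].mean()
                 for a, b in zip(bins, bins[1:])]
        assert all(m1 >= m2 - 1e-9 for m1, m2 in zip(means, means[1:]))

    def test_too_small_filter_rejected(self):
        tiny = CarrierSpec(kx=0.05, ky=0.05, mode="fixed")
        with pytest.raises(ValueError, match="filter too small"):
            make_filter((64, 64), tiny, FilterSpec())


class TestReconstruct:
    def test_roundtrip_noiseless(self):
        """Phase of a ~2.5 rad sphere recovered within 0.02 rad RMS
        (5% border margin)."""
        qpi, holo, spec = _phantom(carrier=(2.2, 1.5), n=1.36, r=4e-6)
        rec = reconstruct_hologram(holo, spec.carrier, FilterSpec(),
                                   wavelength=WL, pixel_size=PX,
                                   medium_index=NMED)
        b = 13  # 5% of 256
        d = (rec.phase - qpi.phase)[b:-b, b:-b]
        d -= np.median(d)
        assert np.sqrt(np.mean(d ** 2)) < 0.02

    def test_roundtrip_noisy(self):
        """1% intensity noise -> phase RMS error < 0.05 rad."""
        qpi, holo, spec = _phantom(carrier=(2.2, 1.5), noise=0.01, seed=11)
        rec = reconstruct_hologram(holo, spec.carrier, FilterSpec(),
                                   wavelength=WL, pixel_size=PX,
                                   medium_index=NMED)
        b = 13
        d = (rec.phase - qpi.phase)[b:-b, b:-b]
        d -= np.median(d)
        assert np.sqrt(np.mean(d ** 2)) < 0.05

    def test_auto_carrier_roundtrip(self):
        qpi, holo, _ = _phantom(carrier=(2.2, 1.5))
        rec = reconstruct_hologram(holo, None, FilterSpec(), wavelength=WL,
                                   pixel_size=PX, medium_index=NMED)
        b = 13
        d = (rec.phase - qpi.phase)[b:-b, b:-b]
        d -= np.median(d)
        assert np.sqrt(np.mean(d ** 2)) < 0.02

    def test_zero_phase_object_flat(self):
        # integer-bin carrier: no spectral leakage obscures the contract
        carrier = (2 * np.pi * 80 / 256, 2 * np.pi * 48 / 256)
        qpi, holo, spec = _phantom(n=NMED, carrier=carrier)  # no contrast
        rec = reconstruct_hologram(holo, spec.carrier, FilterSpec(),
                                   wavelength=WL, pixel_size=PX,
                                   medium_index=NMED)
        ph = rec.phase - np.median(rec.phase)
        assert np.max(np.abs(ph[13:-13, 13:-13])) < 1e-3

    def test_fringe_scaling_leaves_phase_scales_amplitude(self):
        """Linearity: halving the fringe modulation halves the amplitude
        and leaves the phase unchanged."""
        qpi, h1, spec1 = _phantom(carrier=(2.2, 1.5), contrast=1.0)
        _, h2, spec2 = _phantom(carrier=(2.2, 1.5), contrast=0.5)
        r1 = reconstruct_hologram(h1, spec1.carrier, FilterSpec(),
                                  wavelength=WL, pixel_size=PX,
                                  medium_index=NMED)
        r2 = reconstruct_hologram(h2, spec2.carrier, FilterSpec(),
                                  wavelength=WL, pixel_size=PX,
                                  medium_index=NMED)
        b = 13
        assert np.allclose(r1.phase[b:-b, b:-b], r2.phase[b:-b, b:-b],
                           atol=1e-6)
        ratio = r1.amplitude[b:-b, b:-b] / r2.amplitude[b:-b, b:-b]
        assert np.allclose(ratio, 2.0, atol=1e-3)


class TestUnwrap:
    def test_wrapped_ramp_recovered(self):
        yy, xx = np.indices((64, 64), dtype=float)
        plane = 0.4 * xx + 0.2 * yy
        wrapped = np.angle(np.exp(1j * plane))
        out = unwrap_phase(wrapped)
        d = out - plane
        # flat up to a global 2 pi integer offset
        assert np.ptp(d) < 1e-9
        assert abs(d.mean() / (2 * np.pi) - round(d.mean() / (2 * np.pi))) \
            < 1e-9

    def test_smooth_input_unchanged(self):
        rng = np.random.default_rng(0)
        smooth = 0.5 * np.sin(np.linspace(0, 3, 64))[:, None] \
            * np.cos(np.linspace(0, 2, 64))[None, :]
        out = unwrap_phase(smooth)
        assert np.allclose(out, smooth, atol=1e-9)

    def test_tall_sphere_phase_unwrapped_exactly(self):
        """A 7-rad projection sphere wraps several times; unwrapping must
        restore it to machine precision."""
        g = Grid(shape=(200, 200), pixel_size=PX, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=NMED + 7 * WL / (4 * np.pi * 5e-6), r=5e-6,
                         cx=100, cy=100)
        from spherepipe.models import projection_phase
        phase = projection_phase(p, g)
        assert phase.max() > 6.9  # really wraps
        out = unwrap_phase(np.angle(np.exp(1j * phase)))
        assert np.max(np.abs(out - phase)) < 1e-6

    def test_congruence_mod_2pi(self):
        rng = np.random.default_rng(1)
        wrapped = rng.uniform(-np.pi, np.pi, (32, 32))
        out = unwrap_phase(wrapped)
        k = (out - wrapped) / (2 * np.pi)
        assert np.allclose(k, np.round(k), atol=1e-9)
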