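"""Forward models: closed forms, weak-scattering limits, oracles."""

import numpy as np
import pytest

from spherepipe.holo import QPImage
from spherepipe.models import (Grid, RytovSCCoeffs, SphereParams,
                               born_field_fourier, edge_estimate,
                               projection_phase, rytov_field,
                               rytov_sc_correct)

WL, NMED = 550e-9, 1.335


class TestProjection:
    def test_peak_matches_closed_form(self):
        """lambda=500 nm, dn=0.02, r=5 um -> peak = 2.5133 rad."""
        g = Grid(shape=(256, 256), pixel_size=0.05e-6, wavelength=500e-9,
                 medium_index=1.335)
        p = SphereParams(n=1.355, r=5e-6, cx=128, cy=128)
        phase = projection_phase(p, g)
        expected = 4 * np.pi / 500e-9 * 0.02 * 5e-6
        assert expected == pytest.approx(2.5133, abs=1e-4)
        assert phase.max() == pytest.approx(expected, rel=1e-6)

    def test_zero_contrast_gives_offset_only(self):
        g = Grid(shape=(64, 64), pixel_size=0.1e-6, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=NMED, r=3e-6, cx=32, cy=32, phase_offset=0.7)
        assert np.allclose(projection_phase(p, g), 0.7)

    def test_phase_integral_matches_volume(self):
        """Riemann sum of the phase equals (2 pi/lambda) dn (4/3) pi r^3
        within 0.5% on a 400^2 grid at 0.05 um sampling."""
        g = Grid(shape=(400, 400), pixel_size=0.05e-6, wavelength=500e-9,
                 medium_index=1.335)
        p = SphereParams(n=1.355, r=5e-6, cx=200, cy=200)
        integral = projection_phase(p, g).sum() * g.pixel_size ** 2
        expected = (2 * np.pi / g.wavelength) * 0.02 \
            * (4 / 3) * np.pi * (5e-6) ** 3
        assert integral == pytest.approx(expected, rel=5e-3)

    def test_linear_in_contrast(self):
        g = Grid(shape=(64, 64), pixel_size=0.15e-6, wavelength=WL,
                 medium_index=NMED)
        p1 = SphereParams(n=NMED + 0.01, r=3e-6, cx=32, cy=32)
        p2 = SphereParams(n=NMED + 0.03, r=3e-6, cx=32, cy=32)
        assert np.allclose(projection_phase(p2, g),
                           3 * projection_phase(p1, g), atol=1e-12)

    def test_translation_equivariance(self):
        g = Grid(shape=(96, 96), pixel_size=0.15e-6, wavelength=WL,
                 medium_index=NMED)
        a = projection_phase(SphereParams(1.35, 2e-6, 40, 40), g)
        b = projection_phase(SphereParams(1.35, 2e-6, 47, 43), g)
        assert np.allclose(a[20:60, 20:60], b[23:63, 27:67], atol=1e-12)


class TestRytov:
    GRID = Grid(shape=(256, 256), pixel_size=0.1e-6, wavelength=WL,
                medium_index=NMED)

    def test_zero_contrast_trivial(self):
        p = SphereParams(n=NMED, r=4e-6, cx=128, cy=128, phase_offset=0.3)
        phase, amplitude = rytov_field(p, self.GRID)
        assert np.allclose(phase, 0.3, atol=1e-12)
        assert np.allclose(amplitude, 1.0, atol=1e-12)

    def test_weak_scattering_interior_limit(self):
        """Away from the diffraction-dominated rim band, the Rytov phase
        approaches the projection phase as the contrast vanishes, and the
        relative deviation decreases monotonically with contrast."""
        yy, xx = np.indices(self.GRID.shape)
        rho = np.hypot(xx - 128, yy - 128) * self.GRID.pixel_size
        devs = []
        for dn in (0.005, 0.002, 0.001, 0.0005):
            p = SphereParams(n=NMED + dn, r=4e-6, cx=128, cy=128)
            phase, _ = rytov_field(p, self.GRID)
            proj = projection_phase(p, self.GRID)
            interior = rho <= 0.8 * p.r
            devs.append(np.max(np.abs(phase - proj)[interior]) / proj.max())
        assert devs[-1] < 0.02  # dn = 0.0005: < 2% of the peak phase
        assert all(a > b for a, b in zip(devs, devs[1:]))  # monotone

    def test_peak_follows_contrast_superlinearity(self):
        """The scattering potential chi = (n/n_med)^2 - 1 is superlinear
        in dn, so the Rytov peak exceeds the projection peak by about
        dn / (2 n_med) in relative terms at moderate contrast."""
        p = SphereParams(n=NMED + 0.03, r=5e-6, cx=128, cy=128)
        phase, _ = rytov_field(p, self.GRID)
        proj = projection_phase(p, self.GRID)
        ratio = phase.max() / proj.max()
        assert ratio == pytest.approx(1 + 0.03 / (2 * NMED), abs=0.01)

    def test_translation_equivariance(self):
        g = Grid(shape=(128, 128), pixel_size=0.15e-6, wavelength=WL,
                 medium_index=NMED)
        pa = SphereParams(n=NMED + 0.01, r=3e-6, cx=60, cy=60)
        pb = SphereParams(n=NMED + 0.01, r=3e-6, cx=65, cy=63)
        a, _ = rytov_field(pa, g)
        b, _ = rytov_field(pb, g)
        assert np.allclose(a[30:80, 30:80], b[33:83, 35:85], atol=1e-6)

    def test_under_resolved_sphere_warns(self):
        g = Grid(shape=(64, 64), pixel_size=0.5e-6, wavelength=WL,
                 medium_index=NMED)
        with pytest.warns(UserWarning, match="under-resolved"):
            rytov_field(SphereParams(n=NMED + 0.01, r=2e-6, cx=32, cy=32), g)


class TestBornOracle:
    def test_fourier_route_matches_direct_space_integration(self):
        """The FFT-route scattered field agrees with brute-force
        direct-space Born integration (64^3 voxels) within 1% of the
        field peak on an exterior plane."""
        from spherepipe.born_direct import born_field_direct_radial
        g = Grid(shape=(128, 128), pixel_size=0.15e-6, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=NMED * 1.03, r=5e-6, cx=63.5, cy=63.5)
        z_d = p.r + 3e-6
        u_fourier = born_field_fourier(p, g, z=z_d, pad_factor=4)
        rho = g.radius_map(p.cx, p.cy)
        radii = np.linspace(0, rho.max() + 2e-7, 400)
        prof = born_field_direct_radial(p, g, z_d, radii, n_voxels=64,
                                        supersample=3)
        u_direct = (np.interp(rho, radii, prof.real)
                    + 1j * np.interp(rho, radii, prof.imag))
        err = np.abs(u_fourier - u_direct).max() / np.abs(u_direct).max()
        assert err < 0.01

    def test_direct_route_requires_exterior_plane(self):
        from spherepipe.born_direct import born_field_direct_radial
        g = Grid(shape=(32, 32), pixel_size=0.2e-6, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=NMED + 0.01, r=3e-6, cx=16, cy=16)
        with pytest.raises(ValueError, match="outside the sphere"):
            born_field_direct_radial(p, g, 1e-6, np.zeros(3))


class TestEdgeEstimate:
    def _qpi(self, phase, px=0.1e-6):
        return QPImage(phase=phase, amplitude=np.ones_like(phase),
                       wavelength=WL, pixel_size=px, medium_index=NMED)

    def test_recovers_noiseless_phantom(self):
        g = Grid(shape=(200, 200), pixel_size=0.1e-6, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=1.355, r=5e-6, cx=100, cy=100)
        est = edge_estimate(self._qpi(projection_phase(p, g)))
        assert abs(est.r / p.r - 1) < 0.02
        assert abs(est.n - p.n) < 0.002
        assert abs(est.cx - 100) < 1 and abs(est.cy - 100) < 1

    def test_disk_average_identity(self):
        """Mean phase inside the true circle equals
        (2 pi / lambda) dn (4 r / 3) within 0.5% (Riemann sum)."""
        g = Grid(shape=(400, 400), pixel_size=0.05e-6, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=1.355, r=5e-6, cx=200, cy=200)
        phase = projection_phase(p, g)
        rho = g.radius_map(p.cx, p.cy)
        mean_inside = phase[rho <= p.r].mean()
        expected = (2 * np.pi / WL) * 0.02 * (4 * p.r / 3)
        assert mean_inside == pytest.approx(expected, rel=5e-3)

    def test_blank_roi_errors(self):
        with pytest.raises(ValueError, match="no object edge found"):
            edge_estimate(self._qpi(np.zeros((64, 64))))

    def test_estimate_reproduces_disk_average(self):
        """Projecting the estimated sphere reproduces the measured mean
        phase within 1% (closure of the estimator)."""
        g = Grid(shape=(200, 200), pixel_size=0.1e-6, wavelength=WL,
                 medium_index=NMED)
        p = SphereParams(n=1.36, r=4e-6, cx=100, cy=100)
        phase = projection_phase(p, g)
        est = edge_estimate(self._qpi(phase))
        model = projection_phase(est, g) - est.phase_offset
        rho = g.radius_map(est.cx, est.cy)
        inside = rho <= est.r
        assert model[inside].mean() == pytest.approx(
            phase[inside].mean(), rel=0.01)


class TestRytovSC:
    def test_identity_coefficients_reproduce_fit(self):
        ident = RytovSCCoeffs()
        assert rytov_sc_correct(1.36, 5e-6, NMED, ident) == (1.36, 5e-6)

    def test_pure_offset_at_zero_contrast(self):
        coeffs = RytovSCCoeffs(c_n0=0.01, c_n1=1.0, c_r0=1.0, c_r1=0.0)
        n_sc, r_sc = rytov_sc_correct(NMED, 5e-6, NMED, coeffs)
        assert n_sc == pytest.approx(NMED * 1.01)
        assert r_sc == 5e-6

    def test_affine_formula(self):
        coeffs = RytovSCCoeffs(c_n0=0.001, c_n1=0.98, c_r0=0.99, c_r1=0.5)
        n_fit, r_fit = 1.36, 5e-6
        x = n_fit / NMED - 1
        n_sc, r_sc = rytov_sc_correct(n_fit, r_fit, NMED, coeffs)
        assert n_sc == pytest.approx(NMED * (1 + 0.001 + 0.98 * x))
        assert r_sc == pytest.approx(r_fit * (0.99 + 0.5 * x))

    def test_default_coefficients_near_identity(self):
        """The packaged calibration compensates numeric route bias only,
        so it must stay close to the identity mapping."""
        from spherepipe._constants import RYTOV_SC_DEFAULT
        assert abs(RYTOV_SC_DEFAULT.c_n0) < 0.01
        assert RYTOV_SC_DEFAULT.c_n1 == pytest.approx(1.0, abs=0.05)
        assert RYTOV_SC_DEFAULT.c_r0 == pytest.approx(1.0, abs=0.05)
        assert abs(RYTOV_SC_DEFAULT.c_r1) < 0.05

    def test_calibration_harness_recovers_reference_contrast(self):
        """Small-scale calibration run: fitting the Rytov model to
        direct-route Born references and applying the regressed affine
        correction recovers the true contrast within 5%."""
        from spherepipe.calib import calibrate_rytov_sc
        coeffs, records = calibrate_rytov_sc(
            x_grid=(0.01, 0.04), r_grid=(3e-6,), n_voxels=48,
            pixels_per_radius=10.0)
        for rec in records:
            n_fit = NMED * (1 + rec["x_fit"])
            n_sc, r_sc = rytov_sc_correct(n_fit, rec["r_fit"], NMED, coeffs)
            assert abs((n_sc / NMED - 1) / rec["x_true"] - 1) < 0.05
            assert abs(r_sc / rec["r_true"] - 1) < 0.05
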