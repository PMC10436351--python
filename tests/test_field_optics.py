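"""Image formation: Fresnel interface, propagation, BFP mask, contrast."""

import dataclasses

import numpy as np
import pytest

from mpsim import (FieldMap, OpticalConfig, apply_bfp_mask, fresnel_interface,
                   image_point_source, propagate, ratiometric_contrast)
from mpsim.field_optics import (DivisionGuardError, InvalidConfigError,
                                PropagationRangeError, WrongPlaneError,
                                imaged_reference_field, sample_to_bfp)


class TestFresnelInterface:
    def test_normal_incidence_reflectivity(self, config):
        co = fresnel_interface(config, [0.0])
        assert abs(co.rs[0]) ** 2 == pytest.approx(0.004, abs=2e-4)
        assert abs(co.rs[0]) ** 2 == pytest.approx(abs(co.rp[0]) ** 2)

    def test_index_matched_interface_is_transparent(self):
        cfg = OpticalConfig(n_glass=1.4, n_medium=1.4, na=1.35,
                            n_immersion=1.4)
        co = fresnel_interface(cfg, np.linspace(0, 1.2, 7))
        assert np.allclose(co.rs, 0) and np.allclose(co.rp, 0)
        assert np.allclose(co.t1s, 1) and np.allclose(co.t2p, 1)

    def test_45deg_s_pol_against_textbook_formula(self, config):
        # direct evaluation: rs = (n1 cos t1 - n2 cos t2)/(n1 cos t1 + n2 cos t2)
        n1, n2, th = 1.515, 1.333, np.deg2rad(45)
        c1 = np.cos(th)
        c2 = np.sqrt(1 - (n1 * np.sin(th) / n2) ** 2)
        expected = (n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)
        co = fresnel_interface(config, [th])
        assert co.rs[0] == pytest.approx(expected, rel=1e-12)

    def test_energy_conservation_subcritical(self, config):
        th = np.linspace(0, 0.9 * np.arcsin(1.333 / 1.515), 25)
        co = fresnel_interface(config, th)
        n1, n2 = 1.515, 1.333
        c1 = np.cos(th)
        c2 = np.sqrt(1 - (n1 * np.sin(th) / n2) ** 2).real
        ts_power = np.abs(co.t1s) ** 2 * (n2 * c2) / (n1 * c1)
        assert np.allclose(np.abs(co.rs) ** 2 + ts_power, 1.0, atol=1e-10)

    def test_rejects_nonphysical_inputs(self, config):
        with pytest.raises(InvalidConfigError):
            fresnel_interface(config, [-0.1])
        with pytest.raises(InvalidConfigError):
            OpticalConfig(n_medium=-1.0)


def _gaussian_field(config, waist=0.6e-6):
    x = config.pixel_centers()
    xx, yy = np.meshgrid(x, x)
    data = np.exp(-(xx**2 + yy**2) / waist**2).astype(complex)
    f = FieldMap(data, "sample", config.pixel_size)
    f.wavelength = config.wavelength
    return f


class TestPropagate:
    def test_zero_distance_is_identity(self, config):
        f = _gaussian_field(config)
        out = propagate(f, 0.0, 1.333)
        assert np.array_equal(out.data, f.data)

    def test_plane_wave_phase_advance(self, config):
        n = config.grid_size
        k = 2 * np.pi / config.wavelength * 1.333
        # tilted plane wave on an exact grid frequency
        kx = 2 * np.pi * 3 / (n * config.pixel_size)
        x = config.pixel_centers()
        f = FieldMap(np.exp(1j * kx * x)[None, :] * np.ones((n, 1)),
                     "sample", config.pixel_size)
        f.wavelength = config.wavelength
        d = 2e-6
        out = propagate(f, d, 1.333)
        expected = np.exp(1j * np.sqrt(k**2 - kx**2) * d)
        ratio = out.data / f.data
        assert np.allclose(ratio, expected, atol=1e-9)

    def test_round_trip_inversion(self, config):
        # window large enough that the Gaussian is negligible both at the
        # edges and beyond the evanescent cutoff
        cfg = dataclasses.replace(config, grid_size=128)
        f = _gaussian_field(cfg, waist=0.7e-6)
        out = propagate(propagate(f, 1.5e-6, 1.333), -1.5e-6, 1.333)
        err = np.abs(out.data - f.data).max() / np.abs(f.data).max()
        assert err < 1e-10

    def test_parseval_power_conservation(self, config):
        f = _gaussian_field(config)
        out = propagate(f, 1.5e-6, 1.333)
        assert out.power == pytest.approx(f.power, rel=1e-9)

    def test_wraparound_refused(self, config):
        f = _gaussian_field(config)
        with pytest.raises(PropagationRangeError):
            propagate(f, 1e-3, 1.333)


class TestBfpMask:
    def test_transparent_mask_is_identity(self, config):
        cfg = dataclasses.replace(config, mask_transmission=1.0, mask_phase=0.0)
        bfp = sample_to_bfp(_gaussian_field(cfg))
        out = apply_bfp_mask(bfp, cfg)
        assert np.allclose(out.data, bfp.data)

    def test_power_attenuation_inside_cutoff(self, config):
        cfg = dataclasses.replace(config, mask_transmission=0.01)
        # broad Gaussian -> spectrum concentrated well inside the cutoff
        bfp = sample_to_bfp(_gaussian_field(cfg, waist=0.8e-6))
        out = apply_bfp_mask(bfp, cfg)
        assert out.power == pytest.approx(0.01 * bfp.power, rel=1e-2)

    def test_phase_mask_per_pixel_oracle(self, config):
        cfg = dataclasses.replace(config, mask_transmission=0.01,
                                  mask_phase=np.pi / 2)
        bfp = sample_to_bfp(_gaussian_field(cfg))
        out = apply_bfp_mask(bfp, cfg)
        kx, ky = bfp.freq_grid()
        inside = kx**2 + ky**2 <= (cfg.mask_cutoff_na * cfg.k0) ** 2
        expected = np.where(inside, bfp.data * 0.1 * 1j, bfp.data)
        assert np.allclose(out.data, expected)

    def test_wrong_plane_rejected(self, config):
        with pytest.raises(WrongPlaneError):
            apply_bfp_mask(_gaussian_field(config), config)


class TestImageFormation:
    def test_zero_scatterer_gives_uniform_reference(self, config):
        img = image_point_source(config, 0.0)
        assert img.std() / img.mean() < 1e-12
        r2 = config.fresnel_normal**2
        assert img.mean() == pytest.approx(r2 * config.mask_transmission, rel=1e-9)

    def test_contrast_linear_in_polarizability(self, config):
        bkg = image_point_source(config, 0.0)
        c1 = ratiometric_contrast(image_point_source(config, 2e4), bkg)
        c2 = ratiometric_contrast(image_point_source(config, 4e4), bkg)
        peak = np.abs(c1).max()
        # interferometric term doubles within quadratic corrections
        assert np.abs(c2 / c1)[np.abs(c1) > 0.3 * peak].mean() == pytest.approx(
            2.0, rel=0.01)

    def test_wave_optics_scale_invariance(self, config):
        sphere_alpha = 1e5
        scaled = OpticalConfig(
            wavelength=config.wavelength * 2, na=config.na,
            mask_transmission=config.mask_transmission,
            pixel_size=config.pixel_size * 2, grid_size=config.grid_size,
            pupil_samples=config.pupil_samples)
        bkg = image_point_source(config, 0.0)
        c = ratiometric_contrast(image_point_source(config, sphere_alpha), bkg)
        bkg2 = image_point_source(scaled, 0.0)
        # alpha scales with volume = length^3
        c2 = ratiometric_contrast(
            image_point_source(scaled, sphere_alpha * 8), bkg2)
        assert np.abs(c2).max() == pytest.approx(np.abs(c).max(), rel=1e-6)

    def test_closed_form_interferometric_contrast(self):
        # synthetic fields: C = 2 (s/r) cos(phi) + (s/r)^2
        r, s, phi = 0.006, 0.0004, 0.7
        i_bkg = np.full((4, 4), r**2)
        i_det = np.abs(r + s * np.exp(1j * phi)) ** 2 * np.ones((4, 4))
        c = ratiometric_contrast(i_det, i_bkg)
        expected = 2 * (s / r) * np.cos(phi) + (s / r) ** 2
        assert np.allclose(c, expected, rtol=1e-12)

    def test_ratiometric_trivial_cases(self):
        i = np.ones((8, 8))
        assert np.all(ratiometric_contrast(i, i) == 0)
        assert np.allclose(ratiometric_contrast(1.01 * i, i), 0.01)
        with pytest.raises(DivisionGuardError):
            ratiometric_contrast(i, 0 * i)

    def test_flat_reference_field_uniform(self, config):
        ref = imaged_reference_field(config, None, z_sample=0.3e-6)
        assert np.allclose(ref, ref[0, 0])
        assert abs(ref[0, 0]) == pytest.approx(
            abs(config.fresnel_normal) * np.sqrt(config.mask_transmission))
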