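import numpy as np
import pytest

import mechanoscope as ms
from mechanoscope.reconstruct import _odd_size


def make_volume(data, geometry, **kw):
    return ms.ComplexOCMVolume(data=data, geometry=geometry, **kw)


class TestPhaseDifference:
    def test_identical_volumes_zero_phase(self, rng, geometry):
        d = rng.standard_normal((6, 6, 12)) + 1j * rng.standard_normal((6, 6, 12))
        a, b = make_volume(d, geometry), make_volume(d.copy(), geometry)
        dphi, w = ms.phase_difference(a, b)
        assert np.allclose(dphi, 0.0, atol=1e-12)
        assert np.all(w > 0)

    def test_unit_phasors_quarter_turn(self, geometry):
        a = make_volume(np.full((1, 1, 1), np.exp(1j * 0.0)), geometry)
        b = make_volume(np.full((1, 1, 1), np.exp(1j * np.pi / 2)), geometry)
        dphi, _ = ms.phase_difference(a, b, averaging_kernel_um=(0.1, 0.1, 0.1))
        assert dphi[0, 0, 0] == pytest.approx(np.pi / 2)

    def test_kernel_average_matches_bruteforce_complex_sum(self, rng, geometry):
        shape = (9, 9, 9)
        a = make_volume(rng.standard_normal(shape) + 1j * rng.standard_normal(shape), geometry)
        b = make_volume(rng.standard_normal(shape) + 1j * rng.standard_normal(shape), geometry)
        dphi, _ = ms.phase_difference(a, b, averaging_kernel_um=(6.0, 6.0, 6.0))
        # explicit complex-sum oracle at the central voxel (3x3x3 kernel)
        acc = 0.0 + 0.0j
        for i in range(3, 6):
            for j in range(3, 6):
                for k in range(3, 6):
                    acc += b.data[i, j, k] * np.conj(a.data[i, j, k])
        assert dphi[4, 4, 4] == pytest.approx(np.angle(acc), abs=1e-12)

    def test_shape_mismatch_rejected(self, rng, geometry):
        a = make_volume(np.ones((4, 4, 4), complex), geometry)
        b = make_volume(np.ones((4, 4, 5), complex), geometry)
        with pytest.raises(ValueError):
            ms.phase_difference(a, b)


class TestPhaseToDisplacement:
    def test_zero_phase_zero_displacement(self, geometry):
        disp = ms.phase_to_displacement(np.zeros((2, 2, 4)), geometry)
        assert np.all(disp.u_z == 0.0)

    def test_pi_phase_arithmetic(self):
        geom = ms.AcquisitionGeometry(wavelength_nm=800.0, refractive_index=1.35)
        disp = ms.phase_to_displacement(np.full((1, 1, 1), np.pi), geom)
        assert disp.u_z[0, 0, 0] == pytest.approx(800.0 / (4.0 * 1.35), rel=1e-6)  # ~148.15 nm

    def test_linearity(self, rng, geometry):
        dphi = rng.uniform(-1.0, 1.0, (3, 3, 6))
        u1 = ms.phase_to_displacement(dphi, geometry).u_z
        u2 = ms.phase_to_displacement(2.0 * dphi, geometry).u_z
        assert np.allclose(u2, 2.0 * u1, rtol=1e-12)

    def test_invalid_flag_propagates_from_zero_weight(self, geometry):
        w = np.ones((2, 2, 4))
        w[0, 0, 0] = 0.0
        disp = ms.phase_to_displacement(np.zeros((2, 2, 4)), geometry, weight=w)
        assert not disp.valid[0, 0, 0]
        assert disp.valid.sum() == 15


class TestEstimateStrain:
    def test_linear_profile_recovered_exactly(self, geometry, rng):
        shape = (6, 6, 40)
        z_nm = (np.arange(40) + 0.5) * 2000.0
        u = np.broadcast_to(0.002 * z_nm, shape).copy()
        disp = ms.DisplacementField(
            u_z=u, weight=rng.uniform(0.5, 2.0, shape), valid=np.ones(shape, bool), geometry=geometry
        )
        strain = ms.estimate_strain(disp, window_fwhm_axial_um=14.0, smoothing_fwhm_lateral_um=5.0)
        assert np.allclose(strain.strain_z[strain.valid], 0.002, rtol=1e-9)

    def test_weighted_normal_equation_example(self):
        # points (z, u) = (0,0), (1,1), (2,4), weights (1,1,4) -> slope 15/7
        geom = ms.AcquisitionGeometry(voxel_pitch_um=(1.0, 1.0, 1e-3))  # z pitch 1 nm
        u = np.array([0.0, 1.0, 4.0])[None, None, :]
        w = np.array([1.0, 1.0, 4.0])[None, None, :]
        disp = ms.DisplacementField(u_z=u, weight=w, valid=w > 0, geometry=geom)
        strain = ms.estimate_strain(disp, window_fwhm_axial_um=3e-3, smoothing_fwhm_lateral_um=0.0)
        assert strain.strain_z[0, 0, 1] == pytest.approx(15.0 / 7.0, rel=1e-12)

    def test_uniform_weights_equal_unweighted(self, geometry, rng):
        shape = (5, 5, 30)
        u = rng.standard_normal(shape) * 10.0
        d1 = ms.DisplacementField(u, np.full(shape, 3.7), np.ones(shape, bool), geometry)
        d2 = ms.DisplacementField(u.copy(), np.ones(shape), np.ones(shape, bool), geometry)
        s1 = ms.estimate_strain(d1, 10.0, 0.0)
        s2 = ms.estimate_strain(d2, 10.0, 0.0)
        assert np.allclose(s1.strain_z[s1.valid], s2.strain_z[s2.valid], rtol=1e-10)

    def test_matches_bruteforce_wls_oracle_on_random_field(self, rng):
        # every voxel of a random 32^3 field, including truncated edge windows
        geom = ms.AcquisitionGeometry(voxel_pitch_um=(2.0, 2.0, 2.0))
        shape = (32, 32, 32)
        u = rng.standard_normal(shape) * 50.0
        w = rng.uniform(0.0, 2.0, shape)
        disp = ms.DisplacementField(u, w, w > 0, geom)
        strain = ms.estimate_strain(disp, window_fwhm_axial_um=10.0, smoothing_fwhm_lateral_um=0.0)
        n = 5  # 10 um / 2 um pitch
        z = (np.arange(shape[2]) + 0.5) * 2000.0
        for i, j in rng.integers(0, 32, size=(40, 2)):
            for k in rng.integers(0, 32, size=8):
                lo, hi = max(0, k - n // 2), min(shape[2], k + n // 2 + 1)
                zz, uu, ww = z[lo:hi], u[i, j, lo:hi], w[i, j, lo:hi]
                A = np.array([[np.sum(ww), np.sum(ww * zz)], [np.sum(ww * zz), np.sum(ww * zz * zz)]])
                bvec = np.array([np.sum(ww * uu), np.sum(ww * zz * uu)])
                slope = np.linalg.solve(A, bvec)[1]
                assert strain.strain_z[i, j, k] == pytest.approx(slope, rel=1e-10, abs=1e-14)

    def test_all_zero_weight_window_invalid(self, geometry):
        shape = (4, 4, 20)
        w = np.ones(shape)
        w[1, 1, :] = 0.0
        disp = ms.DisplacementField(np.ones(shape), w, w > 0, geometry)
        strain = ms.estimate_strain(disp, 10.0, 0.0)
        assert not strain.valid[1, 1].any()
        assert strain.valid[0, 0].all()


class TestInterfaceAndStress:
    def test_synthetic_step_detected_within_one_voxel(self, geometry):
        vol = np.ones((16, 16, 120))
        vol[:, :, 50:] = 4.0  # step at z = 100 um (pitch 2 um)
        iface, flagged = ms.detect_interface(vol, geometry, search_band_um=(60.0, 160.0))
        assert not flagged.any()
        assert np.all(np.abs(iface - 100.0) <= 2.0)

    def test_phantom_interface_matches_configuration(self, tiny_spec):
        truth = ms.solve_uniaxial_compression(ms.build_modulus_field(tiny_spec), tiny_spec)
        unloaded, _ = ms.render_ocm_pair(truth, tiny_spec, seed=9)
        iface, flagged = ms.detect_interface(unloaded.intensity(), tiny_spec.geometry)
        assert np.median(iface) == pytest.approx(tiny_spec.sample_thickness_um, abs=4.0)

    def test_constant_volume_all_flagged(self, geometry):
        _, flagged = ms.detect_interface(np.ones((8, 8, 30)), geometry)
        assert flagged.all()

    def test_uniform_layer_strain_linear_layer(self, geometry):
        shape = (6, 6, 100)
        strain = ms.StrainField(
            strain_z=np.full(shape, 0.05),
            valid=np.ones(shape, bool),
            geometry=geometry,
            weight=np.ones(shape),
        )
        cal = ms.LayerCalibration.linear(20.0)
        iface = np.full((6, 6), 100.0)
        stress = ms.layer_stress_map(strain, iface, cal, band_gap_um=5.0, band_width_um=50.0)
        assert np.allclose(stress.sigma_kpa, 1.0, rtol=1e-9)
        assert stress.valid.all()

    def test_zero_layer_strain_zero_stress(self, geometry):
        shape = (4, 4, 100)
        strain = ms.StrainField(np.zeros(shape), np.ones(shape, bool), geometry, np.ones(shape))
        stress = ms.layer_stress_map(strain, np.full((4, 4), 100.0), ms.LayerCalibration.linear(20.0))
        assert np.allclose(stress.sigma_kpa, 0.0, atol=1e-15)

    def test_cubic_calibration_band_conversion(self, geometry):
        eps_samples = np.linspace(0.0, 0.08, 9)
        cal = ms.fit_layer_calibration(
            np.column_stack([eps_samples, 20.0 * eps_samples + 300.0 * eps_samples**3])
        )
        shape = (4, 4, 100)
        strain = ms.StrainField(np.full(shape, 0.04), np.ones(shape, bool), geometry, np.ones(shape))
        stress = ms.layer_stress_map(strain, np.full((4, 4), 100.0), cal)
        assert np.allclose(stress.sigma_kpa, 0.8192, rtol=0.01)

    def test_band_outside_volume_rejected(self, geometry):
        shape = (4, 4, 20)  # 40 um deep volume
        strain = ms.StrainField(np.zeros(shape), np.ones(shape, bool), geometry, np.ones(shape))
        with pytest.raises(ValueError):
            ms.layer_stress_map(strain, np.full((4, 4), 30.0), ms.LayerCalibration.linear(20.0))


class TestYoungModulus:
    def _strain(self, geometry, value, shape=(4, 4, 100)):
        return ms.StrainField(
            strain_z=np.full(shape, value),
            valid=np.ones(shape, bool),
            geometry=geometry,
            weight=np.ones(shape),
            window_fwhm_um=10.0,
        )

    def test_simple_ratio(self, geometry):
        strain = self._strain(geometry, 0.01)
        stress = ms.StressMap(np.full((4, 4), 1.0), np.full((4, 4), 150.0), np.ones((4, 4), bool))
        mod = ms.young_modulus(stress, strain)
        assert np.allclose(mod.E_kpa[mod.valid], 100.0, rtol=1e-12)
        # layer side and interface-adjacent voxels are masked
        z = (np.arange(100) + 0.5) * 2.0
        assert not mod.valid[:, :, z >= 145.0].any()

    def test_zero_strain_masked_not_raised(self, geometry):
        strain = self._strain(geometry, 0.0)
        stress = ms.StressMap(np.full((4, 4), 1.0), np.full((4, 4), 150.0), np.ones((4, 4), bool))
        mod = ms.young_modulus(stress, strain)
        assert not mod.valid.any()

    def test_strain_floor_masks_noise_level_voxels(self, geometry):
        strain = self._strain(geometry, 5e-5)
        stress = ms.StressMap(np.full((4, 4), 1.0), np.full((4, 4), 150.0), np.ones((4, 4), bool))
        assert not ms.young_modulus(stress, strain, strain_floor=1e-4).valid.any()
        assert ms.young_modulus(stress, strain, strain_floor=1e-5).valid.any()


class TestElasticityResolution:
    def test_zero_processing_returns_optical_resolution(self):
        geom = ms.AcquisitionGeometry()
        assert ms.elasticity_resolution(geom, 0.0, 0.0) == pytest.approx((0.5, 0.5, 1.4))

    def test_axial_quadrature_arithmetic(self):
        geom = ms.AcquisitionGeometry()
        res = ms.elasticity_resolution(geom, 0.0, 15.0)
        assert res[2] == pytest.approx(np.sqrt(1.4**2 + 15.0**2), rel=1e-12)  # 15.065

    def test_defaults_reproduce_system_resolution(self):
        res = ms.elasticity_resolution(ms.AcquisitionGeometry(), 5.0, 15.0)
        assert res[0] == pytest.approx(5.0, rel=0.02)
        assert res[1] == pytest.approx(5.0, rel=0.02)
        assert res[2] == pytest.approx(15.1, rel=0.01)


def test_odd_size_helper():
    assert _odd_size(15.0, 2.0) == 9  # round(7.5) = 8 -> 9
    assert _odd_size(0.0, 2.0) == 1
    assert _odd_size(6.0, 2.0) == 3
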