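"""Transfer-matrix engine vs closed-form optics oracles and invariants."""

import numpy as np
import pytest

from tammsensor.materials import Material
from tammsensor.oracles import airy_reflectance, fresnel_rt, quarter_wave_dbr_reflectance
from tammsensor.stack import Layer, StackSpec, build_baseline
from tammsensor.tmm import (PlaneWave, angular_map, field_profile,
                            layer_matrix, rta, spectrum, transfer_matrix)


def _mat(n, k=0.0):
    return Material(f"n{n}", complex(n, k))


class TestFresnelOracle:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 60.0])
    @pytest.mark.parametrize("pol", ["TE", "TM"])
    def test_single_interface_matches_closed_form(self, theta, pol):
        st = StackSpec(_mat(1.0), (), _mat(1.5))
        R, T, A = rta(st, PlaneWave(800.0, theta, pol))
        R_ref, T_ref = fresnel_rt(1.0, 1.5, theta, pol)
        assert R == pytest.approx(R_ref, abs=1e-10)
        assert T == pytest.approx(T_ref, abs=1e-10)
        assert A == pytest.approx(0.0, abs=1e-10)

    def test_normal_incidence_glass_value(self, single_interface):
        R, T, A = rta(single_interface, PlaneWave(600.0))
        assert R == pytest.approx(0.04, abs=1e-10)
        assert T == pytest.approx(0.96, abs=1e-10)

    def test_total_internal_reflection_branch(self):
        # glass -> air beyond the critical angle (~41.8 deg): R = 1 exactly
        st = StackSpec(_mat(1.5), (), _mat(1.0))
        R, T, A = rta(st, PlaneWave(800.0, 60.0, "TE"))
        assert R == pytest.approx(1.0, abs=1e-10)
        assert T == pytest.approx(0.0, abs=1e-10)


class TestEtalonOracle:
    @pytest.mark.parametrize("pol", ["TE", "TM"])
    @pytest.mark.parametrize("theta", [0.0, 25.0])
    def test_airy_formula_across_a_free_spectral_range(self, pol, theta):
        st = StackSpec(_mat(1.0), (Layer(_mat(2.0), 150.0),), _mat(1.0))
        lam = np.linspace(500.0, 700.0, 301)
        sp = spectrum(st, lam, theta, pol)
        ref = airy_reflectance(1.0, 2.0, 1.0, 150.0, lam, theta, pol)
        assert np.max(np.abs(sp.R - ref)) < 1e-8

    def test_half_wave_resonance_unit_transmission(self):
        # symmetric lossless etalon at its half-wave point: T = 1
        st = StackSpec(_mat(1.0), (Layer(_mat(2.0), 150.0),), _mat(1.0))
        R, T, A = rta(st, PlaneWave(600.0))  # 2 n d = 600 nm
        assert T == pytest.approx(1.0, abs=1e-8)


class TestMatrixAlgebra:
    def test_pure_propagation_when_no_impedance_step(self):
        wave = PlaneWave(800.0)
        M = layer_matrix(2.25, 2.25, 120.0, wave)
        alpha = 2 * np.pi / 800.0 * 1.5
        assert M[0, 0] == pytest.approx(np.exp(-1j * alpha * 120.0), abs=1e-12)
        assert M[1, 1] == pytest.approx(np.exp(1j * alpha * 120.0), abs=1e-12)
        assert abs(M[0, 1]) < 1e-14 and abs(M[1, 0]) < 1e-14

    def test_pure_interface_form(self):
        M = layer_matrix(1.0, 2.25, 0.0, PlaneWave(800.0))
        assert np.allclose(M, 0.5 * np.array([[2.5, -0.5], [-0.5, 2.5]]),
                           atol=1e-12)

    def test_te_tm_matrices_reciprocal_h_at_normal_incidence(self):
        # the TM matrix follows from h -> 1/h; amplitudes differ but the
        # normal-incidence spectra must coincide (checked elsewhere)
        M_te = layer_matrix(1.0, 2.25, 0.0, PlaneWave(800.0, 0.0, "TE"))
        M_tm = layer_matrix(1.0, 2.25, 0.0, PlaneWave(800.0, 0.0, "TM"))
        assert M_te[0, 0] != pytest.approx(M_tm[0, 0])
        r_te = M_te[1, 0] / M_te[0, 0]
        r_tm = M_tm[1, 0] / M_tm[0, 0]
        assert abs(r_te) == pytest.approx(abs(r_tm), abs=1e-12)

    def test_group_property_layer_splitting(self):
        whole = StackSpec(_mat(1.0), (Layer(_mat(2.0), 300.0),), _mat(1.5))
        split = StackSpec(
            _mat(1.0),
            (Layer(_mat(2.0), 130.0), Layer(_mat(2.0), 170.0)),
            _mat(1.5),
        )
        wave = PlaneWave(780.0, 20.0, "TM")
        assert np.allclose(transfer_matrix(whole, wave),
                           transfer_matrix(split, wave), atol=1e-12)

    def test_identity_for_empty_stack_identical_media(self):
        st = StackSpec(_mat(1.5), (), _mat(1.5))
        assert np.allclose(transfer_matrix(st, PlaneWave(900.0)), np.eye(2),
                           atol=1e-14)

    def test_determinant_fixed_by_media_admittances(self, lib):
        # det of every interface factor is q_next/q_prev and propagation has
        # det 1, so det(M) telescopes to q_exit/q_incident -- independent of
        # the internal (lossless) layers and of wavelength for constant media
        st = StackSpec(
            _mat(1.0),
            (Layer(_mat(2.4), 80.0), Layer(_mat(1.47), 130.0),
             Layer(_mat(2.4), 80.0)),
            _mat(1.5),
        )
        dets = [np.linalg.det(transfer_matrix(st, PlaneWave(l)))
                for l in (700.0, 850.0, 1000.0)]
        assert np.allclose(dets, 1.5, atol=1e-10)


class TestEnergyAndReciprocity:
    def test_lossless_stack_absorbs_nothing(self):
        layers = tuple(
            Layer(_mat(n), d) for n, d in
            [(2.4, 79), (1.47, 129), (2.4, 81), (1.47, 131), (1.335, 1000)]
        )
        st = StackSpec(_mat(1.5), layers, _mat(1.5))
        lam = np.linspace(750.0, 1100.0, 200)
        sp = spectrum(st, lam, 15.0, "TM")
        assert np.max(np.abs(sp.A)) < 1e-10
        assert np.all(sp.R >= 0) and np.all(sp.R <= 1)
        assert np.all(sp.T >= 0) and np.all(sp.T <= 1)

    def test_transmittance_reciprocity_absorbing_stack(self, baseline_ag):
        rev = baseline_ag.reversed()
        for lam in (805.0, 900.0, 931.2, 1031.0):
            for pol in ("TE", "TM"):
                wave = PlaneWave(lam, 18.0, pol)
                assert rta(baseline_ag, wave)[1] == pytest.approx(
                    rta(rev, wave)[1], abs=1e-10
                )

    def test_te_tm_degenerate_at_normal_incidence(self, baseline_ag):
        lam = np.linspace(780.0, 1060.0, 120)
        te = spectrum(baseline_ag, lam, 0.0, "TE")
        tm = spectrum(baseline_ag, lam, 0.0, "TM")
        assert np.max(np.abs(te.R - tm.R)) < 1e-12
        assert np.max(np.abs(te.T - tm.T)) < 1e-12


class TestSpectrum:
    def test_three_deep_dips_in_bandgap(self, baseline_ag):
        lam = np.arange(750.0, 1100.0001, 0.1)
        sp = spectrum(baseline_ag, lam)
        from scipy.signal import find_peaks
        idx, props = find_peaks(-sp.R, prominence=0.15)
        assert len(idx) == 3

    def test_determinism(self, baseline_ag):
        lam = np.linspace(800.0, 1000.0, 50)
        a = spectrum(baseline_ag, lam)
        b = spectrum(baseline_ag, lam)
        assert np.array_equal(a.R, b.R) and np.array_equal(a.T, b.T)

    def test_single_point_grid_equals_rta(self, baseline_ag):
        sp = spectrum(baseline_ag, np.array([931.2]))
        R, T, A = rta(baseline_ag, PlaneWave(931.2))
        assert sp.R[0] == pytest.approx(R, abs=1e-14)
        assert sp.A[0] == pytest.approx(A, abs=1e-14)

    def test_rejects_bad_grid(self, baseline_ag):
        with pytest.raises(ValueError):
            spectrum(baseline_ag, np.array([900.0, 899.0]))

    def test_dbr_peak_reflectance_matches_closed_form(self):
        # lossless quarter-wave mirror at its design wavelength
        lam0, nH, nL, N = 900.0, 2.4, 1.47, 6
        layers = []
        for _ in range(N):
            layers += [Layer(_mat(nH), lam0 / (4 * nH)),
                       Layer(_mat(nL), lam0 / (4 * nL))]
        st = StackSpec(_mat(1.0), tuple(layers), _mat(1.5))
        R, _, _ = rta(st, PlaneWave(lam0))
        assert R == pytest.approx(
            quarter_wave_dbr_reflectance(1.0, nH, nL, 1.5, N), abs=1e-8
        )


class TestFieldProfile:
    def test_uniform_medium_unit_amplitude(self):
        st = StackSpec(_mat(1.5), (Layer(_mat(1.5), 400.0),), _mat(1.5))
        prof = field_profile(st, PlaneWave(900.0), 2.0)
        assert np.allclose(np.abs(prof.E), 1.0, atol=1e-12)

    def test_te_field_continuity_at_dielectric_interfaces(self):
        st = StackSpec(
            _mat(1.0),
            (Layer(_mat(2.4), 90.0), Layer(_mat(1.47), 150.0)),
            _mat(1.5),
        )
        prof = field_profile(st, PlaneWave(800.0, 10.0, "TE"), 0.05)
        for z0 in (0.0, 90.0, 240.0):
            near = np.abs(prof.z_nm - z0) < 0.6
            vals = prof.E[near]
            assert np.max(np.abs(np.diff(vals))) < 2e-2

    def test_cavity_mode_peaks_in_analyte(self, baseline_ag, baseline_modes):
        cav = [m for m in baseline_modes if m.label == "cavity"][0]
        prof = field_profile(baseline_ag, PlaneWave(cav.lambda0_nm), 2.0)
        lo, hi = baseline_ag.analyte_span_nm
        zmax = prof.z_nm[np.argmax(prof.intensity)]
        assert lo <= zmax <= hi

    def test_tamm_mode_peaks_at_first_metal_film(self, baseline_ag, baseline_modes):
        tpp1 = baseline_modes[0]
        prof = field_profile(baseline_ag, PlaneWave(tpp1.lambda0_nm), 2.0)
        metal_z = baseline_ag.boundaries_nm[12]  # PC1-side metal interface
        zmax = prof.z_nm[np.argmax(prof.intensity)]
        assert abs(zmax - metal_z) < 200.0


class TestAngularMap:
    def test_zero_angle_column_equals_normal_spectrum(self, baseline_ag):
        lam = np.linspace(800.0, 1000.0, 60)
        Rmap = angular_map(baseline_ag, lam, np.array([0.0, 12.0]), "TM")
        sp = spectrum(baseline_ag, lam, 0.0, "TM")
        assert np.allclose(Rmap[0], sp.R, atol=1e-14)

    def test_resonances_blueshift_with_angle(self, baseline_ag):
        from scipy.signal import find_peaks
        lam = np.arange(760.0, 1060.0001, 0.2)
        for pol in ("TE", "TM"):
            R0 = angular_map(baseline_ag, lam, np.array([0.0]), pol)[0]
            R20 = angular_map(baseline_ag, lam, np.array([20.0]), pol)[0]
            d0 = lam[find_peaks(-R0, prominence=0.1)[0]]
            d20 = lam[find_peaks(-R20, prominence=0.1)[0]]
            # every dip at 20 deg sits below its normal-incidence partner
            for d in d20[:3]:
                assert d < d0.max()
            assert d20.min() < d0.min()

    def test_te_dips_keep_contrast_no_brewster_window(self, baseline_ag):
        # the metal films suppress any Brewster-type contrast vanishing:
        # a deep dip survives at every probed angle
        lam = np.arange(700.0, 1050.0001, 0.25)
        thetas = np.array([10.0, 25.0, 40.0])
        Rmap = angular_map(baseline_ag, lam, thetas, "TE")
        for row in Rmap:
            assert row.min() < 0.5
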