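"""IR/Raman intensities, unit conversions, lineshapes, averaging."""

import math

import numpy as np
import pytest
import scipy.constants as sc
from conftest import random_rotation

from pespectra.constants import CM_TO_PER_METER
from pespectra.spectra import (
    RamanSettings,
    SpectrumGrid,
    average_spectra,
    cauchy_lineshape,
    default_grid,
    ir_epsilon,
    ir_mode_strength,
    ir_spectrum,
    raman_cross_section,
    raman_invariants,
)
from pespectra.units import (
    IR_UNIT_FACTORS,
    RAMAN_UNIT_FACTORS,
    convert_ir_units,
    convert_raman_units,
    ir_integrated_absorption_coefficient,
)


class TestUnitEngine:
    def test_dipole_strength_factor_matches_printed_value(self):
        """C²·kg⁻¹ → D²·Å⁻²·amu⁻¹ is 1.4924 × 10¹² to 5 significant figures."""
        factor = convert_ir_units(1.0, "C2/kg", "D2/(A2 amu)")
        assert factor == pytest.approx(1.4924e12, rel=5e-5)

    def test_raman_activity_factor_matches_printed_value(self):
        """C⁴·m²·J⁻²·kg⁻¹ → Å⁴·amu⁻¹ is 1.3413 × 10³³ to 5 significant figures."""
        factor = convert_raman_units(1.0, "C4 m2/(J2 kg)", "A4/amu")
        assert factor == pytest.approx(1.3413e33, rel=5e-5)

    def test_chain_identities(self):
        assert convert_ir_units(1.0, "m/mol", "km/mol") == pytest.approx(1e-3, rel=1e-14)
        assert convert_ir_units(1.0, "m2/mol", "L/(mol cm)") == pytest.approx(10.0, rel=1e-14)
        # napierian to decadic scale differs by ln 10
        assert convert_ir_units(1.0, "m/mol", "m2/mol") == pytest.approx(
            1.0 / math.log(10.0), rel=1e-14
        )

    def test_round_trips_are_identity(self):
        for a in IR_UNIT_FACTORS:
            for b in IR_UNIT_FACTORS:
                v = convert_ir_units(convert_ir_units(3.7, a, b), b, a)
                assert v == pytest.approx(3.7, rel=1e-12)
        for a in RAMAN_UNIT_FACTORS:
            for b in RAMAN_UNIT_FACTORS:
                v = convert_raman_units(convert_raman_units(0.2, a, b), b, a)
                assert v == pytest.approx(0.2, rel=1e-12)

    def test_raman_m4_per_kg_is_coulomb_constant_squared(self):
        k = 1.0 / (4 * np.pi * sc.epsilon_0)
        # scipy.constants tracks a newer CODATA release; agree to 1e-7
        assert convert_raman_units(1.0, "si", "m4/kg") == pytest.approx(
            k**2, rel=1e-7
        )

    def test_unknown_unit_is_an_error(self):
        with pytest.raises(ValueError, match="unknown unit"):
            convert_ir_units(1.0, "furlongs", "m/mol")


class TestCauchy:
    def test_half_maximum_at_gamma(self):
        gamma = 3.0
        center = 1000.0
        grid = np.array([center - gamma, center, center + gamma])
        f = cauchy_lineshape(grid, center, gamma)
        assert f[0] == pytest.approx(f[1] / 2, rel=1e-12)
        assert f[2] == pytest.approx(f[1] / 2, rel=1e-12)

    def test_peak_value_is_inverse_pi_gamma(self):
        gamma = 2.5
        f = cauchy_lineshape(np.array([500.0]), 500.0, gamma)
        assert f[0] == pytest.approx(1.0 / (np.pi * gamma), rel=1e-12)

    def test_normalization_over_wide_grid(self):
        gamma = 1.0
        grid = np.linspace(-600, 600, 240001) + 2000.0
        f = cauchy_lineshape(grid, 2000.0, gamma)
        assert np.trapezoid(f, grid) == pytest.approx(1.0, abs=1.5e-3)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            cauchy_lineshape(np.array([1.0]), 0.0, 0.0)


class TestIR:
    def test_mode_strength_sums_squared_components(self):
        g = np.array([[1.0, 0.0, 0.0], [0.3, -0.4, 1.2]])
        np.testing.assert_allclose(ir_mode_strength(g), [1.0, 1.69])

    def test_mode_strength_rotation_invariant(self, rng):
        g = rng.normal(size=(4, 3))
        base = ir_mode_strength(g)
        for _ in range(10):
            rot = random_rotation(rng)
            np.testing.assert_allclose(ir_mode_strength(g @ rot.T), base,
                                       rtol=1e-12)

    def test_band_integral_equals_napierian_over_ln10(self):
        mu_q, nu_i, gamma = 3e-13, 1500.0, 3.0
        grid = np.arange(nu_i - 900.0, nu_i + 900.0, 0.02)
        eps = ir_epsilon(mu_q, nu_i, gamma, grid)
        integral_per_m = np.trapezoid(eps, grid) * CM_TO_PER_METER
        a_i = ir_integrated_absorption_coefficient(mu_q)
        # wide Cauchy tails: grid spans ±300γ, capturing ~99.8% of the band
        assert integral_per_m == pytest.approx(a_i / math.log(10.0), rel=3e-3)

    def test_zero_strength_is_flat_zero(self):
        eps = ir_epsilon(0.0, 1000.0, 3.0, default_grid())
        assert np.all(eps == 0.0)

    def test_spectrum_unit_rescaling(self):
        nu = np.array([900.0, 1500.0])
        mq = np.array([1e-13, 2e-13])
        s1 = ir_spectrum(nu, mq, unit="m2/mol")
        s2 = ir_spectrum(nu, mq, unit="L/(mol cm)")
        np.testing.assert_allclose(s2.intensities, 10 * s1.intensities, rtol=1e-12)


class TestRamanInvariants:
    def test_isotropic_tensor(self):
        t = np.eye(3)[None] * 2.0
        a, b2 = raman_invariants(t)
        assert a[0] == pytest.approx(2.0)
        assert b2[0] == pytest.approx(0.0)

    def test_uniaxial_tensor(self):
        c = 1.7
        t = np.diag([c, 0.0, 0.0])[None]
        a, b2 = raman_invariants(t)
        assert a[0] == pytest.approx(c / 3)
        assert b2[0] == pytest.approx(c**2)

    def test_invariant_under_100_random_rotations(self, rng):
        t = rng.normal(size=(3, 3))
        t = 0.5 * (t + t.T)
        a0, b20 = raman_invariants(t[None])
        for _ in range(100):
            rot = random_rotation(rng)
            a, b2 = raman_invariants((rot @ t @ rot.T)[None])
            assert a[0] == pytest.approx(a0[0], abs=1e-10)
            assert b2[0] == pytest.approx(b20[0], abs=1e-10)

    def test_asymmetric_tensor_rejected(self):
        t = np.zeros((1, 3, 3))
        t[0, 0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            raman_invariants(t)


class TestRamanCrossSection:
    def test_boltzmann_factor_is_one_at_zero_temperature(self):
        s0 = raman_cross_section(1.0, 0.0, 1000.0,
                                 RamanSettings(temperature=0.0))
        st = raman_cross_section(1.0, 0.0, 1000.0,
                                 RamanSettings(temperature=298.0))
        assert st > s0  # thermal population only increases the Stokes signal

    def test_quartic_scaling_with_shifted_wavenumber(self):
        nu_i = 1000.0
        s1 = raman_cross_section(
            1.0, 0.0, nu_i,
            RamanSettings(incident_wavenumber=nu_i + 5000.0, temperature=0.0),
        )
        s2 = raman_cross_section(
            1.0, 0.0, nu_i,
            RamanSettings(incident_wavenumber=nu_i + 10000.0, temperature=0.0),
        )
        assert s2 == pytest.approx(16.0 * s1, rel=1e-12)

    def test_matches_independent_constant_chain(self):
        """b²=0, a=1: σ′ recomputed directly from scipy.constants."""
        nu_i_cm, t = 1200.0, 0.0
        settings = RamanSettings(incident_wavenumber=19435.0, temperature=t)
        ours = raman_cross_section(1.0, 0.0, nu_i_cm, settings)
        nu_i = nu_i_cm * 100.0
        nu_0 = 19435.0 * 100.0
        ref = (
            sc.h / (8 * sc.epsilon_0**2 * sc.c * nu_i)
            * (nu_0 - nu_i) ** 4
            * (45.0 * 1.0 + 7.0 * 0.0) / 45.0
        )
        # scipy.constants tracks a newer CODATA release; agree to 1e-7
        assert ours == pytest.approx(ref, rel=1e-7)

    def test_nonpositive_mode_wavenumber_rejected(self):
        with pytest.raises(ValueError):
            raman_cross_section(1.0, 0.0, -5.0)

    def test_anti_stokes_regime_warns(self):
        with pytest.warns(UserWarning, match="anti-Stokes"):
            raman_cross_section(
                1.0, 0.0, 2000.0, RamanSettings(incident_wavenumber=1000.0)
            )


class TestAveraging:
    def _single_peak(self, center, scale=1.0):
        grid = default_grid()
        return SpectrumGrid(
            wavenumbers=grid,
            intensities=scale * cauchy_lineshape(grid, center, 3.0),
            unit="m2/mol", kind="ir",
        )

    def test_identical_snapshots_average_to_themselves(self):
        s = self._single_peak(1500.0)
        avg = average_spectra([s, s, s])
        np.testing.assert_allclose(avg.intensities, s.intensities, rtol=1e-15)

    def test_single_snapshot_identity(self):
        s = self._single_peak(800.0)
        np.testing.assert_array_equal(average_spectra([s]).intensities,
                                      s.intensities)

    def test_two_disjoint_peaks_halve(self):
        s1, s2 = self._single_peak(1000.0), self._single_peak(3000.0)
        avg = average_spectra([s1, s2])
        i1000 = np.argmin(np.abs(avg.wavenumbers - 1000.0))
        # the far peak's Cauchy tail adds ~2e-6 relative at 2000 cm^-1 away
        assert avg.intensities[i1000] == pytest.approx(
            s1.intensities[i1000] / 2, rel=1e-4
        )

    def test_commutes_with_scalar_scaling(self):
        s1, s2 = self._single_peak(1000.0), self._single_peak(1400.0, 2.0)
        a1 = average_spectra([s1, s2])
        s1.intensities *= 3.0
        s2.intensities *= 3.0
        a2 = average_spectra([s1, s2])
        np.testing.assert_allclose(a2.intensities, 3.0 * a1.intensities,
                                   rtol=1e-14)

    def test_mismatched_grids_rejected(self):
        s1 = self._single_peak(1000.0)
        s2 = SpectrumGrid(wavenumbers=np.array([1.0, 2.0]),
                          intensities=np.zeros(2), unit="m2/mol", kind="ir")
        with pytest.raises(ValueError, match="grids"):
            average_spectra([s1, s2])
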