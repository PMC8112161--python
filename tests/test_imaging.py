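"""SNR, dose-for-SNR, MTF and energy selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ionct as ic

FIXED_RANGE = {r.ion: r for r in ic.load_fixture("fixed_range")}
FIXED_MTF = {r.ion: r for r in ic.load_fixture("fixed_mtf")}
SCENARIO = ic.ImagingScenario()


class TestSnr:
    def test_sqrt_particle_count_law(self):
        base = ic.ImagingScenario(n_detected=100)
        quad = ic.ImagingScenario(n_detected=400)
        a = ic.snr(base, 87.0, 2.0, ic.PROTON)
        b = ic.snr(quad, 87.0, 2.0, ic.PROTON)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_linear_pixel_size_law(self):
        a1 = ic.snr(ic.ImagingScenario(pixel_size=1.0), 87.0, 2.0, ic.PROTON)
        a2 = ic.snr(ic.ImagingScenario(pixel_size=2.0), 87.0, 2.0, ic.PROTON)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)

    def test_degenerate_noise_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ic.snr(SCENARIO, 87.0, 0.0, ic.PROTON)

    def test_proton_to_helium_snr_ratio_from_table(self):
        # at equal N_D the SNR ratio is the inverse sigma_WET ratio
        p, he = FIXED_RANGE["proton"], FIXED_RANGE["helium"]
        snr_p = ic.snr(SCENARIO, p.E_out, p.sigma_wet
                       * ic.stopping_power(p.E_out, ic.PROTON), ic.PROTON)
        snr_he = ic.snr(SCENARIO, he.E_out, he.sigma_wet
                        * ic.stopping_power(he.E_out, ic.HELIUM), ic.HELIUM)
        assert snr_p / snr_he == pytest.approx(
            he.sigma_wet / p.sigma_wet, rel=1e-9)


class TestDose:
    def test_quadratic_snr_law(self):
        nuc = FIXED_RANGE["proton"].nuclear_factors()
        d1 = ic.dose_for_snr(5.0, SCENARIO, 2.52, nuc)
        d2 = ic.dose_for_snr(10.0, SCENARIO, 2.52, nuc)
        assert d2 == pytest.approx(4.0 * d1, rel=1e-12)

    def test_inverse_fourth_power_pixel_law(self):
        nuc = FIXED_RANGE["proton"].nuclear_factors()
        d1 = ic.dose_for_snr(5.0, ic.ImagingScenario(pixel_size=1.0), 2.52, nuc)
        d2 = ic.dose_for_snr(5.0, ic.ImagingScenario(pixel_size=2.0), 2.52, nuc)
        assert d1 == pytest.approx(16.0 * d2, rel=1e-12)

    def test_nuclear_factors_never_defaulted(self):
        with pytest.raises((TypeError, ValueError)):
            ic.dose_for_snr(5.0, SCENARIO, 2.52, None)

    @pytest.mark.parametrize("ion,excess_pct", [
        ("helium", 36.0), ("lithium", 75.0), ("boron", 46.0), ("carbon", 40.0),
    ])
    def test_excess_dose_versus_proton(self, ion, excess_pct):
        # the D_c/SNR^2 ratio between ions cancels SNR, a and rho
        p = FIXED_RANGE["proton"]
        r = FIXED_RANGE[ion]
        d_p = ic.dose_for_snr(1.0, SCENARIO, p.sigma_wet, p.nuclear_factors())
        d_i = ic.dose_for_snr(1.0, SCENARIO, r.sigma_wet, r.nuclear_factors())
        assert 100.0 * (d_i / d_p - 1.0) == pytest.approx(excess_pct, abs=2.0)

    def test_fixed_mtf_scenario_orders_proton_worst_carbon_best(self):
        doses = {
            name: ic.dose_for_snr(1.0, SCENARIO, row.sigma_wet,
                                  row.nuclear_factors())
            for name, row in FIXED_MTF.items()
        }
        assert doses["proton"] == max(doses.values())
        assert doses["carbon"] == min(doses.values())

    def test_mgy_conversion(self):
        # 1 MeV/mm^3 per unit density = 1000 MeV/g = 1.602e-7 Gy
        assert ic.dose_in_mgy(1.0) == pytest.approx(1.602e-4, rel=1e-3)


class TestMtf:
    def test_unity_at_zero_frequency(self):
        for mode in ("scattering_only", "complete"):
            curve = ic.mtf([0.0], 0.6, pixel_size=0.25, mode=mode)
            assert curve.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_scattering_only_monotone_decreasing(self):
        curve = ic.mtf(np.linspace(0, 2, 50), 0.6)
        assert np.all(np.diff(curve.values) < 0)

    def test_closed_form_ten_percent_frequency(self):
        sigma = 0.6
        eps = ic.mtf10_closed_form(sigma)
        assert ic.mtf([eps], sigma).values[0] == pytest.approx(0.1, rel=1e-9)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            ic.mtf([-0.1], 0.6)

    @settings(max_examples=30, deadline=None)
    @given(sigma=st.floats(0.05, 1.0), a=st.floats(0.1, 1.0))
    def test_complete_mtf10_never_exceeds_nyquist(self, sigma, a):
        nyq = 0.5 / a

        def val(eps):
            return ic.mtf([eps], sigma, a, "complete").values[0]

        # at the Nyquist frequency the aliased replicas fold symmetrically;
        # above it the MTF cannot recover a crossing that matters
        freqs = np.linspace(0, nyq, 40)
        curve = [val(f) for f in freqs]
        crossing = freqs[np.argmax(np.array(curve) < 0.1)] if min(curve) < 0.1 else nyq
        assert crossing <= nyq + 1e-9


class TestMtf10:
    def test_proton_200mev_20cm_resolution(self):
        f, capped = ic.mtf10(200.0, ic.PROTON, 200.0)
        assert not capped
        assert f == pytest.approx(5.73, rel=0.10)

    def test_monotone_increasing_in_energy(self):
        f1 = ic.mtf10(200.0, ic.PROTON, 200.0)[0]
        f2 = ic.mtf10(300.0, ic.PROTON, 200.0)[0]
        f3 = ic.mtf10(400.0, ic.PROTON, 200.0)[0]
        assert f1 < f2 < f3

    def test_monotone_decreasing_in_thickness(self):
        f = [ic.mtf10(200.0, ic.PROTON, t)[0] for t in (100.0, 150.0, 200.0)]
        assert f[0] > f[1] > f[2]

    def test_complete_mode_capped_at_nyquist_for_sharp_beams(self):
        # carbon through 10 cm: the scattering blur alone would resolve
        # beyond the 0.25 mm pixel Nyquist of 20 lp/cm
        f, capped = ic.mtf10(386.9, ic.CARBON, 100.0, mode="complete",
                             pixel_size=0.25)
        assert capped and f == pytest.approx(20.0, rel=1e-6)

    def test_complete_mode_below_scattering_only(self):
        fs = ic.mtf10(350.0, ic.PROTON, 200.0)[0]
        fc, capped = ic.mtf10(350.0, ic.PROTON, 200.0, mode="complete",
                              pixel_size=0.25)
        assert not capped and fc < fs


class TestSelectEnergy:
    def test_fixed_range_matches_table_energy(self):
        sel = ic.select_energy(ic.PROTON, policy="fixed_range", R=260.0)
        assert sel.E_u == pytest.approx(200.0, rel=0.01)

    def test_fixed_mtf_proton_meets_target_unbound(self):
        sel = ic.select_energy(ic.PROTON, policy="fixed_mtf", mtf_target=10.0)
        assert not sel.bound_by_exit_energy
        assert sel.mtf10 == pytest.approx(10.0, abs=0.05)
        assert sel.E_u == pytest.approx(350.0, rel=0.10)
        assert sel.E_out_u > 70.0

    @pytest.mark.parametrize("ion_name", ["helium", "lithium", "boron", "carbon"])
    def test_fixed_mtf_heavier_ions_bind_at_exit_energy_floor(self, ion_name):
        sel = ic.select_energy(ic.get_ion(ion_name), policy="fixed_mtf",
                               mtf_target=10.0)
        assert sel.bound_by_exit_energy
        assert sel.mtf10 >= 10.0
        assert sel.E_out_u == pytest.approx(70.0, abs=0.5)
        assert sel.E_u == pytest.approx(FIXED_MTF[ion_name].E_init, rel=0.01)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            ic.select_energy(ic.PROTON, policy="fixed_dose")


class TestUncertainty:
    def test_binomial_variance(self):
        assert ic.binomial_variance(0.5) == 0.25
        assert ic.binomial_variance(0.0) == 0.0
        with pytest.raises(ValueError):
            ic.binomial_variance(1.5)

    def test_zero_inputs_zero_uncertainty(self):
        nuc = ic.NuclearFactors(1.12, 1.08, 1.13)
        assert ic.propagate_dose_uncertainty(10.0, 2.52, 0.0, nuc) == 0.0

    def test_single_factor_log_derivative(self):
        nuc = ic.NuclearFactors(1.12, 1.08, 1.13, sigma_g_ph=0.10)
        sd = ic.propagate_dose_uncertainty(10.0, 2.52, 0.0, nuc)
        assert sd / 10.0 == pytest.approx(0.10 / 1.12, rel=1e-12)

    def test_full_proton_row_matches_hand_quadrature(self):
        row = FIXED_RANGE["proton"]
        nuc = row.nuclear_factors()
        d = ic.dose_for_snr(5.0, SCENARIO, row.sigma_wet, nuc)
        sd = ic.propagate_dose_uncertainty(d, row.sigma_wet,
                                           row.sigma_wet_err, nuc)
        expected_rel = np.sqrt(
            (2 * 0.10 / 2.52) ** 2 + (0.10 / 1.12) ** 2
            + (0.07 / 1.08) ** 2 + (0.05 / 1.13) ** 2)
        assert sd / d == pytest.approx(expected_rel, rel=1e-9)
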