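"""Radiative-transfer contracts: energy conservation, monotonicity,
xanthophyll locality, fluorescence linearity and the photon budget."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafvcmax.errors import DomainError, GridError
from leafvcmax.leaf_rt import (
    LeafOpticalParams,
    build_absorption,
    simulate_fluorescence,
    simulate_rt,
    tav,
)
from leafvcmax.coupling import scale_incident_to_ipar
from leafvcmax.spectra import Spectrum

EMPTY = dict(cab=0, ccar=0, cant=0, cw=0, cdm=0, cs=0, cx=0)


class TestAbsorptionMixing:
    def test_empty_leaf_has_zero_absorption(self, sacs):
        k = build_absorption(LeafOpticalParams(**EMPTY, eta=0), sacs)
        assert np.all(k.values == 0.0)

    def test_cx_zero_matches_static_sum(self, sacs, default_optics):
        k0 = build_absorption(default_optics.replace(cx=0.0), sacs)
        manual = (
            default_optics.cab * sacs.cab
            + default_optics.ccar * sacs.ccar
            + default_optics.cant * sacs.cant
            + default_optics.cw * sacs.cw
            + default_optics.cdm * sacs.cdm
            + default_optics.cs * sacs.cs
        ) / default_optics.n_layers
        np.testing.assert_allclose(k0.values, manual, rtol=1e-12)

    def test_mixing_rule_is_linear_in_cab(self, sacs):
        base = LeafOpticalParams(**EMPTY)
        k1 = build_absorption(base.replace(cab=20.0), sacs).values
        k2 = build_absorption(base.replace(cab=40.0), sacs).values
        np.testing.assert_allclose(k2, 2.0 * k1, rtol=1e-12, atol=1e-300)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            LeafOpticalParams(cab=-1.0)


class TestPlateModel:
    def test_interface_transmissivity_bounds(self, sacs):
        for arr in (sacs.t_alpha, sacs.t12, sacs.t21):
            assert np.all(arr > 0) and np.all(arr < 1)
        # normal-incidence limit matches the Fresnel closed form
        n = np.array([1.5])
        t0 = tav(1e-9, n)
        assert t0[0] == pytest.approx(1 - ((1.5 - 1) / (1.5 + 1)) ** 2, abs=1e-9)

    def test_empty_leaf_conserves_energy(self, sacs):
        rho, tau = simulate_rt(LeafOpticalParams(**EMPTY, eta=0), sacs)
        np.testing.assert_allclose(rho.values + tau.values, 1.0, atol=1e-6)

    def test_passive_medium(self, sacs, default_optics):
        rho, tau = simulate_rt(default_optics, sacs)
        total = rho.values + tau.values
        assert np.all(total <= 1.0 + 1e-12)
        assert np.all(rho.values >= 0) and np.all(tau.values >= 0)

    def test_structure_parameter_raises_nir_reflectance(self, sacs,
                                                        default_optics):
        """More plates -> more internal interfaces -> brighter NIR rho,
        dimmer tau (checked pointwise over 800-1300 nm)."""
        rho1, tau1 = simulate_rt(default_optics.replace(n_layers=1.0), sacs)
        rho3, tau3 = simulate_rt(default_optics.replace(n_layers=3.0), sacs)
        sel = (sacs.wavelengths >= 800) & (sacs.wavelengths <= 1300)
        assert np.all(rho3.values[sel] > rho1.values[sel])
        assert np.all(tau3.values[sel] < tau1.values[sel])

    def test_chlorophyll_darkens_red_transmittance(self, sacs,
                                                   default_optics):
        _, tau_lo = simulate_rt(default_optics.replace(cab=30.0), sacs)
        _, tau_hi = simulate_rt(default_optics.replace(cab=60.0), sacs)
        assert tau_hi.value_at(680) < tau_lo.value_at(680)

    def test_cx_acts_only_in_green_window(self, sacs, default_optics):
        rho0, tau0 = simulate_rt(default_optics.replace(cx=0.0), sacs)
        rho1, tau1 = simulate_rt(default_optics.replace(cx=1.0), sacs)
        outside = (sacs.wavelengths < 500) | (sacs.wavelengths > 570)
        np.testing.assert_allclose(rho1.values[outside], rho0.values[outside],
                                   atol=1e-12)
        np.testing.assert_allclose(tau1.values[outside], tau0.values[outside],
                                   atol=1e-12)
        inside = (sacs.wavelengths >= 510) & (sacs.wavelengths <= 545)
        assert np.all(rho1.values[inside] < rho0.values[inside])
        assert np.all(tau1.values[inside] < tau0.values[inside])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        cab=st.floats(0, 100), ccar=st.floats(0, 30), cw=st.floats(0, 0.4),
        cdm=st.floats(0, 0.5), n_layers=st.floats(1, 4), cx=st.floats(0, 1.5),
    )
    def test_energy_conservation_property(self, sacs, cab, ccar, cw, cdm,
                                          n_layers, cx):
        p = LeafOpticalParams(cab=cab, ccar=ccar, cant=0, cw=cw, cdm=cdm,
                              n_layers=n_layers, cs=0, cx=cx)
        rho, tau = simulate_rt(p, sacs)
        total = rho.values + tau.values
        assert np.all(total <= 1.0 + 1e-9)
        assert np.all((rho.values >= 0) & (tau.values >= 0))


class TestFluorescence:
    def test_zero_efficiency_means_no_emission(self, sacs, lamp,
                                               default_optics):
        inc = scale_incident_to_ipar(lamp, 1000.0)
        cb, cf = simulate_fluorescence(default_optics.replace(eta=0.0),
                                       sacs, inc)
        assert np.all(cb.values == 0.0) and np.all(cf.values == 0.0)

    def test_no_excitation_above_750(self, sacs, lamp, default_optics):
        wl = lamp.wavelengths
        nir_only = Spectrum(wl, np.where(wl > 750, lamp.values, 0.0))
        cb, cf = simulate_fluorescence(default_optics, sacs, nir_only)
        assert np.all(cb.values == 0.0) and np.all(cf.values == 0.0)

    def test_linear_in_eta(self, sacs, lamp, default_optics):
        inc = scale_incident_to_ipar(lamp, 800.0)
        cb1, cf1 = simulate_fluorescence(default_optics.replace(eta=0.01),
                                         sacs, inc)
        cb2, cf2 = simulate_fluorescence(default_optics.replace(eta=0.02),
                                         sacs, inc)
        np.testing.assert_array_equal(cb2.values, 2.0 * cb1.values)
        np.testing.assert_array_equal(cf2.values, 2.0 * cf1.values)

    def test_doubling_resolution_converged(self, sacs, lamp, default_optics):
        inc = scale_incident_to_ipar(lamp, 1000.0)
        cb6, cf6 = simulate_fluorescence(default_optics, sacs, inc,
                                         doubling_levels=6)
        cb7, cf7 = simulate_fluorescence(default_optics, sacs, inc,
                                         doubling_levels=7)
        for a, b in ((cb6, cb7), (cf6, cf7)):
            rel = np.abs(b.values - a.values) / np.maximum(a.values, 1e-30)
            assert rel.max() < 1e-3

    def test_incident_not_covering_excitation_raises(self, sacs,
                                                     default_optics):
        narrow = Spectrum(np.arange(500.0, 751.0), np.ones(251))
        with pytest.raises(GridError):
            simulate_fluorescence(default_optics, sacs, narrow)

    def test_photon_budget(self, sacs, lamp, default_optics):
        """Total emitted quanta cannot exceed eta times the quanta absorbed
        by chlorophyll, computed by an independent dense integration of the
        excitation flux profile."""
        inc = scale_incident_to_ipar(lamp, 1000.0)
        cb, cf = simulate_fluorescence(default_optics, sacs, inc)
        emitted = cb.integral() + cf.integral()

        # independent oracle: Riemann integration of the two-bounce-series
        # flux profile on a much finer grid
        p = default_optics
        exc = (sacs.wavelengths >= 400) & (sacs.wavelengths <= 750)
        wl_e = sacs.wavelengths[exc]
        flux = np.interp(wl_e, lamp.wavelengths, inc.values)
        ktot = (
            p.cab * sacs.cab + p.ccar * sacs.ccar + p.cant * sacs.cant
            + p.cw * sacs.cw + p.cdm * sacs.cdm + p.cs * sacs.cs
            + p.cx * sacs.cx_band
        )[exc]
        fcab = np.where(ktot > 0, p.cab * sacs.cab[exc] / np.maximum(ktot, 1e-300), 0.0)
        r21 = sacs.r21[exc]
        talf = sacs.t_alpha[exc]
        m = 4096
        z = np.linspace(0.0, 1.0, m + 1)[:, None]
        a_full = np.exp(-2.0 * ktot)
        denom = 1.0 - (r21 * a_full) ** 2
        d = talf * np.exp(-2.0 * ktot * z) / denom
        u = talf * r21 * a_full * np.exp(-2.0 * ktot * (1.0 - z)) / denom
        absorbed = (d[0] - d[-1]) + (u[-1] - u[0])  # total absorbed per unit
        absorbed_by_cab = float(np.sum(fcab * absorbed * flux))
        assert emitted <= p.eta * absorbed_by_cab * (1.0 + 1e-9)
        assert emitted > 0.0
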