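"""Inversion contracts: cost bookkeeping, noiseless self-inversion of all
three retrieval methods and the static-optics fit, and the degenerate-input
behaviour (bounds, identifiability flags)."""

import numpy as np
import pytest

from conftest import make_noiseless_dataset
from leafvcmax.biochem import BiochemParams, Forcing
from leafvcmax.errors import DataError, InsufficientDataError
from leafvcmax.leaf_rt import LeafOpticalParams, simulate_rt
from leafvcmax.retrieval import (
    Method3Problem,
    PAMRecord,
    ResponseCurveDataset,
    cost_residuals,
    retrieve_method1,
    retrieve_method2,
    retrieve_method3,
    retrieve_static_optics,
)
from leafvcmax.spectra import Spectrum


class TestCostResiduals:
    def test_identical_inputs_cost_zero(self):
        r, c = cost_residuals([1.0, 2.0], [1.0, 2.0])
        assert c == 0.0 and np.all(r == 0.0)

    def test_arithmetic(self):
        _, c = cost_residuals([1.0, 2.0], [0.0, 0.0])
        assert c == 5.0

    def test_matrices_flatten(self):
        m = np.arange(6.0).reshape(2, 3)
        r, c = cost_residuals(m, np.zeros((2, 3)))
        assert r.shape == (6,)
        assert c == pytest.approx(np.sum(m**2))

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            cost_residuals([1.0], [1.0, 2.0])


class TestMethod1:
    def test_noiseless_self_inversion(self, light_dataset):
        r = retrieve_method1(light_dataset)
        assert r["vcmax"] == pytest.approx(85.0, abs=0.5)
        assert r.cost <= r.cost_initial

    def test_light_and_co2_curves_agree(self, light_dataset, co2_dataset):
        v_light = retrieve_method1(light_dataset)["vcmax"]
        v_co2 = retrieve_method1(co2_dataset)["vcmax"]
        assert v_co2 == pytest.approx(v_light, rel=0.01)

    def test_all_zero_assimilation_hits_lower_bound(self, light_dataset):
        ds = ResponseCurveDataset(
            kind=light_dataset.kind, steps=light_dataset.steps,
            a_meas=np.zeros(len(light_dataset.steps)),
        )
        r = retrieve_method1(ds)
        assert r["vcmax"] <= 1e-3
        assert "vcmax_at_lower_bound" in r.flags

    def test_too_few_points_rejected(self):
        ds = ResponseCurveDataset(
            kind="light", steps=[Forcing(ipar=v) for v in (0, 100, 500)],
            a_meas=np.array([0.0, 1.0, 2.0]),
        )
        with pytest.raises(InsufficientDataError):
            retrieve_method1(ds)


class TestMethod2:
    def test_noiseless_self_inversion(self, light_dataset):
        r = retrieve_method2(light_dataset)
        assert r["vcmax"] == pytest.approx(85.0, rel=0.02)
        assert r["kn0"] == pytest.approx(3.0, rel=0.05)

    def test_optimum_reproduces_npq_plateau(self, light_dataset):
        r = retrieve_method2(light_dataset)
        b = BiochemParams(vcmax=r["vcmax"], kn0=r["kn0"], beta=r["beta"],
                          gamma=r["gamma"])
        from leafvcmax.biochem import solve_photosynthesis

        pam = light_dataset.pam
        npq_meas = (pam.fm_dark - pam.fm_prime) / pam.fm_prime
        top = np.argmax([f.ipar for f in light_dataset.steps])
        npq_sim = solve_photosynthesis(b, light_dataset.steps[top]).npq
        assert npq_sim == pytest.approx(npq_meas[top], rel=0.02)

    def test_flat_npq_makes_kn0_unidentifiable(self):
        """With NPQ constant at zero (no quenching ever engaged), Kn0 has
        no leverage; the fit must report it, not fail."""
        steps = [Forcing(ipar=v) for v in (0, 20, 40, 60, 80)]
        b = BiochemParams()
        fo, fm = 0.01, 0.05
        pam = PAMRecord(
            fs=np.full(5, fo), fm_prime=np.full(5, fm),
            fo_dark=fo, fm_dark=fm,
        )
        ds = ResponseCurveDataset(kind="light", steps=steps, pam=pam)
        r = retrieve_method2(ds)
        width = r.bounds["kn0"][1] - r.bounds["kn0"][0]
        assert (
            r.sigma_p.get("kn0", np.inf) > width
            or any("kn0" in f or "singular" in f for f in r.flags)
        )

    def test_missing_dark_reference_rejected(self, light_dataset):
        pam = PAMRecord(fs=light_dataset.pam.fs,
                        fm_prime=light_dataset.pam.fm_prime,
                        fo_dark=0.0, fm_dark=0.05)
        ds = ResponseCurveDataset(kind="light", steps=light_dataset.steps,
                                  pam=pam)
        with pytest.raises(DataError):
            retrieve_method2(ds)


class TestStaticOptics:
    def test_noiseless_identifiability(self, sacs, interior_optics):
        rho, tau = simulate_rt(interior_optics.replace(cx=0.0), sacs)
        optics, r = retrieve_static_optics(rho=rho, tau=tau, sacs=sacs)
        for name in ("cab", "ccar", "cant", "cw", "cdm", "n_layers", "cs"):
            assert getattr(optics, name) == pytest.approx(
                getattr(interior_optics, name), rel=0.01
            ), name

    def test_tau_only_recovers_water_and_dry_matter(self, sacs,
                                                    interior_optics):
        _, tau = simulate_rt(interior_optics.replace(cx=0.0), sacs)
        optics, _ = retrieve_static_optics(tau=tau, sacs=sacs)
        assert optics.cw == pytest.approx(interior_optics.cw, rel=0.05)
        assert optics.cdm == pytest.approx(interior_optics.cdm, rel=0.05)

    def test_unphysical_flat_spectrum_flagged(self, sacs):
        ones = Spectrum(sacs.wavelengths, np.ones_like(sacs.wavelengths))
        _, r = retrieve_static_optics(tau=ones, sacs=sacs)
        assert "large_residual" in r.flags or any(
            "bound" in f for f in r.flags
        )

    def test_out_of_range_spectrum_rejected(self, sacs):
        bad = Spectrum(sacs.wavelengths,
                       np.full_like(sacs.wavelengths, 1.5))
        with pytest.raises(DataError):
            retrieve_static_optics(tau=bad, sacs=sacs)


class TestMethod3:
    def test_residual_zero_at_generating_parameters(self, light_dataset,
                                                    sacs, lamp,
                                                    interior_optics):
        prob = Method3Problem(light_dataset, interior_optics, lamp, sacs,
                              mode="forward")
        r = prob.residual([85.0, 3.0, 0.01])
        assert np.abs(r).max() < 1e-10

    def test_noiseless_self_inversion(self, light_dataset, sacs, lamp,
                                      interior_optics):
        r = retrieve_method3(light_dataset, interior_optics, lamp, sacs,
                             mode="forward")
        assert r["vcmax"] == pytest.approx(85.0, rel=0.02)
        assert r["kn0"] == pytest.approx(3.0, rel=0.02)
        assert r["sigma_scale"] == pytest.approx(0.01, rel=0.02)
        assert r.cost <= r.cost_initial

    def test_forward_backward_modes_agree(self, light_dataset, sacs, lamp,
                                          interior_optics):
        v_f = retrieve_method3(light_dataset, interior_optics, lamp, sacs,
                               mode="forward")["vcmax"]
        v_b = retrieve_method3(light_dataset, interior_optics, lamp, sacs,
                               mode="backward")["vcmax"]
        assert v_b == pytest.approx(v_f, rel=0.05)

    def test_missing_spectra_rejected(self, light_dataset, sacs, lamp,
                                      interior_optics):
        ds = ResponseCurveDataset(kind="light", steps=light_dataset.steps,
                                  a_meas=light_dataset.a_meas)
        with pytest.raises(DataError):
            retrieve_method3(ds, interior_optics, lamp, sacs)
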