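"""Synthetic fixtures: SAC sets, lamp spectra, protocols and full datasets.

Everything the pipeline needs to run and be tested is generated here with
known ground truth.  The SAC fixture places Gaussian absorption bands at
physically plausible positions (chlorophyll ~430/680 nm, carotenoids
450-500 nm, anthocyanins ~540 nm, water 970/1200/1450/1940 nm, dry matter
in the SWIR, a broad brown-pigment tail, and the differential xanthophyll
band confined to 500-570 nm); the emission shape is the typical double
peak near 685 and 740 nm, normalized to unit integral.

The measurement protocols are the chamber sequences: a 10-step light
curve (0, 50, 100, 150, 250, 350, 500, 700, 1000, 1300 umol m-2 s-1 at
400 ppm CO2) and a 12-step CO2 curve (400, 50, 100, 150, 250, 350, 500,
700, 900, 1200, 700, 400 ppm at 1000 umol m-2 s-1).  Default noise:
1% multiplicative Gaussian on spectra, 2% on assimilation and on PAM
yields.  True Vcmax values are drawn from U(50, 100) umol m-2 s-1, the
span the retrieval is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biochem import BiochemParams, Forcing
from .coupling import CouplingParams, forward_coupled
from .errors import DomainError
from .leaf_rt import LeafOpticalParams, SACSet, simulate_rt
from .retrieval import PAMRecord, ResponseCurveDataset, StepSpectra
from .spectra import GRID_FULL, Spectrum

__all__ = [
    "Protocol",
    "SyntheticTruth",
    "LIGHT_SEQUENCE",
    "CO2_SEQUENCE",
    "make_sac_fixture",
    "make_lamp_spectrum",
    "make_protocol",
    "sample_truth",
    "simulate_dataset",
]

LIGHT_SEQUENCE = (0.0, 50.0, 100.0, 150.0, 250.0, 350.0, 500.0, 700.0, 1000.0, 1300.0)
CO2_SEQUENCE = (400.0, 50.0, 100.0, 150.0, 250.0, 350.0, 500.0, 700.0, 900.0, 1200.0, 700.0, 400.0)

DEFAULT_NOISE = {"spectra": 0.01, "a": 0.02, "pam": 0.02}


@dataclass(frozen=True)
class Protocol:
    """An ordered sequence of forcing steps of one response-curve kind."""

    kind: str  # 'light' | 'co2'
    steps: tuple

    def __post_init__(self):
        if self.kind not in ("light", "co2"):
            raise DomainError(f"unknown protocol kind '{self.kind}'")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one synthetic leaf plus the noise model."""

    optical: LeafOpticalParams
    biochem: BiochemParams
    coupling: CouplingParams
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0


def _gauss(wl, center, sigma, amp):
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def make_sac_fixture(seed: int = 0) -> SACSet:
    """Deterministic Gaussian-band SAC fixture on the 1 nm 400-2500 grid.

    The fixture is a fully deterministic function of ``seed`` (and is in
    fact seed-independent: the band positions and amplitudes are fixed
    design constants, so any seed returns the identical set).
    """
    wl = GRID_FULL.copy()

    cab = _gauss(wl, 430.0, 30.0, 0.05) + _gauss(wl, 680.0, 22.0, 0.042)
    ccar = _gauss(wl, 450.0, 18.0, 0.028) + _gauss(wl, 485.0, 16.0, 0.022)
    cant = _gauss(wl, 540.0, 28.0, 0.02)
    cw = (
        _gauss(wl, 970.0, 35.0, 3.0)
        + _gauss(wl, 1200.0, 45.0, 10.0)
        + _gauss(wl, 1450.0, 45.0, 120.0)
        + _gauss(wl, 1940.0, 60.0, 300.0)
        + _gauss(wl, 2500.0, 120.0, 150.0)
    )
    cdm = np.where(
        wl >= 800.0,
        _gauss(wl, 1720.0, 60.0, 30.0)
        + _gauss(wl, 2100.0, 80.0, 55.0)
        + _gauss(wl, 2300.0, 60.0, 45.0)
        + 5.0 * (1.0 - np.exp(-(wl - 800.0) / 700.0)),
        0.0,
    )
    cs = 2.0 * np.exp(-(wl - 400.0) / 250.0)

    cx_band = _gauss(wl, 525.0, 12.0, 0.1)
    cx_band[(wl < 500.0) | (wl > 570.0)] = 0.0

    refractive = 1.52 - 0.15 * (wl - 400.0) / 2100.0

    phi = _gauss(wl, 685.0, 10.0, 0.6) + _gauss(wl, 740.0, 34.0, 1.0)
    phi[(wl < 640.0) | (wl > 850.0)] = 0.0
    emis = (wl >= 640.0) & (wl <= 850.0)
    phi /= np.trapezoid(phi[emis], wl[emis])

    return SACSet(wl, cab, ccar, cant, cw, cdm, cs, cx_band, refractive, phi)


def make_lamp_spectrum(filtered: bool = False, temperature_k: float = 3200.0) -> Spectrum:
    """Smooth halogen-like lamp spectrum in quanta units on 400-2500 nm.

    A Planck curve at ``temperature_k`` converted from energy to quanta
    (multiplied by wavelength), normalized so the 400-700 nm quanta
    integral equals 1 (rescale with
    :func:`~leafvcmax.coupling.scale_incident_to_ipar`).  With
    ``filtered=True``, a short-pass cut at 700 nm emulates the chamber
    filter used for fluorescence measurements.
    """
    wl = GRID_FULL.copy()
    wl_m = wl * 1e-9
    h, c, kb = 6.626e-34, 2.998e8, 1.381e-23
    planck = 1.0 / (wl_m**5 * (np.expm1(h * c / (wl_m * kb * temperature_k))))
    quanta = planck * wl_m
    quanta = quanta / np.max(quanta)
    if filtered:
        quanta = np.where(wl > 700.0, 0.0, quanta)
    s = Spectrum(wl, quanta)
    par = s.integral(400.0, 700.0)
    return s.scaled(1.0 / par)


def make_protocol(kind: str, steps=None, t_leaf: float = 25.0, rh: float = 0.6) -> Protocol:
    """Chamber measurement protocol ('light' or 'co2'), or a custom sequence."""
    if kind == "light":
        seq = LIGHT_SEQUENCE if steps is None else tuple(steps)
        forcings = tuple(
            Forcing(ipar=v, t_leaf=t_leaf, cs_air=400.0, rh=rh) for v in seq
        )
    elif kind == "co2":
        seq = CO2_SEQUENCE if steps is None else tuple(steps)
        forcings = tuple(
            Forcing(ipar=1000.0, t_leaf=t_leaf, cs_air=v, rh=rh) for v in seq
        )
    else:
        raise DomainError(f"unknown protocol kind '{kind}'")
    return Protocol(kind=kind, steps=forcings)


def sample_truth(
    seed: int,
    vcmax_range: tuple = (50.0, 100.0),
    noise: dict | None = None,
) -> SyntheticTruth:
    """Draw one synthetic leaf: random optics and Vcmax, standard coupling."""
    rng = np.random.default_rng(seed)
    optical = LeafOpticalParams(
        cab=rng.uniform(30.0, 60.0),
        ccar=rng.uniform(5.0, 15.0),
        cant=0.0,
        cw=rng.uniform(0.005, 0.02),
        cdm=rng.uniform(0.008, 0.02),
        n_layers=rng.uniform(1.2, 2.0),
        cs=0.0,
    )
    biochem = BiochemParams(vcmax=rng.uniform(*vcmax_range))
    return SyntheticTruth(
        optical=optical,
        biochem=biochem,
        coupling=CouplingParams(),
        noise=dict(DEFAULT_NOISE if noise is None else noise),
        seed=seed,
    )


def _noisy_spectrum(s: Spectrum, sd: float, rng) -> Spectrum:
    if sd <= 0:
        return s
    factor = 1.0 + sd * rng.standard_normal(len(s))
    return Spectrum(s.wavelengths, np.maximum(s.values * factor, 0.0))


def simulate_dataset(
    truth: SyntheticTruth,
    protocol: Protocol,
    incident: Spectrum,
    sacs: SACSet,
    doubling_levels: int = 6,
) -> ResponseCurveDataset:
    """Emulate one chamber response-curve measurement with known truth.

    Runs the coupled forward model along the protocol, then applies
    per-block multiplicative Gaussian noise (``truth.noise``): spectra,
    assimilation, and PAM yields.  The reference spectrum pair for the
    static-optics retrieval is the dark-adapted leaf (Cx = 0,
    eta = sigma_scale, i.e. epsilon = 1), as measured before a light
    curve.  The truth is recorded on the dataset for recovery tests.
    """
    rng = np.random.default_rng(truth.seed)
    points = forward_coupled(
        truth.optical, truth.biochem, truth.coupling, protocol.steps,
        incident, sacs, doubling_levels=doubling_levels,
    )
    sd_spec = truth.noise.get("spectra", 0.0)
    sd_a = truth.noise.get("a", 0.0)
    sd_pam = truth.noise.get("pam", 0.0)

    a_meas = np.array(
        [p.state.a * (1.0 + sd_a * rng.standard_normal()) for p in points]
    )
    fs = np.array(
        [p.state.fs * (1.0 + sd_pam * rng.standard_normal()) for p in points]
    )
    fm_prime = np.array(
        [p.state.fm_prime * (1.0 + sd_pam * rng.standard_normal()) for p in points]
    )
    dark = points[0].state  # yields fo/fm are forcing-independent constants
    pam = PAMRecord(
        fs=fs,
        fm_prime=fm_prime,
        fo_dark=dark.fo * (1.0 + sd_pam * rng.standard_normal()),
        fm_dark=dark.fm * (1.0 + sd_pam * rng.standard_normal()),
    )
    spectra = [
        StepSpectra(
            rho=_noisy_spectrum(p.rho, sd_spec, rng),
            tau=_noisy_spectrum(p.tau, sd_spec, rng),
            chlf_forward=_noisy_spectrum(p.chlf_forward, sd_spec, rng),
            chlf_backward=_noisy_spectrum(p.chlf_backward, sd_spec, rng),
        )
        for p in points
    ]

    dark_optics = truth.optical.replace(
        cx=0.0, eta=truth.coupling.sigma_scale
    )
    rho0, tau0 = simulate_rt(dark_optics, sacs)
    ref_rho = _noisy_spectrum(rho0, sd_spec, rng)
    ref_tau = _noisy_spectrum(tau0, sd_spec, rng)

    return ResponseCurveDataset(
        kind=protocol.kind,
        steps=list(protocol.steps),
        a_meas=a_meas,
        pam=pam,
        spectra=spectra,
        reference_rho=ref_rho,
        reference_tau=ref_tau,
        truth=truth,
    )
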