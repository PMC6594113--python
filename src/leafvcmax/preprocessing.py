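"""Convert raw radiance measurements into spectra and derived observables.

The chamber protocol records, per step, the leaf radiance with and
without a short-pass filter in front of the lamp, plus white-reference
(panel) radiances of the unfiltered and filtered lamp.  Transmittance (or
reflectance) is the ratio of leaf to incident radiance; chlorophyll
fluorescence is the filtered leaf radiance minus the leakage of filtered
incident light through (or off) the leaf:

    ChlF(l) = L_leaf_filtered(l) - (rho_or_tau)(l) * L_incident_filtered(l)

evaluated on 640-850 nm and floored at zero.  Also computed here: the
photochemical reflectance index PRI = (R531 - R570)/(R531 + R570), its
curve-normalized form dPRI, the far-red fluorescence F740 and dF740, PAM
derivatives (PhiPSII, NPQ, ETR) and light-use efficiency LUE = A/iPAR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError
from .spectra import Spectrum, require_same_grid

__all__ = [
    "RadianceSet",
    "DerivedIndices",
    "radiance_to_spectra",
    "spectral_indices",
    "pam_derive",
    "lue",
]

logger = logging.getLogger(__name__)

#: PRI band positions [nm] and the far-red fluorescence band.
PRI_BANDS = (531.0, 570.0)
F740_WL = 740.0
#: PSII partitioning factor and leaf absorptance used in ETR.
ETR_PSII_FRACTION = 0.5
ETR_ABSORPTANCE = 0.84


@dataclass
class RadianceSet:
    """Radiances of one measurement step.

    geometry is 'transmitted' (chamber: fibre below the leaf) or
    'reflected' (leaf clip).  Filtered radiances are taken with the
    short-pass filter slotted in front of the lamp.
    """

    l_incident: Spectrum
    l_incident_filtered: Spectrum
    l_leaf: Spectrum
    l_leaf_filtered: Spectrum
    geometry: str = "transmitted"

    def __post_init__(self):
        if self.geometry not in ("transmitted", "reflected"):
            raise DomainError(f"unknown geometry '{self.geometry}'")
        require_same_grid(
            self.l_incident, self.l_incident_filtered,
            self.l_leaf, self.l_leaf_filtered,
        )
        for name in ("l_incident", "l_incident_filtered", "l_leaf",
                     "l_leaf_filtered"):
            if np.any(getattr(self, name).values < 0):
                raise DataError(f"{name} has negative radiance")


@dataclass
class DerivedIndices:
    """Per-step derived observables."""

    pri: float
    delta_pri: float
    f740: float
    delta_f740: float
    lue: float | None = None


def radiance_to_spectra(
    rs: RadianceSet,
    leakage_correction: bool = True,
) -> tuple[Spectrum, Spectrum]:
    """Transmittance (or reflectance) and leakage-corrected ChlF.

    Returns ``(rho_or_tau, chlf)``; the ratio spectrum lives on the full
    input grid clipped to [0, 1], the fluorescence on the 640-850 nm part
    of it, floored at zero.  With ``leakage_correction=False`` the raw
    filtered leaf radiance is returned as ChlF.
    """
    inc = rs.l_incident.values
    if np.any(inc <= 0):
        raise DataError("incident radiance must be > 0 everywhere")
    ratio = np.clip(rs.l_leaf.values / inc, 0.0, 1.0)
    ratio_spec = Spectrum(rs.l_incident.wavelengths, ratio)

    wl = rs.l_incident.wavelengths
    emis = (wl >= 640.0) & (wl <= 850.0)
    if not emis.any():
        raise DataError("radiances do not cover the 640-850 nm emission range")
    leaf_f = rs.l_leaf_filtered.values[emis]
    if leakage_correction:
        leakage = ratio[emis] * rs.l_incident_filtered.values[emis]
        chlf = np.maximum(leaf_f - leakage, 0.0)
    else:
        chlf = leaf_f
    return ratio_spec, Spectrum(wl[emis], chlf)


def spectral_indices(
    spectra,
    chlf_spectra,
    kind: str,
    steps,
    a_meas=None,
    subtract_rho_565: bool = False,
) -> list:
    """PRI, dPRI, F740 and dF740 (plus LUE) for every curve step.

    ``spectra`` are the per-step rho or tau spectra, ``chlf_spectra`` the
    per-step fluorescence, ``steps`` the forcing sequence.  The reference
    step for the deltas is the lowest nonzero illumination for light
    curves and the highest CO2 step for CO2 curves.  For leaf-clip
    reflectance, ``subtract_rho_565`` removes the specular offset before
    the index computation.
    """
    if kind not in ("light", "co2"):
        raise DomainError(f"unknown curve kind '{kind}'")
    spectra = list(spectra)
    chlf_spectra = list(chlf_spectra)
    steps = list(steps)
    if not (len(spectra) == len(chlf_spectra) == len(steps)):
        raise DataError("spectra, chlf and steps must have equal lengths")

    if kind == "light":
        candidates = [i for i, s in enumerate(steps) if s.ipar > 0]
        if not candidates:
            raise DataError("light curve has no illuminated reference step")
        ref = min(candidates, key=lambda i: steps[i].ipar)
    else:
        ref = max(range(len(steps)), key=lambda i: steps[i].cs_air)

    pris, f740s = [], []
    for s, c in zip(spectra, chlf_spectra):
        r531 = s.value_at(PRI_BANDS[0])
        r570 = s.value_at(PRI_BANDS[1])
        if subtract_rho_565:
            off = s.value_at(565.0)
            r531, r570 = r531 - off, r570 - off
        denom = r531 + r570
        if denom == 0:
            raise DataError("PRI undefined: R531 + R570 = 0")
        pris.append((r531 - r570) / denom)
        f740s.append(c.value_at(F740_WL))

    out = []
    for i, (p, f) in enumerate(zip(pris, f740s)):
        step_lue = None
        if a_meas is not None:
            step_lue = lue(a_meas[i], steps[i].ipar, strict=False)
        out.append(
            DerivedIndices(
                pri=p,
                delta_pri=p - pris[ref],
                f740=f,
                delta_f740=f - f740s[ref],
                lue=step_lue,
            )
        )
    return out


def pam_derive(fs, fm_prime, fo, fm, par):
    """PhiPSII, NPQ and ETR from PAM yields.

    PhiPSII = (Fm'-Fs)/Fm'; NPQ = (Fm-Fm')/Fm';
    ETR = PhiPSII * PAR * absorptance(0.84) * PSII fraction(0.5).
    Accepts scalars or arrays (fo/fm are the dark-adapted scalars).
    """
    fm_prime = np.asarray(fm_prime, dtype=float)
    fs = np.asarray(fs, dtype=float)
    if np.any(fm_prime <= 0) or fm <= 0:
        raise DataError("Fm' and Fm must be > 0")
    phi_psii = (fm_prime - fs) / fm_prime
    npq = (fm - fm_prime) / fm_prime
    etr = phi_psii * np.asarray(par, dtype=float) * ETR_ABSORPTANCE * ETR_PSII_FRACTION
    if np.ndim(fs) == 0:
        return float(phi_psii), float(npq), float(etr)
    return phi_psii, npq, etr


def lue(a: float, ipar: float, strict: bool = True):
    """Light-use efficiency A/iPAR [umol CO2 per umol photons].

    Undefined at iPAR = 0; ``strict=True`` raises, otherwise the step is
    excluded (None returned) with a logged warning.
    """
    if ipar <= 0:
        if strict:
            raise DomainError("LUE undefined at iPAR = 0")
        logger.warning("LUE undefined at iPAR=0; step excluded")
        return None
    return float(a) / float(ipar)
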