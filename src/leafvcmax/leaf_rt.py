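"""Leaf radiative transfer: reflectance, transmittance and fluorescence.

The leaf is modelled as a stack of ``N`` absorbing plates (the generalized
plate model / Stokes system of the PROSPECT family).  Absorption of each
elementary layer is a linear mixture of the leaf constituents weighted by
their specific absorption coefficients (SACs), plus a differential
xanthophyll term scaled by the photochemical reflectance parameter ``Cx``
that acts only in the green (500-570 nm).

Chlorophyll fluorescence is simulated with a sublayer scheme: the leaf
interior (total absorber column between the two air-leaf interfaces) is
split into ``2**doubling_levels`` thin sublayers; the excitation flux
profile, the quanta absorbed by chlorophyll in each sublayer, and the
re-emission (efficiency ``eta``, spectral shape ``phi``) transported to
either face - including multiple internal reflections at the interfaces -
are accumulated analytically.  Because the mesophyll of a plate-model leaf
does not scatter volumetrically, the adding/doubling operator products
collapse to these closed-form bounce series; the sublayer count only
controls the source-position discretization, which converges as O(M^-2).

Diffuse propagation inside the slab uses the two-stream diffusivity factor
2 (attenuation ``exp(-2K)`` for an absorber column K).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import exp1

from .errors import DomainError, GridError
from .spectra import GRID_EMISSION, GRID_EXCITATION, GRID_FULL, Spectrum

__all__ = [
    "LeafOpticalParams",
    "SACSet",
    "tav",
    "build_absorption",
    "simulate_rt",
    "simulate_fluorescence",
    "OPTICAL_RANGES",
]

#: Valid ranges of the leaf optical inputs (lower, upper).
OPTICAL_RANGES = {
    "cab": (0.0, 100.0),
    "ccar": (0.0, 30.0),
    "cant": (0.0, 10.0),
    "cw": (0.0, 0.4),
    "cdm": (0.0, 0.5),
    "n_layers": (1.0, 4.0),
    "cs": (0.0, 0.6),
    "eta": (0.0, 0.2),
    "cx": (0.0, 1.5),
}


@dataclass(frozen=True)
class LeafOpticalParams:
    """The nine leaf optical inputs.

    cab : chlorophyll a+b content [ug cm-2]
    ccar : total carotenoid content [ug cm-2]
    cant : anthocyanin content [ug cm-2]
    cw : equivalent water thickness [cm]
    cdm : dry matter content [g cm-2]
    n_layers : mesophyll structure parameter N [-]
    cs : senescent (brown pigment) content [arbitrary]
    eta : bulk fluorescence quantum efficiency [-]
    cx : photochemical reflectance (xanthophyll) parameter [-]
    """

    cab: float = 40.0
    ccar: float = 10.0
    cant: float = 0.0
    cw: float = 0.009
    cdm: float = 0.012
    n_layers: float = 1.4
    cs: float = 0.0
    eta: float = 0.01
    cx: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            lo, hi = OPTICAL_RANGES[f.name]
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < lo or v > hi:
                raise DomainError(
                    f"{f.name}={v} outside valid range [{lo}, {hi}]"
                )

    def replace(self, **kw) -> "LeafOpticalParams":
        return replace(self, **kw)


def tav(alpha_deg: float, n: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface.

    Unpolarized Fresnel transmittance from air into a medium of refractive
    index ``n``, averaged over an incidence cone of half-angle
    ``alpha_deg`` with the usual sin(2 theta) solid-angle weighting.
    Computed by Gauss-Legendre quadrature (vectorized over wavelength).
    """
    n = np.asarray(n, dtype=float)
    alpha = np.deg2rad(alpha_deg)
    if alpha <= 0:
        # normal incidence limit
        r0 = ((n - 1.0) / (n + 1.0)) ** 2
        return 1.0 - r0
    nodes, weights = leggauss(64)
    theta = 0.5 * alpha * (nodes + 1.0)  # map [-1,1] -> [0, alpha]
    w = 0.5 * alpha * weights
    st = np.sin(theta)[:, None]
    ct = np.cos(theta)[:, None]
    n2 = n[None, :]
    stt = np.clip(st / n2, 0.0, 1.0)
    ctt = np.sqrt(1.0 - stt**2)
    rs = ((ct - n2 * ctt) / (ct + n2 * ctt)) ** 2
    rp = ((ctt - n2 * ct) / (ctt + n2 * ct)) ** 2
    t_fres = 1.0 - 0.5 * (rs + rp)
    wgt = (st * ct) * w[:, None]
    return np.sum(t_fres * wgt, axis=0) / np.sum(wgt, axis=0)


class SACSet:
    """Specific absorption coefficients, refractive index and emission shape.

    All arrays live on one strictly increasing wavelength grid.  ``cx_band``
    is the differential xanthophyll absorption (nonzero only in
    500-570 nm); ``phi`` is the fluorescence emission probability density
    (nonzero only in 640-850 nm, unit integral).  Interface transmissivities
    derived from the refractive index are precomputed and cached because
    they are reused by every simulation on the same SAC set.
    """

    CONSTITUENTS = ("cab", "ccar", "cant", "cw", "cdm", "cs")

    def __init__(
        self,
        wavelengths,
        cab,
        ccar,
        cant,
        cw,
        cdm,
        cs,
        cx_band,
        refractive,
        phi,
        validate: bool = True,
    ):
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.cab = np.asarray(cab, dtype=float)
        self.ccar = np.asarray(ccar, dtype=float)
        self.cant = np.asarray(cant, dtype=float)
        self.cw = np.asarray(cw, dtype=float)
        self.cdm = np.asarray(cdm, dtype=float)
        self.cs = np.asarray(cs, dtype=float)
        self.cx_band = np.asarray(cx_band, dtype=float)
        self.refractive = np.asarray(refractive, dtype=float)
        self.phi = np.asarray(phi, dtype=float)
        arrays = [
            self.cab, self.ccar, self.cant, self.cw, self.cdm, self.cs,
            self.cx_band, self.refractive, self.phi,
        ]
        if any(a.shape != self.wavelengths.shape for a in arrays):
            raise GridError("all SAC arrays must share the wavelength grid")
        if validate:
            self._validate()
        # cached interface terms (depend only on n)
        self.t_alpha = tav(40.0, self.refractive)  # top entry, ~40 deg cone
        self.t12 = tav(90.0, self.refractive)  # diffuse, air -> leaf
        self.t21 = self.t12 / self.refractive**2  # diffuse, leaf -> air
        self.r21 = 1.0 - self.t21

    def _validate(self):
        wl = self.wavelengths
        if np.any(np.diff(wl) <= 0):
            raise GridError("SAC wavelengths must be strictly increasing")
        for name in self.CONSTITUENTS + ("cx_band", "phi"):
            if np.any(getattr(self, name) < 0):
                raise DomainError(f"SAC '{name}' has negative values")
        outside = (wl < 500.0) | (wl > 570.0)
        if np.any(self.cx_band[outside] != 0.0):
            raise DomainError("xanthophyll band must vanish outside 500-570 nm")
        emis = (wl >= 640.0) & (wl <= 850.0)
        if np.any(self.phi[~emis] != 0.0):
            raise DomainError("phi must vanish outside 640-850 nm")
        integral = np.trapezoid(self.phi[emis], wl[emis])
        if abs(integral - 1.0) > 1e-6:
            raise DomainError(
                f"phi must integrate to 1 over 640-850 nm (got {integral})"
            )
        if np.any(self.refractive <= 1.0):
            raise DomainError("refractive index must exceed 1")

    def subset(self, wavelengths) -> "SACSet":
        """SAC set restricted to a subset of the existing grid samples."""
        wl = np.asarray(wavelengths, dtype=float)
        idx = np.searchsorted(self.wavelengths, wl)
        if np.any(idx >= self.wavelengths.size) or np.any(
            self.wavelengths[np.minimum(idx, self.wavelengths.size - 1)] != wl
        ):
            raise GridError("requested wavelengths are not grid samples")
        return SACSet(
            wl,
            self.cab[idx], self.ccar[idx], self.cant[idx],
            self.cw[idx], self.cdm[idx], self.cs[idx],
            self.cx_band[idx], self.refractive[idx], self.phi[idx],
            validate=False,
        )

    def indices_between(self, lo: float, hi: float) -> np.ndarray:
        return np.nonzero(
            (self.wavelengths >= lo) & (self.wavelengths <= hi)
        )[0]


def build_absorption(params: LeafOpticalParams, sacs: SACSet) -> Spectrum:
    """Absorption of one elementary layer: k = (sum_i Ci*SACi + Cx*SACx)/N."""
    total = (
        params.cab * sacs.cab
        + params.ccar * sacs.ccar
        + params.cant * sacs.cant
        + params.cw * sacs.cw
        + params.cdm * sacs.cdm
        + params.cs * sacs.cs
        + params.cx * sacs.cx_band
    )
    return Spectrum(sacs.wavelengths, total / params.n_layers)


def _layer_transmission(k: np.ndarray) -> np.ndarray:
    """Diffuse flux transmission of one elementary absorbing layer.

    theta(k) = (1-k) e^{-k} + k^2 E1(k); theta(0) = 1.
    """
    theta = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    theta[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return np.clip(theta, 0.0, 1.0)


def simulate_rt(
    params: LeafOpticalParams,
    sacs: SACSet,
    wavelengths=None,
) -> tuple[Spectrum, Spectrum]:
    """Reflectance and transmittance of the N-plate leaf.

    The first plate's upper interface sees a ~40 degree incidence cone
    (near-collimated illumination); all other interfaces see isotropic
    diffuse flux.  The remaining N-1 plates are combined with the Stokes
    expressions for a pile of identical plates, N real-valued.
    """
    if params.n_layers < 1.0:
        raise DomainError("mesophyll structure parameter N must be >= 1")
    s = sacs if wavelengths is None else sacs.subset(wavelengths)
    k = build_absorption(params, s).values
    theta = _layer_transmission(k)
    n_plates = params.n_layers

    talf, t12, t21, r21 = s.t_alpha, s.t12, s.t21, s.r21
    ralf = 1.0 - talf
    r12 = 1.0 - t12

    denom = 1.0 - r21**2 * theta**2
    # top plate, oblique entry
    t_a = talf * theta * t21 / denom
    r_a = ralf + r21 * theta * t_a
    # generic plate, diffuse entry
    t_one = t12 * theta * t21 / denom
    r_one = r12 + r21 * theta * t_one

    rho, tau = _stack_plates(r_a, t_a, r_one, t_one, n_plates)
    rho = np.clip(rho, 0.0, 1.0)
    tau = np.clip(tau, 0.0, 1.0)
    return Spectrum(s.wavelengths, rho), Spectrum(s.wavelengths, tau)


def _stack_plates(r_a, t_a, r, t, n_plates: float):
    """Stokes system: top plate (r_a, t_a) over N-1 identical plates (r, t)."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        d_sq = (1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t)
        d = np.sqrt(np.maximum(d_sq, 0.0))
        rq, tq = r**2, t**2
        a = (1.0 + rq - tq + d) / (2.0 * r)
        b = (1.0 - rq + tq + d) / (2.0 * t)
        b_pow = b ** (n_plates - 1.0)
        b2 = b_pow**2
        a2 = a**2
        denom = a2 * b2 - 1.0
        r_sub = a * (b2 - 1.0) / denom
        t_sub = b_pow * (a2 - 1.0) / denom

    # conservative (lossless) limit: a, b -> 1 and the expressions above
    # become 0/0; use the exact N-plate limit instead
    cons = (r + t) >= 1.0 - 1e-12
    if np.any(cons):
        tc = t[cons]
        t_sub_c = tc / (tc + (1.0 - tc) * (n_plates - 1.0))
        t_sub = np.where(cons, _fill(t_sub, cons, t_sub_c), t_sub)
        r_sub = np.where(cons, 1.0 - t_sub, r_sub)
    # opaque limit: t -> 0, the pile below reflects like a single interface
    opaque = t < 1e-30
    if np.any(opaque):
        r_sub = np.where(opaque, r, r_sub)
        t_sub = np.where(opaque, 0.0, t_sub)

    denom2 = 1.0 - r_sub * r
    tau = t_a * t_sub / denom2
    rho = r_a + t_a * r_sub * t * (1.0 / denom2)
    return rho, tau


def _fill(base, mask, values):
    out = base.copy()
    out[mask] = values
    return out


def simulate_fluorescence(
    params: LeafOpticalParams,
    sacs: SACSet,
    incident: Spectrum,
    emission_wavelengths=None,
    doubling_levels: int = 6,
) -> tuple[Spectrum, Spectrum]:
    """Chlorophyll fluorescence emitted from the two leaf faces.

    Parameters
    ----------
    incident
        Incident spectral flux (quanta per nm); must cover the excitation
        range present in the SAC grid (400-750 nm).
    emission_wavelengths
        Optional subset of the 640-850 nm grid on which to evaluate the
        emission (used by the spectral-fitting code to avoid computing
        bands that are not part of the cost function).
    doubling_levels
        The leaf is split into ``2**doubling_levels`` source sublayers.

    Returns
    -------
    (chlf_backward, chlf_forward)
        Emission exiting the illuminated (backward) and shaded (forward)
        face, same per-nm flux units as ``incident``.
    """
    exc_idx = sacs.indices_between(GRID_EXCITATION[0], GRID_EXCITATION[-1])
    if exc_idx.size == 0:
        raise GridError("SAC grid has no samples in the excitation range")
    wl_e = sacs.wavelengths[exc_idx]
    if incident.wavelengths[0] > wl_e[0] or incident.wavelengths[-1] < wl_e[-1]:
        raise GridError(
            "incident spectrum does not cover the excitation range "
            f"[{wl_e[0]}, {wl_e[-1]}] nm"
        )
    flux_in = np.interp(wl_e, incident.wavelengths, incident.values)

    if emission_wavelengths is None:
        em_idx = sacs.indices_between(GRID_EMISSION[0], GRID_EMISSION[-1])
        wl_f = sacs.wavelengths[em_idx]
    else:
        wl_f = np.asarray(emission_wavelengths, dtype=float)
        if np.any(wl_f < GRID_EMISSION[0]) or np.any(wl_f > GRID_EMISSION[-1]):
            raise GridError("emission wavelengths must lie in 640-850 nm")
        em_idx = np.searchsorted(sacs.wavelengths, wl_f)
        if np.any(sacs.wavelengths[em_idx] != wl_f):
            raise GridError("emission wavelengths are not SAC grid samples")

    m_sub = 2 ** int(doubling_levels)
    # total absorber column between the interfaces (N elementary layers)
    k_elem = build_absorption(params, sacs).values
    k_total = k_elem * params.n_layers

    # --- excitation side -------------------------------------------------
    ke = k_total[exc_idx]
    fcab = np.zeros_like(ke)
    nz = ke > 0
    fcab[nz] = (params.cab * sacs.cab[exc_idx][nz]) / ke[nz]
    r21e = sacs.r21[exc_idx]
    talf_e = sacs.t_alpha[exc_idx]
    z_edges = np.linspace(0.0, 1.0, m_sub + 1)[:, None]
    down = np.exp(-2.0 * ke[None, :] * z_edges)  # (M+1, ne)
    up = np.exp(-2.0 * ke[None, :] * (1.0 - z_edges))
    a_full = np.exp(-2.0 * ke)
    denom_e = 1.0 - (r21e * a_full) ** 2
    d_prof = talf_e * down / denom_e
    u_prof = talf_e * r21e * a_full * up / denom_e
    absorbed = (d_prof[:-1] - d_prof[1:]) + (u_prof[1:] - u_prof[:-1])  # (M, ne)
    # quanta absorbed by chlorophyll in each sublayer, per unit incident
    src = 0.5 * fcab[None, :] * absorbed  # half up, half down

    # --- emission side ---------------------------------------------------
    kf = k_total[em_idx]
    r21f = sacs.r21[em_idx]
    t21f = sacs.t21[em_idx]
    phi_f = sacs.phi[em_idx]
    z_mid = ((np.arange(m_sub) + 0.5) / m_sub)[:, None]
    au = np.exp(-2.0 * kf[None, :] * z_mid)  # mid-layer -> top
    ad = np.exp(-2.0 * kf[None, :] * (1.0 - z_mid))  # mid-layer -> bottom
    af = np.exp(-2.0 * kf)
    denom_f = 1.0 - (r21f * af) ** 2
    w_back = (au + ad * r21f * af) / denom_f * t21f  # (M, nf)
    w_forw = (ad + au * r21f * af) / denom_f * t21f

    # integrate the source over excitation first (1 nm grid: plain sum),
    # then transport the per-sublayer totals to each face
    src_total = src @ flux_in  # (M,) quanta emitted per face per sublayer
    back = params.eta * phi_f * (w_back.T @ src_total)
    forw = params.eta * phi_f * (w_forw.T @ src_total)
    return Spectrum(wl_f, back), Spectrum(wl_f, forw)
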