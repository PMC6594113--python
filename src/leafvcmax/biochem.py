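"""Farquhar-Collatz photosynthesis with fluorescence-yield bookkeeping.

Net assimilation is the smoothed minimum of the Rubisco-limited and the
electron-transport-limited rate; stomatal conductance follows Ball-Berry;
the intercellular CO2 concentration Ci is solved to a fixed point by
damped iteration.  From the solved state, a light-saturation measure

    x = 1 - Ja/Je

drives the empirical nonphotochemical-quenching rate coefficient

    Kn = Kn0 * (1 + beta) * x**gamma / (beta + x**gamma)

and the PAM-equivalent fluorescence yields are computed from the rate
coefficients Kf (fluorescence), Kd (heat), Kp (photochemistry, dark) and
Kn.  With the default normalization Kf + Kd = 1, Kn is numerically equal
to NPQ = (Fm - Fm')/Fm'.

All experiments this package emulates run at 25 C; the kinetic constants
are therefore fixed 25 C literature values and no temperature-response
functions are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConvergenceError, DomainError

__all__ = [
    "BiochemParams",
    "Forcing",
    "PhotosynthesisState",
    "kn_from_saturation",
    "fluorescence_yields",
    "solve_photosynthesis",
]


@dataclass(frozen=True)
class BiochemParams:
    """Inputs of the photosynthesis model (defaults: standard values).

    vcmax : maximum carboxylation capacity [umol CO2 m-2 s-1]
    m : Ball-Berry slope [-]
    rd_param : dark respiration as a fraction of vcmax [-]
    kn0, beta, gamma : fitting parameters of the Kn(x) relation [-]
    kf, kd, kp : rate coefficients for fluorescence, heat dissipation and
        dark-adapted photochemistry [-]; kf + kd = 1 by default so that
        Kn equals NPQ
    gamma_star : CO2 compensation point without Rd at 25 C [umol mol-1]
    kc : Michaelis constant for CO2 at 25 C [umol mol-1]
    ko : Michaelis constant for O2 at 25 C [mmol mol-1]
    o2 : oxygen concentration [mmol mol-1]
    g0 : residual stomatal conductance [mol m-2 s-1]
    absorptance : leaf PAR absorptance [-]
    theta_curv : curvature of the smoothed minimum of (Ac, Aj) [-]
    """

    vcmax: float = 70.0
    m: float = 8.0
    rd_param: float = 0.015
    kn0: float = 2.48
    beta: float = 0.114
    gamma: float = 2.83
    kf: float = 0.05
    kd: float = 0.95
    kp: float = 4.0
    gamma_star: float = 42.75
    kc: float = 404.9
    ko: float = 278.4
    o2: float = 210.0
    g0: float = 0.01
    absorptance: float = 0.84
    theta_curv: float = 0.98

    def __post_init__(self):
        if not (0.0 <= self.vcmax <= 250.0):
            raise DomainError(f"vcmax={self.vcmax} outside [0, 250]")
        for name in ("kf", "kd", "kp"):
            if getattr(self, name) <= 0:
                raise DomainError(f"rate coefficient {name} must be > 0")
        if self.rd_param < 0 or self.kn0 <= 0 or self.beta < 0 or self.gamma < 0:
            raise DomainError("invalid NPQ/respiration parameters")
        if not (0.0 < self.theta_curv <= 1.0):
            raise DomainError("theta_curv must be in (0, 1]")

    @property
    def phi_po(self) -> float:
        """Dark-adapted photochemical yield Kp/(Kp+Kf+Kd)."""
        return self.kp / (self.kp + self.kf + self.kd)

    @property
    def rd(self) -> float:
        """Dark respiration [umol CO2 m-2 s-1]."""
        return self.rd_param * self.vcmax

    def replace(self, **kw) -> "BiochemParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class Forcing:
    """One environmental step of a response curve.

    ipar : incident PAR [umol photons m-2 s-1]
    t_leaf : leaf temperature [C]
    cs_air : CO2 mole fraction at the leaf surface [ppm]
    rh : relative humidity [0-1]
    """

    ipar: float
    t_leaf: float = 25.0
    cs_air: float = 400.0
    rh: float = 0.6

    def __post_init__(self):
        if self.ipar < 0:
            raise DomainError("iPAR must be >= 0")
        if self.cs_air <= 0:
            raise DomainError("CO2 concentration must be > 0")
        if not (0.0 < self.rh <= 1.0):
            raise DomainError("relative humidity must be in (0, 1]")


@dataclass(frozen=True)
class PhotosynthesisState:
    """Full per-step output of the photosynthesis model."""

    a: float  # net assimilation [umol m-2 s-1]
    ag: float  # gross assimilation
    ci: float  # intercellular CO2 [ppm]
    gs: float  # stomatal conductance [mol m-2 s-1]
    je: float  # potential electron transport [umol m-2 s-1]
    ja: float  # actual electron transport
    x: float  # light-saturation measure [0-1]
    phi_p: float  # photochemical yield
    phi_po: float  # dark-adapted photochemical yield
    kn: float  # NPQ rate coefficient
    fo: float
    fm: float
    fm_prime: float
    fs: float
    epsilon: float  # Fs/Fo
    npq: float
    phi_psii: float
    etr: float
    n_iter: int = 0


def kn_from_saturation(x: float, kn0: float, beta: float, gamma: float) -> float:
    """Empirical NPQ rate coefficient Kn = Kn0 (1+b) x^g / (b + x^g)."""
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"light saturation x={x} outside [0, 1]")
    if kn0 <= 0 or beta < 0 or gamma < 0:
        raise DomainError("kn0 must be > 0 and beta, gamma >= 0")
    if x == 0.0:
        return 0.0
    xg = x**gamma
    return kn0 * (1.0 + beta) * xg / (beta + xg)


def fluorescence_yields(
    phi_p: float,
    phi_po: float,
    kn: float,
    kf: float,
    kd: float,
    kp: float,
) -> dict:
    """PAM-equivalent fluorescence yields from the rate coefficients.

    Fo = Kf/(Kf+Kp+Kd), Fm = Kf/(Kf+Kd), Fm' = Kf/(Kf+Kd+Kn),
    Fs = Fm' (1 - phi_p); and the derived epsilon = Fs/Fo,
    NPQ = (Fm-Fm')/Fm' = Kn/(Kf+Kd), PhiPSII = (Fm'-Fs)/Fm' = phi_p.
    """
    if kf <= 0 or kd <= 0 or kp <= 0:
        raise DomainError("rate coefficients must be > 0")
    if kn < 0:
        raise DomainError("Kn must be >= 0")
    if not (0.0 <= phi_p <= phi_po < 1.0):
        raise DomainError("need 0 <= phi_p <= phi_po < 1")
    fo = kf / (kf + kp + kd)
    fm = kf / (kf + kd)
    fm_prime = kf / (kf + kd + kn)
    fs = fm_prime * (1.0 - phi_p)
    return {
        "fo": fo,
        "fm": fm,
        "fm_prime": fm_prime,
        "fs": fs,
        "epsilon": fs / fo,
        "npq": kn / (kf + kd),
        "phi_psii": (fm_prime - fs) / fm_prime,
    }


def _smooth_min(a: float, b: float, theta: float) -> float:
    """Lower root of theta*y^2 - (a+b)*y + a*b = 0 (smoothed minimum)."""
    s = a + b
    disc = s * s - 4.0 * theta * a * b
    return (s - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def solve_photosynthesis(
    params: BiochemParams,
    forcing: Forcing,
    ci_init: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> PhotosynthesisState:
    """Solve the coupled A-gs-Ci system and derive the fluorescence state.

    The Ci fixed point is found by damped iteration (damping 0.5) to a
    tolerance of ``tol`` ppm on the undamped update.  At iPAR = 0 the
    light-saturation measure x is defined as 0 (dark-adapted, all reaction
    centres open), which gives Kn = 0 and Fs = Fo exactly.
    """
    g_star = params.gamma_star
    kc_eff = params.kc * (1.0 + params.o2 / params.ko)
    je = 0.5 * params.phi_po * params.absorptance * forcing.ipar
    rd = params.rd
    cs = forcing.cs_air

    ci = 0.7 * cs if ci_init is None else float(ci_init)
    ci = min(max(ci, 1e-3), 10.0 * cs)

    def assimilation(ci_val: float):
        ac = params.vcmax * (ci_val - g_star) / (ci_val + kc_eff)
        aj = je * (ci_val - g_star) / (4.0 * ci_val + 8.0 * g_star)
        ag = _smooth_min(ac, aj, params.theta_curv)
        a = ag - rd
        gs = max(params.g0, params.g0 + params.m * a * forcing.rh / cs)
        return ac, aj, ag, a, gs

    def ci_update(ci_val: float) -> float:
        _, _, _, a, gs = assimilation(ci_val)
        return min(max(cs - 1.6 * a / gs, 1e-3), 10.0 * cs)

    n_iter = 0
    step = math.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        step = ci_update(ci) - ci
        ci = ci + 0.5 * step
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        # near the compensation point the conductance floor makes the map
        # expansive and the damped iteration cycles; the fixed point still
        # exists and is bracketed, so fall back to root finding on
        # g(Ci) = update(Ci) - Ci
        from scipy.optimize import brentq

        lo, hi = 1e-3, 10.0 * cs
        g_lo, g_hi = ci_update(lo) - lo, ci_update(hi) - hi
        if g_lo * g_hi > 0:
            raise ConvergenceError(
                "Ci fixed point did not converge",
                {"ci": ci, "step": step, "iterations": n_iter,
                 "forcing": forcing, "vcmax": params.vcmax},
            )
        ci = brentq(lambda c: ci_update(c) - c, lo, hi, xtol=tol)

    _, _, ag, a, gs = assimilation(ci)

    phi_po = params.phi_po
    if je <= 0.0:
        ja, x = 0.0, 0.0
    elif ci - g_star <= 1e-9:
        ja, x = 0.0, 1.0  # compensation point: no net electron demand
    else:
        ja = 4.0 * ag * (ci + 2.0 * g_star) / (ci - g_star)
        ja = min(max(ja, 0.0), je)
        x = min(max(1.0 - ja / je, 0.0), 1.0)

    phi_p = phi_po * (1.0 - x)
    kn = kn_from_saturation(x, params.kn0, params.beta, params.gamma)
    y = fluorescence_yields(phi_p, phi_po, kn, params.kf, params.kd, params.kp)

    return PhotosynthesisState(
        a=a, ag=ag, ci=ci, gs=gs, je=je, ja=ja, x=x,
        phi_p=phi_p, phi_po=phi_po, kn=kn,
        fo=y["fo"], fm=y["fm"], fm_prime=y["fm_prime"], fs=y["fs"],
        epsilon=y["epsilon"], npq=y["npq"], phi_psii=y["phi_psii"],
        etr=ja, n_iter=n_iter,
    )
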