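"""Link the photosynthesis model to the leaf radiative-transfer model.

Two linear bridges connect the biochemical outputs to the optical inputs:

* ``Cx = slope_cx * NPQ`` - the xanthophyll de-epoxidation parameter that
  darkens the green (500-570 nm) reflectance and transmittance scales
  linearly with nonphotochemical quenching (default slope 0.3187, a
  previously calibrated coefficient);
* ``eta = sigma_scale * epsilon`` - the absolute fluorescence emission
  efficiency is the relative steady-state efficiency epsilon = Fs/Fo
  scaled by ``sigma_scale`` (default 0.007, the quantum efficiency of
  fluorescence of a dark-adapted leaf, where epsilon = 1).

``forward_coupled`` runs the fully coupled simulation along a measurement
protocol: per step, the photosynthesis state gives (NPQ, epsilon), which
set (Cx, eta) for the radiative-transfer run; the static optical
properties (pigments, water, structure) are held fixed along the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .biochem import BiochemParams, Forcing, PhotosynthesisState, solve_photosynthesis
from .errors import DomainError
from .leaf_rt import (
    OPTICAL_RANGES,
    LeafOpticalParams,
    SACSet,
    simulate_fluorescence,
    simulate_rt,
)
from .spectra import Spectrum

__all__ = [
    "CouplingParams",
    "CoupledPoint",
    "cx_from_npq",
    "eta_from_epsilon",
    "forward_coupled",
    "scale_incident_to_ipar",
]

logger = logging.getLogger(__name__)

_CX_MAX = OPTICAL_RANGES["cx"][1]
_ETA_MAX = OPTICAL_RANGES["eta"][1]


@dataclass(frozen=True)
class CouplingParams:
    """Linear coupling coefficients between the two leaf models.

    slope_cx : coefficient of the Cx-NPQ relation [-]
    sigma_scale : scaling factor linking epsilon to eta [-]
    """

    slope_cx: float = 0.3187
    sigma_scale: float = 0.007

    def __post_init__(self):
        if self.slope_cx <= 0:
            raise DomainError("slope_cx must be > 0")
        if not (0.0 <= self.sigma_scale <= 0.2):
            raise DomainError("sigma_scale outside [0, 0.2]")

    def replace(self, **kw) -> "CouplingParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CoupledPoint:
    """One protocol step of the fully coupled forward simulation."""

    forcing: Forcing
    state: PhotosynthesisState
    optical: LeafOpticalParams  # with Cx, eta set by the coupling
    rho: Spectrum
    tau: Spectrum
    chlf_backward: Spectrum
    chlf_forward: Spectrum


def cx_from_npq(npq: float, slope_cx: float = 0.3187) -> float:
    """Xanthophyll parameter from NPQ, clipped to the valid Cx range."""
    if npq < 0:
        raise DomainError("NPQ must be >= 0")
    cx = slope_cx * npq
    if cx > _CX_MAX:
        logger.warning("Cx=%.3f clipped to %.1f", cx, _CX_MAX)
        cx = _CX_MAX
    return cx


def eta_from_epsilon(epsilon: float, sigma_scale: float = 0.007) -> float:
    """Fluorescence efficiency eta from epsilon = Fs/Fo, clipped to range."""
    if epsilon < 0:
        raise DomainError("epsilon must be >= 0")
    eta = sigma_scale * epsilon
    if eta > _ETA_MAX:
        logger.warning("eta=%.4f clipped to %.1f", eta, _ETA_MAX)
        eta = _ETA_MAX
    return eta


def scale_incident_to_ipar(incident: Spectrum, ipar: float) -> Spectrum:
    """Rescale a lamp spectrum so its 400-700 nm quanta integral is iPAR.

    The lamp spectrum defines the spectral *shape*; each protocol step
    fixes its own PAR level, so the shape is rescaled per step.  A zero
    iPAR (dark step) gives a zero spectrum.
    """
    par = incident.integral(400.0, 700.0)
    if par <= 0:
        raise DomainError("incident spectrum has no PAR (400-700 nm) flux")
    return incident.scaled(ipar / par)


def forward_coupled(
    static_optics: LeafOpticalParams,
    biochem: BiochemParams,
    coupling: CouplingParams,
    protocol,
    incident: Spectrum,
    sacs: SACSet,
    doubling_levels: int = 6,
) -> list[CoupledPoint]:
    """Run the coupled model along a sequence of forcing steps.

    ``incident`` is the lamp spectral shape; it is rescaled per step to
    the step's iPAR.  The static optical fields are held constant across
    the curve; only Cx and eta vary, driven by the biochemical state.
    """
    protocol = list(protocol)
    if not protocol:
        raise DomainError("protocol must contain at least one step")
    points = []
    for forcing in protocol:
        state = solve_photosynthesis(biochem, forcing)
        cx = cx_from_npq(state.npq, coupling.slope_cx)
        eta = eta_from_epsilon(state.epsilon, coupling.sigma_scale)
        optical = static_optics.replace(cx=cx, eta=eta)
        rho, tau = simulate_rt(optical, sacs)
        step_incident = scale_incident_to_ipar(incident, forcing.ipar)
        chlf_b, chlf_f = simulate_fluorescence(
            optical, sacs, step_incident, doubling_levels=doubling_levels
        )
        points.append(
            CoupledPoint(
                forcing=forcing,
                state=state,
                optical=optical,
                rho=rho,
                tau=tau,
                chlf_backward=chlf_b,
                chlf_forward=chlf_f,
            )
        )
    return points
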