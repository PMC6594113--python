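"""Bounded trust-region inversions that retrieve Vcmax (methods 1-3).

* Method 1 - gas exchange: fit Vcmax by matching modelled to measured
  net assimilation along a light- or CO2-response curve.
* Method 2 - PAM fluorometry: fit (Vcmax, Kn0, beta, gamma) by matching
  Fs/Fo and NPQ curves.
* Method 3 - spectroscopy: fit (Vcmax, Kn0, sigma_scale) of the fully
  coupled model by matching a far-red chlorophyll-fluorescence band
  (730-750 nm) and the green transmittance or reflectance band
  (525-545 nm) over the whole response curve at once.  Reflectance is
  normalized by subtracting its value at 565 nm (where the xanthophyll
  signal vanishes) to suppress specular offsets.  The static optical
  properties are retrieved once per leaf beforehand
  (:func:`retrieve_static_optics`) from a reference spectrum.

All fits use the trust-region reflective least-squares solver with the
parameter bounds and initial values of the study design; each residual
block of method 3 is normalized by the mean magnitude of its measured
values so fluorescence and transmittance contribute comparably to the
single cost function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .biochem import BiochemParams, Forcing, solve_photosynthesis
from .coupling import (
    CouplingParams,
    cx_from_npq,
    eta_from_epsilon,
    scale_incident_to_ipar,
)
from .errors import DataError, DomainError, InsufficientDataError
from .leaf_rt import (
    OPTICAL_RANGES,
    LeafOpticalParams,
    SACSet,
    simulate_fluorescence,
    simulate_rt,
)
from .spectra import Spectrum, require_unit_interval

__all__ = [
    "CHLF_BAND",
    "GREEN_BAND",
    "RHO_NORM_WL",
    "StepSpectra",
    "PAMRecord",
    "ResponseCurveDataset",
    "RetrievalResult",
    "cost_residuals",
    "retrieve_method1",
    "retrieve_method2",
    "retrieve_static_optics",
    "retrieve_method3",
    "Method3Problem",
]

#: Fitting windows of method 3 [nm], inclusive.
CHLF_BAND = (730.0, 750.0)
GREEN_BAND = (525.0, 545.0)
#: Reflectance normalization wavelength (xanthophyll-neutral point).
RHO_NORM_WL = 565.0

_VCMAX_BOUNDS = (0.0, 250.0)
_KN0_BOUNDS = (2.0, 6.0)
_BETAGAMMA_BOUNDS = (0.0, 100.0)
_SIGMA_BOUNDS = (0.0, 0.2)


@dataclass
class StepSpectra:
    """Per-step spectral measurements (any subset may be present)."""

    rho: Spectrum | None = None
    tau: Spectrum | None = None
    chlf_forward: Spectrum | None = None
    chlf_backward: Spectrum | None = None


@dataclass
class PAMRecord:
    """PAM yields along a curve plus the dark-adapted references."""

    fs: np.ndarray
    fm_prime: np.ndarray
    fo_dark: float
    fm_dark: float


@dataclass
class ResponseCurveDataset:
    """An ordered response curve with whichever measurements exist."""

    kind: str  # 'light' | 'co2'
    steps: list  # list[Forcing]
    a_meas: np.ndarray | None = None
    pam: PAMRecord | None = None
    spectra: list | None = None  # list[StepSpectra]
    reference_rho: Spectrum | None = None
    reference_tau: Spectrum | None = None
    truth: object | None = None

    def __post_init__(self):
        if self.kind not in ("light", "co2"):
            raise DomainError(f"unknown curve kind '{self.kind}'")
        if self.a_meas is None and self.pam is None and self.spectra is None:
            raise DataError("dataset carries no measurement block")


@dataclass
class RetrievalResult:
    """Outcome of one bounded least-squares inversion."""

    method: str
    names: list
    values: dict
    initials: dict
    bounds: dict
    cost: float
    cost_initial: float
    residual: np.ndarray
    trace: list  # cost at every function evaluation
    sigma_p: dict
    goodness: dict
    flags: list = field(default_factory=list)
    n_eval: int = 0
    success: bool = True

    def __getitem__(self, name):
        return self.values[name]


def cost_residuals(measured, simulated):
    """Elementwise residuals and the scalar cost C = sum((M - S)^2).

    Multi-spectrum matrices are flattened to a single residual vector;
    the squared norm of that vector is C.
    """
    m = np.asarray(measured, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if m.shape != s.shape:
        raise DataError(f"shape mismatch: measured {m.shape} vs simulated {s.shape}")
    resid = (m - s).ravel()
    return resid, float(np.dot(resid, resid))


def _run_fit(method, residual_fn, names, x0, lb, ub, sim_meas_fn=None,
             max_nfev=400):
    """Drive least_squares and package a RetrievalResult."""
    trace = []

    def wrapped(p):
        r = residual_fn(p)
        trace.append(float(np.dot(r, r)))
        return r

    res = least_squares(
        wrapped, np.asarray(x0, dtype=float),
        bounds=(np.asarray(lb, float), np.asarray(ub, float)),
        method="trf", ftol=1e-8, xtol=1e-10, gtol=1e-8, max_nfev=max_nfev,
    )
    cost = float(np.dot(res.fun, res.fun))
    flags = []
    if not res.success:
        flags.append("non_convergence")
    span = np.asarray(ub, float) - np.asarray(lb, float)
    for i, name in enumerate(names):
        if res.x[i] - lb[i] <= 1e-6 * span[i]:
            flags.append(f"{name}_at_lower_bound")
        elif ub[i] - res.x[i] <= 1e-6 * span[i]:
            flags.append(f"{name}_at_upper_bound")

    # parameter standard deviations from the Jacobian at the solution
    sigma_p = {}
    n, p = res.fun.size, len(names)
    if n > p:
        sigma_r2 = cost / (n - p)
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * sigma_r2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * sigma_r2
            flags.append("singular_jacobian")
        diag = np.clip(np.diag(cov), 0.0, None)
        sigma_p = {name: float(np.sqrt(d)) for name, d in zip(names, diag)}
        for i, name in enumerate(names):
            if sigma_p[name] > span[i]:
                flags.append(f"{name}_unidentifiable")

    goodness = {}
    if sim_meas_fn is not None:
        sim, meas = sim_meas_fn(res.x)
        goodness = _goodness(sim, meas)
        rms_meas = float(np.sqrt(np.mean(np.asarray(meas) ** 2)))
        if goodness.get("rmse") is not None and rms_meas > 0:
            if goodness["rmse"] > 0.05 * rms_meas:
                flags.append("large_residual")

    return RetrievalResult(
        method=method,
        names=list(names),
        values={k: float(v) for k, v in zip(names, res.x)},
        initials={k: float(v) for k, v in zip(names, x0)},
        bounds={k: (float(l), float(u)) for k, l, u in zip(names, lb, ub)},
        cost=cost,
        cost_initial=trace[0] if trace else cost,
        residual=res.fun,
        trace=trace,
        sigma_p=sigma_p,
        goodness=goodness,
        flags=flags,
        n_eval=len(trace),
        success=res.success,
    )


def _goodness(predicted, observed):
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    out = {"r2": None, "rmse": None, "rrmse": None}
    if predicted.size >= 2:
        out["rmse"] = float(np.sqrt(np.mean((predicted - observed) ** 2)))
        mo = float(np.mean(observed))
        if mo != 0:
            out["rrmse"] = out["rmse"] / mo
        if np.std(predicted) > 0 and np.std(observed) > 0:
            out["r2"] = float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    return out


# ---------------------------------------------------------------------------
# method 1: gas exchange

def retrieve_method1(
    ds: ResponseCurveDataset,
    biochem_init: BiochemParams | None = None,
) -> RetrievalResult:
    """Fit Vcmax to the measured assimilation curve (all else standard)."""
    if ds.a_meas is None:
        raise InsufficientDataError("dataset has no assimilation measurements")
    a_meas = np.asarray(ds.a_meas, float)
    valid = np.isfinite(a_meas)
    if valid.sum() < 4:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid assimilation points (need >= 4)"
        )
    base = biochem_init or BiochemParams()
    steps = [s for s, ok in zip(ds.steps, valid) if ok]
    meas = a_meas[valid]

    def simulate(p):
        b = base.replace(vcmax=float(p[0]))
        return np.array([solve_photosynthesis(b, f).a for f in steps])

    def residual(p):
        return simulate(p) - meas

    return _run_fit(
        "method1", residual, ["vcmax"], [70.0],
        [_VCMAX_BOUNDS[0]], [_VCMAX_BOUNDS[1]],
        sim_meas_fn=lambda p: (simulate(p), meas),
    )


# ---------------------------------------------------------------------------
# method 2: PAM

def retrieve_method2(
    ds: ResponseCurveDataset,
    biochem_init: BiochemParams | None = None,
) -> RetrievalResult:
    """Fit (Vcmax, Kn0, beta, gamma) to Fs/Fo and NPQ curves.

    PAM signals carry information only in ratios, so the measured Fs is
    normalized to the dark-adapted Fo, and NPQ is formed from Fm and Fm'.
    The residual concatenates the Fs/Fo and NPQ blocks with unit weights.
    """
    if ds.pam is None:
        raise InsufficientDataError("dataset has no PAM measurements")
    pam = ds.pam
    if pam.fo_dark is None or pam.fm_dark is None or pam.fo_dark <= 0:
        raise DataError("dark-adapted Fo/Fm required to form Fs/Fo and NPQ")
    if len(ds.steps) < 4:
        raise InsufficientDataError("need >= 4 PAM points")
    fs_over_fo = np.asarray(pam.fs, float) / pam.fo_dark
    fm_prime = np.asarray(pam.fm_prime, float)
    if np.any(fm_prime <= 0):
        raise DataError("nonpositive Fm' in PAM record")
    npq_meas = (pam.fm_dark - fm_prime) / fm_prime
    meas = np.concatenate([fs_over_fo, npq_meas])
    base = biochem_init or BiochemParams()

    def simulate(p):
        b = base.replace(vcmax=float(p[0]), kn0=float(p[1]),
                         beta=float(p[2]), gamma=float(p[3]))
        states = [solve_photosynthesis(b, f) for f in ds.steps]
        eps = np.array([s.epsilon for s in states])
        npq = np.array([s.npq for s in states])
        return np.concatenate([eps, npq])

    def residual(p):
        return simulate(p) - meas

    names = ["vcmax", "kn0", "beta", "gamma"]
    x0 = [70.0, 2.48, 0.114, 2.83]
    lb = [_VCMAX_BOUNDS[0], _KN0_BOUNDS[0], _BETAGAMMA_BOUNDS[0], _BETAGAMMA_BOUNDS[0]]
    ub = [_VCMAX_BOUNDS[1], _KN0_BOUNDS[1], _BETAGAMMA_BOUNDS[1], _BETAGAMMA_BOUNDS[1]]
    return _run_fit(
        "method2", residual, names, x0, lb, ub,
        sim_meas_fn=lambda p: (simulate(p), meas),
    )


# ---------------------------------------------------------------------------
# static leaf optics (once per leaf)

_STATIC_NAMES = ("cab", "ccar", "cant", "cw", "cdm", "n_layers", "cs")
_STATIC_INIT = (40.0, 10.0, 0.0, 0.009, 0.012, 1.4, 0.0)


def retrieve_static_optics(
    rho: Spectrum | None = None,
    tau: Spectrum | None = None,
    sacs: SACSet | None = None,
    eta_default: float = 0.01,
) -> tuple[LeafOpticalParams, RetrievalResult]:
    """Invert the plate model for the static leaf properties.

    Bounded least squares over the full 400-2500 nm range of whichever
    reference spectra are given (rho, tau or both), with the valid
    parameter ranges as bounds and the standard values as initials.
    Cx is fixed at 0 (dark-adapted reference) and eta at its default.
    """
    if rho is None and tau is None:
        raise DataError("need a reference rho and/or tau spectrum")
    if sacs is None:
        raise DataError("a SAC set is required")
    blocks = []
    if rho is not None:
        require_unit_interval(rho, "reference rho")
        blocks.append(("rho", rho))
    if tau is not None:
        require_unit_interval(tau, "reference tau")
        blocks.append(("tau", tau))
    for _, s in blocks:
        if not np.array_equal(s.wavelengths, sacs.wavelengths):
            raise DataError("reference spectrum is not on the model grid")
    meas = np.concatenate([s.values for _, s in blocks])

    def simulate(p):
        optics = LeafOpticalParams(
            cab=p[0], ccar=p[1], cant=p[2], cw=p[3], cdm=p[4],
            n_layers=p[5], cs=p[6], eta=eta_default, cx=0.0,
        )
        r, t = simulate_rt(optics, sacs)
        parts = []
        for kind, _ in blocks:
            parts.append(r.values if kind == "rho" else t.values)
        return np.concatenate(parts)

    def residual(p):
        return simulate(p) - meas

    lb = [OPTICAL_RANGES[n][0] for n in _STATIC_NAMES]
    ub = [OPTICAL_RANGES[n][1] for n in _STATIC_NAMES]
    result = _run_fit(
        "static_optics", residual, list(_STATIC_NAMES), list(_STATIC_INIT),
        lb, ub, sim_meas_fn=lambda p: (simulate(p), meas),
    )
    optics = LeafOpticalParams(
        cab=result["cab"], ccar=result["ccar"], cant=result["cant"],
        cw=result["cw"], cdm=result["cdm"], n_layers=result["n_layers"],
        cs=result["cs"], eta=eta_default, cx=0.0,
    )
    return optics, result


# ---------------------------------------------------------------------------
# method 3: spectra (the coupled inversion)

class Method3Problem:
    """Precompiled residual machinery for the coupled spectral inversion.

    Collects the measured band values, their per-block normalization
    constants, and the reduced wavelength grids, and exposes
    ``residual(p)`` for ``p = (vcmax, kn0, sigma_scale)``.  Reused by the
    optimizer, the Jacobian diagnostics and the RMSE profiler so they all
    see the identical cost function.
    """

    def __init__(
        self,
        ds: ResponseCurveDataset,
        static_optics: LeafOpticalParams,
        incident: Spectrum,
        sacs: SACSet,
        mode: str = "forward",
        biochem_base: BiochemParams | None = None,
        coupling_base: CouplingParams | None = None,
        doubling_levels: int = 6,
    ):
        if mode not in ("forward", "backward", "both"):
            raise DomainError(f"unknown mode '{mode}'")
        if ds.spectra is None:
            raise DataError("dataset has no spectral measurements")
        if len(ds.spectra) != len(ds.steps):
            raise DataError("one spectra set per protocol step required")
        self.mode = mode
        self.steps = list(ds.steps)
        self.static_optics = static_optics
        self.biochem_base = biochem_base or BiochemParams()
        self.coupling_base = coupling_base or CouplingParams()
        self.doubling_levels = doubling_levels

        self.use_tau = mode in ("forward", "both")
        self.use_rho = mode in ("backward", "both")

        # reduced grids: green band (+ the 565 nm normalization sample)
        # for the plate model, far-red band for the emission
        green_idx = sacs.indices_between(*GREEN_BAND)
        self.green_wl = sacs.wavelengths[green_idx]
        rt_wl = np.union1d(self.green_wl, [RHO_NORM_WL])
        self.rt_sacs = sacs.subset(rt_wl)
        self.green_sel = np.isin(rt_wl, self.green_wl)
        self.rho_norm_sel = rt_wl == RHO_NORM_WL
        chlf_idx = sacs.indices_between(*CHLF_BAND)
        self.chlf_wl = sacs.wavelengths[chlf_idx]
        self.sacs = sacs

        self.incidents = [
            scale_incident_to_ipar(incident, f.ipar) for f in self.steps
        ]

        # measured blocks
        tau_m, rho_m, cf_m, cb_m = [], [], [], []
        for sp in ds.spectra:
            if self.use_tau:
                if sp.tau is None or sp.chlf_forward is None:
                    raise DataError("mode requires tau and forward ChlF per step")
                tau_m.append(sp.tau.band_values(*GREEN_BAND))
                cf_m.append(sp.chlf_forward.band_values(*CHLF_BAND))
            if self.use_rho:
                if sp.rho is None or sp.chlf_backward is None:
                    raise DataError("mode requires rho and backward ChlF per step")
                rho_m.append(
                    sp.rho.band_values(*GREEN_BAND) - sp.rho.value_at(RHO_NORM_WL)
                )
                cb_m.append(sp.chlf_backward.band_values(*CHLF_BAND))
        self.meas_blocks = {}
        self.norms = {}
        for key, rows in (("tau", tau_m), ("rho", rho_m),
                          ("chlf_f", cf_m), ("chlf_b", cb_m)):
            if rows:
                arr = np.concatenate(rows)
                norm = float(np.mean(np.abs(arr)))
                self.norms[key] = norm if norm > 0 else 1.0
                self.meas_blocks[key] = arr

        self.measured = np.concatenate(
            [self.meas_blocks[k] / self.norms[k] for k in self._keys()]
        )
        self.block_labels = np.concatenate(
            [np.full(self.meas_blocks[k].size, k) for k in self._keys()]
        )

    def _keys(self):
        keys = []
        if self.use_tau:
            keys += ["tau", "chlf_f"]
        if self.use_rho:
            keys += ["rho", "chlf_b"]
        return keys

    def simulate(self, p) -> np.ndarray:
        """Normalized simulated vector congruent with ``self.measured``."""
        vcmax, kn0, sigma = (float(v) for v in p)
        b = self.biochem_base.replace(vcmax=vcmax, kn0=kn0)
        coup = self.coupling_base.replace(sigma_scale=sigma)
        sim = {k: [] for k in self._keys()}
        for forcing, inc in zip(self.steps, self.incidents):
            state = solve_photosynthesis(b, forcing)
            cx = cx_from_npq(state.npq, coup.slope_cx)
            eta = eta_from_epsilon(state.epsilon, coup.sigma_scale)
            optics = self.static_optics.replace(cx=cx, eta=eta)
            rho, tau = simulate_rt(optics, self.rt_sacs)
            if self.use_tau:
                sim["tau"].append(tau.values[self.green_sel])
            if self.use_rho:
                sim["rho"].append(
                    rho.values[self.green_sel]
                    - float(rho.values[self.rho_norm_sel][0])
                )
            if self.use_tau or self.use_rho:
                chlf_b, chlf_f = simulate_fluorescence(
                    optics, self.sacs, inc,
                    emission_wavelengths=self.chlf_wl,
                    doubling_levels=self.doubling_levels,
                )
            if self.use_tau:
                sim["chlf_f"].append(chlf_f.values)
            if self.use_rho:
                sim["chlf_b"].append(chlf_b.values)
        return np.concatenate(
            [np.concatenate(sim[k]) / self.norms[k] for k in self._keys()]
        )

    def residual(self, p) -> np.ndarray:
        return self.simulate(p) - self.measured


def retrieve_method3(
    ds: ResponseCurveDataset,
    static_optics: LeafOpticalParams,
    incident: Spectrum,
    sacs: SACSet,
    mode: str = "forward",
    biochem_base: BiochemParams | None = None,
    coupling_base: CouplingParams | None = None,
    doubling_levels: int = 6,
) -> RetrievalResult:
    """Fit (Vcmax, Kn0, sigma_scale) of the coupled model to band spectra.

    ``mode`` selects the measured faces: 'forward' (tau + forward ChlF,
    the chamber configuration), 'backward' (rho + backward ChlF, leaf
    clip) or 'both'.  beta and gamma stay at their standard values; the
    static optics are fixed, having been retrieved once per leaf.
    """
    problem = Method3Problem(
        ds, static_optics, incident, sacs, mode=mode,
        biochem_base=biochem_base, coupling_base=coupling_base,
        doubling_levels=doubling_levels,
    )
    names = ["vcmax", "kn0", "sigma_scale"]
    x0 = [70.0, 2.48, 0.007]
    lb = [_VCMAX_BOUNDS[0], _KN0_BOUNDS[0], _SIGMA_BOUNDS[0]]
    ub = [_VCMAX_BOUNDS[1], _KN0_BOUNDS[1], _SIGMA_BOUNDS[1]]
    return _run_fit(
        "method3", problem.residual, names, x0, lb, ub,
        sim_meas_fn=lambda p: (problem.simulate(p), problem.measured),
    )
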