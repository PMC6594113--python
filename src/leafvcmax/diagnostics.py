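"""Sensitivity and uncertainty diagnostics for the retrievals.

* Normalized Jacobians: central finite differences of a residual-space
  forward function, with each column multiplied by the span of its
  parameter (upper minus lower bound) so sensitivities of parameters of
  very different magnitude become comparable.
* Noise propagation: cov(p) = (J^T J)^-1 sigma_r^2; parameter standard
  deviations are the square roots of the diagonal.
* RMSE-vs-Vcmax profiles: the cost of each measurement block (A, green
  band, far-red fluorescence band) evaluated along a Vcmax grid with all
  other parameters fixed - a direct picture of how well each observable
  constrains Vcmax.
* Goodness of fit: squared Pearson correlation (the R^2 convention used
  throughout), RMSE and relative RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .biochem import BiochemParams
from .coupling import CouplingParams
from .errors import DataError, DomainError
from .retrieval import Method3Problem, ResponseCurveDataset
from .biochem import solve_photosynthesis

__all__ = [
    "JacobianReport",
    "UncertaintyReport",
    "jacobian_normalized",
    "propagate_error",
    "rmse_profile",
    "goodness_of_fit",
]


@dataclass
class JacobianReport:
    """Raw and span-normalized sensitivity matrices."""

    names: list
    spans: np.ndarray
    jacobian: np.ndarray  # raw residual-by-parameter matrix
    normalized: np.ndarray  # columns multiplied by spans
    block_labels: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    def column_norm(self, name: str, block: str | None = None) -> float:
        """Euclidean norm of one normalized column, optionally per block."""
        j = self.normalized[:, self.names.index(name)]
        if block is not None:
            if self.block_labels is None:
                raise DataError("no block labels attached")
            j = j[self.block_labels == block]
        return float(np.linalg.norm(j))


@dataclass
class UncertaintyReport:
    """Measurement-noise propagation to parameter standard deviations."""

    names: list
    sigma_r: float
    covariance: np.ndarray
    sigma_p: dict
    singular: list = field(default_factory=list)


def jacobian_normalized(
    forward,
    params,
    spans,
    names=None,
    bounds=None,
    block_labels=None,
    rel_step: float = 1e-3,
) -> JacobianReport:
    """Central-difference Jacobian with span-normalized columns.

    ``forward`` maps a parameter vector to a residual/output vector.  The
    step for parameter i is ``rel_step * spans[i]``.  If ``bounds`` are
    given and a parameter sits on one, a one-sided difference is used for
    that column and a warning is recorded.
    """
    p0 = np.asarray(params, dtype=float)
    spans = np.asarray(spans, dtype=float)
    if np.any(spans <= 0):
        raise DomainError("every parameter span must be > 0")
    names = list(names) if names is not None else [f"p{i}" for i in range(p0.size)]
    f0 = np.asarray(forward(p0), dtype=float)
    cols = []
    notes = []
    for i in range(p0.size):
        h = rel_step * spans[i]
        lo_ok = hi_ok = True
        if bounds is not None:
            lb, ub = bounds[0][i], bounds[1][i]
            lo_ok = p0[i] - h >= lb
            hi_ok = p0[i] + h <= ub
        if lo_ok and hi_ok:
            pp, pm = p0.copy(), p0.copy()
            pp[i] += h
            pm[i] -= h
            col = (np.asarray(forward(pp)) - np.asarray(forward(pm))) / (2 * h)
        else:
            sign = 1.0 if hi_ok else -1.0
            pp = p0.copy()
            pp[i] += sign * h
            col = sign * (np.asarray(forward(pp)) - f0) / h
            msg = f"{names[i]} on a bound: one-sided difference used"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        cols.append(col)
    jac = np.column_stack(cols)
    return JacobianReport(
        names=names,
        spans=spans,
        jacobian=jac,
        normalized=jac * spans[None, :],
        block_labels=None if block_labels is None else np.asarray(block_labels),
        warnings=notes,
    )


def propagate_error(jacobian: np.ndarray, sigma_r: float,
                    names=None) -> UncertaintyReport:
    """Eqn-style noise propagation: cov = (J^T J)^-1 sigma_r^2.

    Rank-deficient J^T J falls back to the pseudo-inverse and reports the
    parameter names dominating the singular directions instead of raising.
    """
    j = np.asarray(jacobian, dtype=float)
    names = list(names) if names is not None else [f"p{i}" for i in range(j.shape[1])]
    jtj = j.T @ j
    u, s, vt = np.linalg.svd(jtj)
    tol = s[0] * 1e-12 if s.size and s[0] > 0 else 0.0
    singular_names = []
    if s.size == 0 or s[-1] <= tol:
        s_inv = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0), 0.0)
        inv = (vt.T * s_inv) @ u.T
        for k in np.nonzero(s <= tol)[0]:
            singular_names.append(names[int(np.argmax(np.abs(vt[k])))])
    else:
        inv = np.linalg.inv(jtj)
    cov = inv * float(sigma_r) ** 2
    cov = 0.5 * (cov + cov.T)
    sigma_p = {
        n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)
    }
    return UncertaintyReport(
        names=names,
        sigma_r=float(sigma_r),
        covariance=cov,
        sigma_p=sigma_p,
        singular=singular_names,
    )


def rmse_profile(
    problem: Method3Problem,
    vcmax_grid,
    ds: ResponseCurveDataset | None = None,
    kn0: float | None = None,
    sigma_scale: float | None = None,
) -> dict:
    """RMSE of each measurement block along a Vcmax grid.

    With all other fitted parameters held fixed (defaults: the problem's
    base Kn0 and sigma_scale), evaluates the coupled forward model at
    each grid Vcmax and reports the RMSE of the green-band block, the
    fluorescence-band block and - when the dataset carries assimilation
    measurements - the gas-exchange block, plus the argmin of each curve.
    """
    grid = np.asarray(vcmax_grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 250):
        raise DomainError("Vcmax grid must lie within [0, 250]")
    kn0 = problem.biochem_base.kn0 if kn0 is None else kn0
    sigma = problem.coupling_base.sigma_scale if sigma_scale is None else sigma_scale
    labels = problem.block_labels
    spectral = {"tau": [], "rho": [], "chlf_f": [], "chlf_b": []}
    a_curve = []
    a_meas = None
    if ds is not None and ds.a_meas is not None:
        a_meas = np.asarray(ds.a_meas, float)
    for v in grid:
        sim = problem.simulate([v, kn0, sigma])
        diff = sim - problem.measured
        for key in list(spectral):
            sel = labels == key
            if sel.any():
                spectral[key].append(float(np.sqrt(np.mean(diff[sel] ** 2))))
        if a_meas is not None:
            b = problem.biochem_base.replace(vcmax=float(v), kn0=kn0)
            a_sim = np.array(
                [solve_photosynthesis(b, f).a for f in problem.steps]
            )
            a_curve.append(float(np.sqrt(np.mean((a_sim - a_meas) ** 2))))
    out = {"vcmax_grid": grid, "argmin": {}}
    for key, vals in spectral.items():
        if vals:
            arr = np.asarray(vals)
            out[key] = arr
            out["argmin"][key] = float(grid[int(np.argmin(arr))])
    if a_curve:
        arr = np.asarray(a_curve)
        out["a"] = arr
        out["argmin"]["a"] = float(grid[int(np.argmin(arr))])
    return out


def goodness_of_fit(predicted, observed) -> dict:
    """R^2 (squared Pearson correlation), RMSE and relative RMSE.

    R^2 is the square of the correlation coefficient, so a perfectly
    anti-correlated pair also scores 1; zero variance in either vector
    makes the correlation undefined and R^2 is reported as None.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise DataError("need two equal-length vectors of length >= 2")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    mean_o = float(np.mean(o))
    rrmse = rmse / mean_o if mean_o != 0 else None
    if np.std(p) == 0 or np.std(o) == 0:
        r2 = None
    else:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    return {"r2": r2, "rmse": rmse, "rrmse": rrmse}
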