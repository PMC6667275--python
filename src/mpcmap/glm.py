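"""Per-node general linear models for block / event-related BOLD runs.

The response model for each condition is a boxcar at the condition's
onsets/durations convolved with a gamma-variate haemodynamic response
function (HRF), sampled at the repetition time (TR).  Nuisance structure is a
Legendre polynomial drift basis plus optional motion regressors.  Fitting is
ordinary least squares, optionally with single-pass Cochrane-Orcutt AR(1)
prewhitening (pooled lag-1 residual autocorrelation across nodes), which
approximates a generalized-least-squares fit with an estimated temporal
autocorrelation.

All amplitudes are in fraction-of-run-mean units: time series are divided by
their own run mean before fitting (see :func:`scale_by_run_mean`), so a beta
of 0.01 is a 1% signal change and "baseline" is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy import stats


@dataclass(frozen=True)
class HRFSpec:
    """Gamma-variate HRF ``h(t) ~ t**a * exp(-t/b)``, normalized to unit peak.

    The analytic peak is at ``t* = a * b`` (4.70 s for the defaults, the
    conventional gamma used for block designs).
    """

    a: float = 8.6        # shape (dimensionless)
    b: float = 0.547      # scale (s)
    length: float = 30.0  # kernel support (s)

    @property
    def peak_time(self) -> float:
        return self.a * self.b

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("HRF shape and scale must be positive")
        if self.length <= 0:
            raise ValueError("HRF kernel length must be positive")


def gamma_hrf(spec: HRFSpec = HRFSpec(), tr: float = 2.0) -> np.ndarray:
    """Sample the gamma HRF at TR resolution.

    Normalization divides by the analytic peak value h(a*b), so the
    continuous kernel has max exactly 1 (sampled values are <= 1 when the
    peak falls between samples).  h(0) = 0.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, spec.length + 1e-9, tr)
    if t.size < 2:
        raise ValueError("kernel length must cover at least one TR")
    with np.errstate(divide="ignore", invalid="ignore"):
        # h(t) / h(ab) = (t/ab)^a * exp((ab - t)/b), stable in log space
        logh = spec.a * np.log(t / spec.peak_time) + (spec.peak_time - t) / spec.b
    h = np.exp(logh)
    h[t == 0] = 0.0
    return h


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with named, partitioned columns."""

    matrix: np.ndarray
    names: list[str]
    conditions: list[str]          # task column names, in column order
    task_cols: np.ndarray          # integer indices of task columns

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def condition_index(self, condition: str) -> int:
        try:
            return int(self.task_cols[self.conditions.index(condition)])
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}; "
                           f"have {self.conditions}") from None


def _boxcar(onsets: np.ndarray, durations: np.ndarray, n_volumes: int,
            tr: float) -> np.ndarray:
    box = np.zeros(n_volumes)
    for onset, dur in zip(onsets, durations):
        if onset < 0:
            raise ValueError(f"negative event onset {onset}")
        if onset + dur > n_volumes * tr + 1e-9:
            warnings.warn(
                f"event at {onset:g}s (duration {dur:g}s) extends past run end; "
                "truncating", stacklevel=3)
        i0 = int(round(onset / tr))
        i1 = int(np.ceil((onset + dur) / tr - 1e-9))
        box[i0:min(i1, n_volumes)] = 1.0
    return box


def build_design(events, n_volumes: int, tr: float,
                 hrf: np.ndarray | None = None,
                 drift_order: int = 4,
                 nuisance: np.ndarray | None = None,
                 conditions: list[str] | None = None) -> DesignMatrix:
    """Build a GLM design: one HRF-convolved boxcar per condition + nuisance.

    Parameters
    ----------
    events
        DataFrame with columns ``onset``, ``duration``, ``trial_type``
        (seconds).  May be empty, in which case only drift/nuisance columns
        are produced.
    hrf
        Sampled HRF kernel (from :func:`gamma_hrf` at this run's TR).
        Defaults to the standard gamma at ``tr``.
    drift_order
        Highest Legendre polynomial order; orders 0..drift_order are
        included (order 0 is the intercept).
    nuisance
        Optional (n_volumes, k) matrix appended verbatim (e.g. motion).
    conditions
        Task column order; defaults to sorted unique trial types.
    """
    if hrf is None:
        hrf = gamma_hrf(HRFSpec(), tr)
    cols, names = [], []
    ev_conditions: list[str] = []
    if len(events) > 0:
        present = list(dict.fromkeys(events["trial_type"]))
        ev_conditions = conditions if conditions is not None else sorted(present)
        missing = set(present) - set(ev_conditions)
        if missing:
            raise ValueError(f"events contain unknown conditions {sorted(missing)}")
        for cond in ev_conditions:
            sel = events[events["trial_type"] == cond]
            if len(sel) == 0:
                raise ValueError(f"condition {cond!r} has no events (all-zero "
                                 "task column)")
            box = _boxcar(sel["onset"].to_numpy(float),
                          sel["duration"].to_numpy(float), n_volumes, tr)
            cols.append(np.convolve(box, hrf)[:n_volumes])
            names.append(cond)
    task_cols = np.arange(len(cols))
    # Legendre drift basis on [-1, 1]; order 0 doubles as the intercept
    x = np.linspace(-1.0, 1.0, n_volumes)
    drift = legendre.legvander(x, drift_order)
    for k in range(drift_order + 1):
        cols.append(drift[:, k])
        names.append(f"drift_{k}")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance rows must equal run volume count")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(f"nuisance_{k}")
    return DesignMatrix(matrix=np.column_stack(cols), names=names,
                        conditions=ev_conditions, task_cols=task_cols)


def scale_by_run_mean(data: np.ndarray) -> np.ndarray:
    """Divide each node's series by its own run mean (mean becomes 1).

    Nodes with non-positive mean are NaN-masked with a warning.
    """
    data = np.asarray(data, float)
    mean = data.mean(axis=0)
    bad = mean <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} node(s) with non-positive run mean "
                      "masked out", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = data / mean
    scaled[:, bad] = np.nan
    return scaled


@dataclass
class GLMResult:
    """Per-node GLM fit: coefficients, their SEs, and t-versus-baseline."""

    beta: np.ndarray               # (p, n_nodes)
    se: np.ndarray                 # (p, n_nodes)
    sigma2: np.ndarray             # (n_nodes,) residual variance
    dof: int                       # residual degrees of freedom
    names: list[str]
    conditions: list[str]
    task_cols: np.ndarray
    rho: float = 0.0               # AR(1) coefficient used for prewhitening

    def condition_betas(self) -> np.ndarray:
        """(n_conditions, n_nodes) task coefficients in condition order."""
        return self.beta[self.task_cols]

    def t_map(self, condition: str) -> np.ndarray:
        i = self._cond_index(condition)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.beta[i] / self.se[i]
        t[~np.isfinite(self.se[i]) | (self.se[i] == 0)] = np.nan
        return t

    def _cond_index(self, condition: str) -> int:
        try:
            return int(self.task_cols[self.conditions.index(condition)])
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}; "
                           f"have {self.conditions}") from None


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, r, piv = _qr_pivot(X)
        keep = np.abs(np.diag(r)) > np.abs(r[0, 0]) * 1e-10
        bad = [names[piv[i]] for i in range(X.shape[1]) if i >= keep.sum()]
        raise np.linalg.LinAlgError(
            f"design is rank deficient ({rank}/{X.shape[1]}); collinear "
            f"columns involve: {bad}")


def _qr_pivot(X):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def _ols(X: np.ndarray, Y: np.ndarray):
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return beta, se, sigma2, resid, dof


def fit_glm(data: np.ndarray, design: DesignMatrix,
            ar_order: int = 0) -> GLMResult:
    """Fit the GLM at every node.

    ``ar_order=0`` is plain OLS via the normal equations.  ``ar_order=1``
    runs OLS once, pools the lag-1 autocorrelation of the residuals across
    all nodes, applies the Cochrane-Orcutt transform (first row scaled by
    sqrt(1-rho^2)) to data and design, and refits.
    """
    if ar_order not in (0, 1):
        raise ValueError("ar_order must be 0 or 1")
    Y = np.asarray(data, float)
    X = design.matrix
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("data rows must match design rows")
    _check_rank(X, design.names)

    valid = ~np.isnan(Y).any(axis=0)
    Yv = Y[:, valid]
    beta, se, sigma2, resid, dof = _ols(X, Yv)
    rho = 0.0
    if ar_order == 1:
        num = (resid[1:] * resid[:-1]).sum()
        den = (resid ** 2).sum()
        rho = float(num / den) if den > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
        c = np.sqrt(1.0 - rho ** 2)
        Xw = np.vstack([X[:1] * c, X[1:] - rho * X[:-1]])
        Yw = np.vstack([Yv[:1] * c, Yv[1:] - rho * Yv[:-1]])
        beta, se, sigma2, _, dof = _ols(Xw, Yw)

    def expand(a, fill=np.nan):
        out = np.full(a.shape[:-1] + (Y.shape[1],), fill)
        out[..., valid] = a
        return out

    return GLMResult(beta=expand(beta), se=expand(se), sigma2=expand(sigma2),
                     dof=dof, names=design.names,
                     conditions=design.conditions,
                     task_cols=design.task_cols, rho=rho)


def condition_t_map(result: GLMResult, condition: str) -> np.ndarray:
    """Per-node t-versus-baseline map for one condition (NaN where masked)."""
    return result.t_map(condition)


def combine_runs(results: list[GLMResult]) -> GLMResult:
    """Fixed-effects combination of per-run fits for one participant.

    Betas are averaged across runs; the combined SE is
    ``sqrt(sum(se_r^2)) / R`` and t = beta / SE with summed dof.
    """
    if not results:
        raise ValueError("no runs to combine")
    first = results[0]
    for r in results[1:]:
        if r.conditions != first.conditions:
            raise ValueError("runs have differing condition sets")
    R = len(results)
    beta = np.mean([r.beta[r.task_cols] for r in results], axis=0)
    se = np.sqrt(np.sum([r.se[r.task_cols] ** 2 for r in results], axis=0)) / R
    sigma2 = np.mean([r.sigma2 for r in results], axis=0)
    dof = sum(r.dof for r in results)
    n_cond = len(first.conditions)
    return GLMResult(beta=beta, se=se, sigma2=sigma2, dof=dof,
                     names=list(first.conditions),
                     conditions=list(first.conditions),
                     task_cols=np.arange(n_cond), rho=np.nan)


def t_critical(alpha: float, dof: int) -> float:
    """Two-sided t critical value."""
    return float(stats.t.ppf(1 - alpha / 2, dof))
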