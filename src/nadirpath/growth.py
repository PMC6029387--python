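"""Cubic random-effects growth model for early postnatal weight.

Each newborn contributes two weights: birthweight, taken as an observation
of the subject's curve at t = 0, and one measurement at an irregular time
t in the first days of life.  The population curve is a cubic polynomial in
hours since birth; subjects deviate from it through a random intercept and
a random slope,

    weight_i(t) = b0 + b1*t + b2*t^2 + b3*t^3 + u0_i + u1_i*t + eps,

with (u0, u1) bivariate normal and eps i.i.d. normal measurement error.
The population *nadir* is the interior minimum of the fixed cubic; newborn
weight change (NWC) is the percentage change from birthweight to the
predicted weight at the nadir.

Fitting is by maximum likelihood with the fixed effects profiled out: each
subject's marginal covariance is a closed-form 2x2 matrix, so the profiled
log-likelihood over the four variance parameters is evaluated in a single
vectorised pass.  Per-subject effects are empirical-Bayes (BLUP)
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "GrowthCurveFit",
    "CascadeReport",
    "fit_cubic_lmm",
    "population_nadir",
    "predict_weight",
    "compute_nwc",
    "hourly_change_rate",
    "apply_exclusion_cascade",
    "nwc_table",
    "EXCLUSION_REASONS",
]

#: cascade stages, in the order they are applied
EXCLUSION_REASONS = (
    "missing_time",
    "after_96h",
    "outlier_low",
    "outlier_high",
    "incomplete_covariates",
)

_DEFAULT_COVARIATES = ("maternal_education", "pre_pregnancy_bmi", "gestational_age")


class ConvergenceError(RuntimeError):
    """Raised when the profiled-likelihood optimisation does not converge."""


@dataclass
class GrowthCurveFit:
    """Maximum-likelihood fit of the cubic random-effects growth model.

    Attributes
    ----------
    beta : ndarray, shape (4,)
        Fixed cubic coefficients (g, g/h, g/h^2, g/h^3).
    re_cov : ndarray, shape (2, 2)
        Random intercept/slope covariance matrix (g^2, g^2/h, g^2/h^2).
    sd_resid : float
        Residual (measurement-error) SD in grams.
    ranef : pandas.DataFrame
        Per-subject empirical-Bayes effects, indexed by id, columns
        ``b0`` (g) and ``b1`` (g/h).
    beta_cov : ndarray, shape (4, 4)
        GLS covariance of the fixed effects at the ML variance estimates.
    loglik : float
        Maximised log-likelihood.
    converged : bool
    singular_slope : bool
        True when the random-slope SD collapsed and the model fell back
        to a random-intercept-only fit.
    n_subjects : int
    """

    beta: np.ndarray
    re_cov: np.ndarray
    sd_resid: float
    ranef: pd.DataFrame
    beta_cov: np.ndarray
    loglik: float
    converged: bool
    n_subjects: int
    singular_slope: bool = False
    n_iter: int = 0

    @property
    def nadir_time(self) -> float:
        return population_nadir(self)

    def fixed_curve(self, t):
        t = np.asarray(t, dtype=float)
        return self.beta[0] + self.beta[1] * t + self.beta[2] * t**2 + self.beta[3] * t**3


def _design(records: pd.DataFrame):
    """Stack the two observations per newborn into (n,2,·) arrays."""
    t = records["meas_time"].to_numpy(dtype=float)
    y = np.column_stack(
        [records["birthweight"].to_numpy(dtype=float), records["meas_weight"].to_numpy(dtype=float)]
    )
    n = len(t)
    X = np.zeros((n, 2, 4))
    X[:, 0, 0] = 1.0
    X[:, 1, 0] = 1.0
    X[:, 1, 1] = t
    X[:, 1, 2] = t * t
    X[:, 1, 3] = t * t * t
    return t, X, y


def _marginal_inverse(t, g00, g01, g11, s2):
    """Inverse and log-determinant of each subject's 2x2 marginal covariance."""
    v00 = g00 + s2
    v01 = g00 + g01 * t
    v11 = g00 + 2.0 * g01 * t + g11 * t * t + s2
    det = v00 * v11 - v01 * v01
    if np.any(det <= 0) or np.any(v00 <= 0):
        return None
    Vinv = np.empty((len(t), 2, 2))
    Vinv[:, 0, 0] = v11 / det
    Vinv[:, 0, 1] = Vinv[:, 1, 0] = -v01 / det
    Vinv[:, 1, 1] = v00 / det
    return Vinv, np.log(det)


def _gls(X, y, Vinv):
    XtVi = np.einsum("nji,njk->nik", X, Vinv)
    A = np.einsum("nik,nkj->ij", XtVi, X)
    c = np.einsum("nik,nk->i", XtVi, y)
    beta = np.linalg.solve(A, c)
    resid = y - np.einsum("nij,j->ni", X, beta)
    quad = np.einsum("ni,nij,nj->", resid, Vinv, resid)
    return beta, A, resid, quad


_SD_FLOOR = 1e-6  # keeps the likelihood bounded on degenerate (noise-free) data


def _unpack(theta, slope: bool):
    if slope:
        s0, s1, sr = (np.exp(np.clip(theta[i], -30.0, 30.0)) + _SD_FLOOR for i in (0, 1, 3))
        rho = np.tanh(theta[2])
        return s0 * s0, rho * s0 * s1, s1 * s1, sr * sr
    s0, sr = (np.exp(np.clip(theta[i], -30.0, 30.0)) + _SD_FLOOR for i in (0, 1))
    return s0 * s0, 0.0, 0.0, sr * sr


def fit_cubic_lmm(records: pd.DataFrame, *, max_iter: int = 5000) -> GrowthCurveFit:
    """Fit the cubic mixed model by profiled maximum likelihood.

    Parameters
    ----------
    records : DataFrame
        One row per newborn with columns ``id``, ``birthweight``,
        ``meas_time`` (hours, > 0) and ``meas_weight``.  Rows with a
        missing time or weight must be excluded beforehand
        (see :func:`apply_exclusion_cascade`).

    Returns
    -------
    GrowthCurveFit

    Notes
    -----
    ML rather than REML, so log-likelihoods are comparable across mean
    structures.  If the random-slope SD collapses towards zero the model
    is refitted with a random intercept only and flagged
    ``singular_slope``.
    """
    required = {"id", "birthweight", "meas_time", "meas_weight"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records[["birthweight", "meas_time", "meas_weight"]].isna().any().any():
        raise ValueError("records contain missing weights or times; apply the exclusion cascade first")
    if len(records) < 50:
        warnings.warn("fewer than 50 subjects: variance components may be unstable")

    t, X, y = _design(records)
    n = len(t)
    const = 2.0 * n * np.log(2.0 * np.pi)

    def nll(theta, slope=True):
        g00, g01, g11, s2 = _unpack(theta, slope)
        out = _marginal_inverse(t, g00, g01, g11, s2)
        if out is None:
            return 1e12
        Vinv, logdet = out
        try:
            _, _, _, quad = _gls(X, y, Vinv)
        except np.linalg.LinAlgError:
            return 1e12
        return 0.5 * (const + logdet.sum() + quad)

    # moment-based starting values: spread of birthweight vs residual scale
    s0_init = max(np.std(y[:, 0]) * 0.8, 1.0)
    sr_init = max(np.std(y[:, 0]) * 0.15, 1.0)
    x0 = np.array([np.log(s0_init), 0.0, 0.0, np.log(sr_init)])
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-10, maxiter=max_iter, maxfev=2 * max_iter),
    )
    theta = res.x
    singular = np.exp(theta[1]) < 1e-4  # random-slope SD in g/h
    if singular:
        warnings.warn("random-slope variance is singular; refitting with random intercept only")
        res = minimize(
            lambda th: nll(th, slope=False),
            np.array([theta[0], np.log(np.exp(theta[3]) + 1e-8)]),
            method="Nelder-Mead",
            options=dict(xatol=1e-8, fatol=1e-10, maxiter=max_iter),
        )
        theta = res.x
    if not res.success:
        raise ConvergenceError(
            f"growth-model likelihood failed to converge after {res.nit} iterations "
            f"(final nll={res.fun:.6g})"
        )

    g00, g01, g11, s2 = _unpack(theta, slope=not singular)
    Vinv, logdet = _marginal_inverse(t, g00, g01, g11, s2)
    beta, A, resid, quad = _gls(X, y, Vinv)
    loglik = -0.5 * (const + logdet.sum() + quad)

    # BLUP: u_i = G Z_i' Vinv_i r_i  with Z_i = [[1,0],[1,t]]
    G = np.array([[g00, g01], [g01, g11]])
    Z = np.zeros((n, 2, 2))
    Z[:, 0, 0] = 1.0
    Z[:, 1, 0] = 1.0
    Z[:, 1, 1] = t
    u = np.einsum("ij,nkj,nkl,nl->ni", G, Z, Vinv, resid)
    ranef = pd.DataFrame({"b0": u[:, 0], "b1": u[:, 1]}, index=pd.Index(records["id"], name="id"))

    return GrowthCurveFit(
        beta=beta,
        re_cov=G,
        sd_resid=float(np.sqrt(s2)),
        ranef=ranef,
        beta_cov=np.linalg.inv(A),
        loglik=float(loglik),
        converged=bool(res.success),
        n_subjects=n,
        singular_slope=bool(singular),
        n_iter=int(res.nit),
    )


def population_nadir(fit, *, t_max: float = 96.0) -> float:
    """Time (hours) of the interior minimum of the fixed cubic curve.

    Solves ``b1 + 2*b2*t + 3*b3*t^2 = 0`` in closed form and returns the
    root in ``(0, t_max]`` at which the second derivative is positive.
    """
    beta = fit.beta if isinstance(fit, GrowthCurveFit) else np.asarray(fit, dtype=float)
    b1, b2, b3 = beta[1], beta[2], beta[3]
    if b3 == 0.0:
        if b2 <= 0.0:
            raise ValueError("no interior minimum: curve has no positive curvature")
        roots = np.array([-b1 / (2.0 * b2)])
    else:
        disc = 4.0 * b2 * b2 - 12.0 * b3 * b1
        if disc < 0:
            raise ValueError("no interior minimum: derivative has no real root")
        sq = np.sqrt(disc)
        roots = np.array([(-2.0 * b2 - sq) / (6.0 * b3), (-2.0 * b2 + sq) / (6.0 * b3)])
    curv = 2.0 * b2 + 6.0 * b3 * roots
    ok = roots[(roots > 0.0) & (roots <= t_max) & (curv > 0.0)]
    if ok.size == 0:
        raise ValueError(f"no interior minimum in (0, {t_max}]")
    # a cubic has at most one minimum; assert rather than silently pick
    assert ok.size == 1, "multiple admissible minima for a cubic derivative"
    return float(ok[0])


def predict_weight(fit: GrowthCurveFit, ids, t) -> np.ndarray:
    """Predicted weight (g) for subjects ``ids`` at time(s) ``t`` (hours).

    Fixed cubic plus the subject's empirical-Bayes intercept and slope.
    """
    ids = np.atleast_1d(ids)
    unknown = [i for i in ids if i not in fit.ranef.index]
    if unknown:
        raise KeyError(f"unknown subject id(s): {unknown[:5]}")
    u = fit.ranef.loc[ids]
    t = np.broadcast_to(np.asarray(t, dtype=float), (len(ids),))
    pred = fit.fixed_curve(t) + u["b0"].to_numpy() + u["b1"].to_numpy() * t
    return pred if pred.size > 1 else float(pred[0])


def compute_nwc(birthweight, est_min_weight):
    """Newborn weight change as a signed percentage of birthweight.

    ``(est_min_weight - birthweight) / birthweight * 100``; negative
    values are weight loss.
    """
    bw = np.asarray(birthweight, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("birthweight must be positive")
    out = (np.asarray(est_min_weight, dtype=float) - bw) / bw * 100.0
    return float(out) if out.ndim == 0 else out


def hourly_change_rate(birthweight, meas_weight, meas_time):
    """Observed weight change in percent of birthweight per hour."""
    t = np.asarray(meas_time, dtype=float)
    if np.any(t[~np.isnan(t)] <= 0):
        raise ValueError("measurement time must be positive")
    return compute_nwc(birthweight, meas_weight) / t


@dataclass
class CascadeReport:
    """Accounting of the sample-exclusion cascade.

    ``stages`` holds ``(label, n_excluded, n_remaining)`` in application
    order; counts are conserved at every stage.
    """

    n_input: int
    stages: list = field(default_factory=list)
    fences: tuple | None = None
    outlier_counts: tuple = (0, 0)  # (below low fence, above high fence)

    @property
    def n_remaining(self) -> int:
        return self.stages[-1][2] if self.stages else self.n_input

    def add(self, label: str, n_excluded: int, n_remaining: int) -> None:
        self.stages.append((label, int(n_excluded), int(n_remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_excluded", "n_remaining"])

    def to_text(self) -> str:
        lines = [f"eligible newborns: n = {self.n_input}"]
        for label, n_exc, n_rem in self.stages:
            lines.append(f"  |-- excluded, {label}: n = {n_exc}")
            lines.append(f"  v   remaining: n = {n_rem}")
        if self.fences is not None:
            lines.append(
                f"outlier fences (%/h): low {self.fences[0]:.4g}, high {self.fences[1]:.4g}"
            )
        return "\n".join(lines)


def apply_exclusion_cascade(
    records: pd.DataFrame,
    *,
    t_max: float = 96.0,
    fence_multiplier: float = 3.0,
    fixed_fences: tuple | None = None,
    required_covariates=_DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the analysis-sample exclusion cascade, in order.

    Stages: missing measurement time -> measured after ``t_max`` hours ->
    outlying hourly weight-change rate (Tukey fences Q1 - k*IQR /
    Q3 + k*IQR with k = ``fence_multiplier``, computed on the records
    still in the sample, or ``fixed_fences=(low, high)`` in %/h) ->
    incomplete covariates.  Each excluded row carries the first reason
    that triggered.

    Returns the retained rows and a :class:`CascadeReport`; the input
    also gains an ``exclusion_reason`` column in the returned copy.
    """
    if len(records) == 0:
        raise ValueError("empty input")
    rec = records.copy()
    rec["exclusion_reason"] = "none"
    report = CascadeReport(n_input=len(rec))

    alive = rec["exclusion_reason"].eq("none")

    m = alive & rec["meas_time"].isna()
    rec.loc[m, "exclusion_reason"] = "missing_time"
    alive &= ~m
    report.add("missing time of measurement", m.sum(), alive.sum())

    m = alive & (rec["meas_time"] > t_max)
    rec.loc[m, "exclusion_reason"] = "after_96h"
    alive &= ~m
    report.add(f"measured after {t_max:g} h", m.sum(), alive.sum())

    rates = pd.Series(
        hourly_change_rate(
            rec.loc[alive, "birthweight"], rec.loc[alive, "meas_weight"], rec.loc[alive, "meas_time"]
        ),
        index=rec.index[alive],
    )
    if fixed_fences is not None:
        lo, hi = fixed_fences
    else:
        q1, q3 = np.nanquantile(rates, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
    report.fences = (float(lo), float(hi))
    low_ids = rates.index[rates < lo]
    high_ids = rates.index[rates > hi]
    rec.loc[low_ids, "exclusion_reason"] = "outlier_low"
    rec.loc[high_ids, "exclusion_reason"] = "outlier_high"
    report.outlier_counts = (len(low_ids), len(high_ids))
    alive = rec["exclusion_reason"].eq("none")
    report.add(
        f"outlying change rate (<{lo:.3g} or >{hi:.3g} %/h)",
        len(low_ids) + len(high_ids),
        alive.sum(),
    )

    cols = [c for c in required_covariates if c in rec.columns]
    if cols:
        m = alive & rec[cols].isna().any(axis=1)
        rec.loc[m, "exclusion_reason"] = "incomplete_covariates"
        alive &= ~m
        report.add("incomplete key variables", m.sum(), alive.sum())

    kept = rec.loc[alive].drop(columns="exclusion_reason")
    return kept, report


def nwc_table(fit: GrowthCurveFit, records: pd.DataFrame, nadir_time: float | None = None) -> pd.DataFrame:
    """Per-newborn NWC results at the population nadir.

    Returns a frame with ``id``, ``est_min_weight`` (g), ``nwc`` (% of
    birthweight) and ``hourly_rate`` (%/h, from the observed weights).
    """
    if nadir_time is None:
        nadir_time = population_nadir(fit)
    ids = records["id"].to_numpy()
    est = predict_weight(fit, ids, nadir_time)
    est = np.atleast_1d(est)
    bw = records["birthweight"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "id": ids,
            "est_min_weight": est,
            "nwc": compute_nwc(bw, est),
            "hourly_rate": hourly_change_rate(
                bw, records["meas_weight"].to_numpy(dtype=float), records["meas_time"].to_numpy(dtype=float)
            ),
        }
    )
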