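"""Recursive path models estimated by full-information maximum likelihood.

The association models are systems of linear structural equations among
observed variables with a directed acyclic structure: an outcome trait
regressed on newborn weight change (NWC) and confounders, optionally with
the same trait at an earlier age as a mediator.  Estimation maximises the
multivariate-normal likelihood summed over missingness patterns (FIML),
so incomplete rows contribute their observed marginals — valid under
missing-at-random.

Exogenous variables' means and covariance are estimated jointly as
auxiliary parameters (required for FIML when exogenous values are
missing); the covariance is parameterised by its Cholesky factor with a
log diagonal, residual variances by their log, so the optimisation is
unconstrained.  Model fit is judged against the saturated model
(chi-square) and the independence baseline (CFI/TLI), plus RMSEA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import t as t_dist

__all__ = [
    "Edge",
    "PathModelSpec",
    "PathFitResult",
    "build_model",
    "implied_moments",
    "fiml_loglik",
    "fit",
    "bootstrap_ci",
    "fit_indices",
    "effect_decomposition",
    "pearson_matrix",
]

CONFOUNDERS = ("maternal_education", "pre_pregnancy_bmi", "gestational_age", "birthweight")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Edge:
    parent: str
    child: str
    label: str = ""


@dataclass
class PathModelSpec:
    """A recursive (acyclic) path model over observed variables.

    ``equations`` maps each endogenous variable to its list of incoming
    :class:`Edge`; every other variable is exogenous.  ``exog_cov`` is
    ``"full"`` (saturated exogenous block) or ``"diagonal"`` (used for
    the independence baseline model).
    """

    exogenous: list
    equations: dict
    exog_cov: str = "full"

    def __post_init__(self):
        order = self._toposort()
        object.__setattr__(self, "_order", order)

    @property
    def endogenous(self):
        return list(self.equations)

    @property
    def variables(self):
        return list(self.exogenous) + list(self._order)

    def _toposort(self):
        # Kahn's algorithm over endogenous variables only
        known = set(self.exogenous)
        for child, edges in self.equations.items():
            if not edges:
                raise ValueError(f"endogenous variable {child!r} has no parents")
            for e in edges:
                if e.child != child:
                    raise ValueError("edge child does not match equation key")
        remaining = dict(self.equations)
        order = []
        while remaining:
            ready = [
                c for c, edges in remaining.items() if all(e.parent in known for e in edges)
            ]
            if not ready:
                raise ValueError("path model is cyclic or references unknown variables")
            for c in ready:
                order.append(c)
                known.add(c)
                del remaining[c]
        return order

    def n_parameters(self) -> int:
        k = len(self.exogenous)
        exog = 2 * k if self.exog_cov == "diagonal" else k + k * (k + 1) // 2
        endo = sum(2 + len(edges) for edges in self.equations.values())
        return exog + endo

    def to_yaml(self, path) -> None:
        import yaml

        doc = {
            "exogenous": list(self.exogenous),
            "exog_cov": self.exog_cov,
            "equations": {
                child: [{"parent": e.parent, "label": e.label} for e in edges]
                for child, edges in self.equations.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathModelSpec":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        equations = {
            child: [Edge(d["parent"], child, d.get("label", "")) for d in edges]
            for child, edges in doc["equations"].items()
        }
        return cls(
            exogenous=list(doc["exogenous"]),
            equations=equations,
            exog_cov=doc.get("exog_cov", "full"),
        )

    def coefficient_index(self):
        """Rows describing every packed parameter, in packing order."""
        rows = []
        k = len(self.exogenous)
        for v in self.exogenous:
            rows.append(dict(role="exog_mean", child=v, parent="", label=""))
        if self.exog_cov == "diagonal":
            for v in self.exogenous:
                rows.append(dict(role="exog_logsd", child=v, parent="", label=""))
        else:
            for i in range(k):
                for j in range(i + 1):
                    rows.append(
                        dict(
                            role="exog_chol",
                            child=self.exogenous[i],
                            parent=self.exogenous[j],
                            label="",
                        )
                    )
        for child in self._order:
            rows.append(dict(role="intercept", child=child, parent="", label="b0"))
            for e in self.equations[child]:
                rows.append(dict(role="coef", child=child, parent=e.parent, label=e.label))
            rows.append(dict(role="resid_logsd", child=child, parent="", label=""))
        return pd.DataFrame(rows)


def saturated_spec(variables) -> PathModelSpec:
    return PathModelSpec(exogenous=list(variables), equations={})


def baseline_spec(variables) -> PathModelSpec:
    return PathModelSpec(exogenous=list(variables), equations={}, exog_cov="diagonal")


def build_model(trait: str, variant: str) -> PathModelSpec:
    """Path model for one cardio-metabolic trait.

    Variants
    --------
    ``model1_age4``
        total association of NWC with the age-4 trait, adjusted for
        maternal education, pre-pregnancy BMI, gestational age and
        birthweight.
    ``model1_age7``
        total association with the age-7 trait (no gestational age).
    ``model2_age7``
        direct association with the age-7 trait, additionally adjusted
        for the same trait at age 4 (the tracking edge, labelled b5).
    ``joint``
        the mediation system: the age-4 equation plus the age-7
        equation, giving direct/indirect/total decomposition of the NWC
        effect.
    """
    z4, z7 = f"{trait}_z4", f"{trait}_z7"
    eq_age4 = [
        Edge("nwc", z4, "b1"),
        Edge("maternal_education", z4, "b2"),
        Edge("pre_pregnancy_bmi", z4, "b3"),
        Edge("gestational_age", z4, "b4"),
        Edge("birthweight", z4, "b5"),
    ]
    eq_age7_m1 = [
        Edge("nwc", z7, "b1"),
        Edge("maternal_education", z7, "b2"),
        Edge("pre_pregnancy_bmi", z7, "b3"),
        Edge("birthweight", z7, "b4"),
    ]
    eq_age7_m2 = eq_age7_m1 + [Edge(z4, z7, "b5")]
    confs = list(CONFOUNDERS)
    if variant == "model1_age4":
        return PathModelSpec(exogenous=["nwc"] + confs, equations={z4: eq_age4})
    if variant == "model1_age7":
        exog = ["nwc"] + [c for c in confs if c != "gestational_age"]
        return PathModelSpec(exogenous=exog, equations={z7: eq_age7_m1})
    if variant == "model2_age7":
        exog = ["nwc"] + [c for c in confs if c != "gestational_age"] + [z4]
        return PathModelSpec(exogenous=exog, equations={z7: eq_age7_m2})
    if variant == "joint":
        return PathModelSpec(
            exogenous=["nwc"] + confs,
            equations={z4: eq_age4, z7: eq_age7_m2},
        )
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# parameter packing and implied moments


def _unpack(spec: PathModelSpec, params: np.ndarray):
    k = len(spec.exogenous)
    pos = 0
    mu_x = params[pos : pos + k]
    pos += k
    if spec.exog_cov == "diagonal":
        sds = np.exp(np.clip(params[pos : pos + k], -20.0, 20.0))
        cov_x = np.diag(sds * sds)
        pos += k
    else:
        m = k * (k + 1) // 2
        L = np.zeros((k, k))
        idx = np.tril_indices(k)
        L[idx] = params[pos : pos + m]
        # clip log-scale entries so a wandering optimizer cannot overflow
        L[np.diag_indices(k)] = np.exp(np.clip(np.diag(L), -20.0, 20.0)) + 1e-8
        cov_x = L @ L.T
        pos += m
    eqs = {}
    for child in spec._order:
        edges = spec.equations[child]
        a = params[pos]
        pos += 1
        coefs = params[pos : pos + len(edges)]
        pos += len(edges)
        psi = np.exp(2.0 * np.clip(params[pos], -20.0, 20.0)) + 1e-10  # floored and clipped
        pos += 1
        eqs[child] = (a, coefs, psi)
    assert pos == len(params)
    return mu_x, cov_x, eqs


def implied_moments(spec: PathModelSpec, params: np.ndarray):
    """Model-implied mean vector and covariance of all variables.

    Built incrementally in topological order: for an equation
    ``y = a + c'x + e`` the implied mean is ``a + c'mu_x``, the implied
    covariance with any earlier variable is ``c' Cov(x, .)`` and the
    variance ``c' Sigma_xx c + psi``.
    """
    mu_x, cov_x, eqs = _unpack(spec, params)
    names = spec.variables
    p = len(names)
    k = len(spec.exogenous)
    mu = np.zeros(p)
    Sig = np.zeros((p, p))
    mu[:k] = mu_x
    Sig[:k, :k] = cov_x
    index = {v: i for i, v in enumerate(names)}
    for child in spec._order:
        i = index[child]
        a, coefs, psi = eqs[child]
        par_idx = np.array([index[e.parent] for e in spec.equations[child]])
        mu[i] = a + coefs @ mu[par_idx]
        cov_with_prev = coefs @ Sig[np.ix_(par_idx, np.arange(i))]
        Sig[i, :i] = cov_with_prev
        Sig[:i, i] = cov_with_prev
        Sig[i, i] = coefs @ Sig[np.ix_(par_idx, par_idx)] @ coefs + psi
    # diagonal exogenous blocks are PSD by construction; full blocks via Cholesky
    return mu, Sig


# ---------------------------------------------------------------------------
# FIML likelihood


class _PatternData:
    """Rows grouped by missingness pattern with per-pattern sufficient stats."""

    def __init__(self, data: pd.DataFrame, variables):
        arr = data[list(variables)].to_numpy(dtype=float)
        obs = ~np.isnan(arr)
        if np.any(obs.sum(axis=1) == 0):
            raise ValueError("rows with no observed variable contribute nothing; drop them first")
        pats, inverse = np.unique(obs, axis=0, return_inverse=True)
        self.n_total = len(arr)
        self.patterns = []
        for pi in range(len(pats)):
            rows = arr[inverse == pi][:, pats[pi]]
            n = len(rows)
            ybar = rows.mean(axis=0)
            centred = rows - ybar
            S = centred.T @ centred / n
            self.patterns.append((np.flatnonzero(pats[pi]), n, ybar, S))

    def loglik(self, mu, Sig):
        total = 0.0
        for idx, n, ybar, S in self.patterns:
            mu_k = mu[idx]
            Sig_k = Sig[np.ix_(idx, idx)]
            pk = len(idx)
            try:
                L = np.linalg.cholesky(Sig_k)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "implied marginal covariance singular for pattern "
                    f"{idx.tolist()}"
                )
            logdet = 2.0 * np.log(np.diag(L)).sum()
            d = ybar - mu_k
            z = np.linalg.solve(L, d)
            Sinv_S = np.linalg.solve(L.T, np.linalg.solve(L, S))
            total += -0.5 * n * (
                pk * np.log(2.0 * np.pi) + logdet + np.trace(Sinv_S) + z @ z
            )
        return total


def fiml_loglik(spec: PathModelSpec, params: np.ndarray, data: pd.DataFrame) -> float:
    """FIML log-likelihood of ``data`` (NaN = missing) under the model."""
    mu, Sig = implied_moments(spec, params)
    return _PatternData(data, spec.variables).loglik(mu, Sig)


# ---------------------------------------------------------------------------
# fitting


def _initial_params(spec: PathModelSpec, data: pd.DataFrame) -> np.ndarray:
    cols = spec.variables
    d = data[cols]
    means = d.mean().to_numpy()
    means = np.where(np.isfinite(means), means, 0.0)
    cov = d.cov().to_numpy()  # pairwise-complete
    cov = np.where(np.isfinite(cov), cov, 0.0)
    np.fill_diagonal(cov, np.where(np.diag(cov) > 1e-10, np.diag(cov), 1.0))
    # ensure PD for the Cholesky start
    w, V = np.linalg.eigh(cov)
    cov = (V * np.clip(w, 1e-6, None)) @ V.T
    index = {v: i for i, v in enumerate(cols)}

    k = len(spec.exogenous)
    exog_idx = [index[v] for v in spec.exogenous]
    parts = [means[exog_idx]]
    if spec.exog_cov == "diagonal":
        parts.append(0.5 * np.log(np.diag(cov)[exog_idx]))
    else:
        L = np.linalg.cholesky(cov[np.ix_(exog_idx, exog_idx)])
        L = L.copy()
        L[np.diag_indices(k)] = np.log(np.diag(L))
        parts.append(L[np.tril_indices(k)])
    for child in spec._order:
        edges = spec.equations[child]
        pars = [e.parent for e in edges]
        sub = data[[child] + pars].dropna()
        if len(sub) > len(pars) + 2:
            X = np.column_stack([np.ones(len(sub)), sub[pars].to_numpy()])
            y = sub[child].to_numpy()
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            rv = max(resid.var(), 1e-4)
            parts.append(np.concatenate([coef, [0.5 * np.log(rv)]]))
        else:
            parts.append(
                np.concatenate([[means[index[child]]], np.zeros(len(pars)), [0.0]])
            )
    return np.concatenate(parts)


def _optimize(spec, pattern_data, x0, tol=1e-8, max_iter=2000, polish=True):
    def nll(params):
        try:
            mu, Sig = implied_moments(spec, params)
            return -pattern_data.loglik(mu, Sig)
        except np.linalg.LinAlgError:
            return 1e12

    res = minimize(
        nll, x0, method="L-BFGS-B", options=dict(maxiter=max_iter, ftol=tol * 1e-4, gtol=1e-7)
    )
    if not res.success and polish:
        res2 = minimize(
            nll,
            res.x,
            method="Nelder-Mead",
            options=dict(maxiter=max_iter * 2, xatol=1e-9, fatol=tol),
        )
        if res2.fun <= res.fun:
            res = res2
    return res


@dataclass
class PathFitResult:
    """Estimates, fit statistics and (optionally) bootstrap CIs."""

    spec: PathModelSpec
    params: np.ndarray
    table: pd.DataFrame  # per-parameter rows with estimate (and se for coefficients)
    loglik: float
    n_obs: int
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    converged: bool
    effects: pd.DataFrame | None = None

    def coefficient(self, child: str, parent: str) -> float:
        m = (self.table["role"] == "coef") & (self.table["child"] == child) & (
            self.table["parent"] == parent
        )
        if not m.any():
            raise KeyError(f"no edge {parent} -> {child}")
        return float(self.table.loc[m, "estimate"].iloc[0])


def _hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H, f0


def fit(
    spec: PathModelSpec,
    data: pd.DataFrame,
    *,
    tol: float = 1e-8,
    max_iter: int = 2000,
    standard_errors: bool = True,
    fit_statistics: bool = True,
    polish: bool = True,
    x0: np.ndarray | None = None,
) -> PathFitResult:
    """Estimate a path model by FIML.

    On complete data the coefficient estimates coincide with
    per-equation least squares (the classical equivalence for recursive
    systems); with missing data the likelihood is summed over
    missingness patterns.  Fit statistics compare the model against the
    saturated and independence models estimated by the same machinery.

    ``standard_errors=False`` skips the observed-information standard
    errors (used inside the bootstrap for speed).
    """
    pattern_data = _PatternData(data, spec.variables)
    if x0 is None:
        x0 = _initial_params(spec, data)
    res = _optimize(spec, pattern_data, x0, tol=tol, max_iter=max_iter, polish=polish)
    if not res.success and res.fun >= 1e11:
        raise ConvergenceError(f"path-model optimisation failed: {res.message}")
    params = res.x
    loglik = -res.fun

    n = pattern_data.n_total
    if fit_statistics:
        # saturated and baseline fits for chi-square and incremental indices
        sat = saturated_spec(spec.variables)
        res_sat = _optimize(sat, pattern_data, _initial_params(sat, data), tol=tol)
        base = baseline_spec(spec.variables)
        res_base = _optimize(base, pattern_data, _initial_params(base, data), tol=tol)
        ll_sat, ll_base = -res_sat.fun, -res_base.fun

        chi2 = max(2.0 * (ll_sat - loglik), 0.0)
        df = sat.n_parameters() - spec.n_parameters()
        chi2_b = max(2.0 * (ll_sat - ll_base), 0.0)
        df_b = sat.n_parameters() - base.n_parameters()
        cfi, tli, rmsea = fit_indices(chi2, df, chi2_b, df_b, n)
    else:
        chi2 = chi2_b = float("nan")
        df = df_b = 0
        cfi = tli = rmsea = float("nan")

    table = spec.coefficient_index()
    table["estimate"] = params
    table["se"] = np.nan
    if standard_errors:
        def nll(p):
            try:
                mu, Sig = implied_moments(spec, p)
                return -pattern_data.loglik(mu, Sig)
            except np.linalg.LinAlgError:
                return 1e12

        H, _ = _hessian(nll, params)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            table["se"] = se
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; standard errors unavailable")

    result = PathFitResult(
        spec=spec,
        params=params,
        table=table,
        loglik=float(loglik),
        n_obs=n,
        chi2=float(chi2),
        df=int(df),
        chi2_baseline=float(chi2_b),
        df_baseline=int(df_b),
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        converged=bool(res.success),
    )
    eff = _try_effects(result)
    result.effects = eff
    return result


def fit_indices(chi2_m: float, df_m: int, chi2_b: float, df_b: int, n: int):
    """CFI, TLI and RMSEA from model and baseline chi-squares.

    CFI and TLI are clamped to [0, 1]; a saturated model (df = 0) has
    RMSEA 0 by convention and an undefined TLI (NaN).
    """
    num_m = max(chi2_m - df_m, 0.0)
    num_b = max(chi2_b - df_b, num_m, 0.0)
    cfi = 1.0 if num_b == 0 else 1.0 - num_m / num_b
    if df_m == 0:
        tli = float("nan")
        rmsea = 0.0
    else:
        denom = chi2_b / df_b - 1.0 if df_b > 0 else float("nan")
        tli = (chi2_b / df_b - chi2_m / df_m) / denom if denom else float("nan")
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
    return float(np.clip(cfi, 0.0, 1.0)), float(np.clip(tli, 0.0, 1.0)) if np.isfinite(tli) else tli, rmsea


def _find_mediation_edges(spec: PathModelSpec, exposure: str = "nwc"):
    """Locate exposure->mediator, mediator->outcome, exposure->outcome edges."""
    endo = spec.endogenous
    if len(endo) != 2:
        return None
    mediator, outcome = endo
    parents_out = {e.parent for e in spec.equations[outcome]}
    if mediator not in parents_out:
        mediator, outcome = outcome, mediator
        parents_out = {e.parent for e in spec.equations[outcome]}
        if mediator not in parents_out:
            return None
    parents_med = {e.parent for e in spec.equations[mediator]}
    if exposure not in parents_med or exposure not in parents_out:
        return None
    return exposure, mediator, outcome


def effect_decomposition(result: PathFitResult, exposure: str = "nwc") -> pd.DataFrame:
    """Direct, indirect and total effect of the exposure on the outcome.

    Requires the joint mediation model (exposure -> mediator,
    mediator -> outcome and exposure -> outcome edges).  The indirect
    effect is the product of the two mediated-path coefficients; the
    total is direct + indirect.
    """
    found = _find_mediation_edges(result.spec, exposure)
    if found is None:
        raise ValueError("model lacks the exposure->mediator->outcome structure")
    exposure, mediator, outcome = found
    a = result.coefficient(mediator, exposure)
    b = result.coefficient(outcome, mediator)
    direct = result.coefficient(outcome, exposure)
    return pd.DataFrame(
        {
            "effect": ["direct", "indirect", "total"],
            "estimate": [direct, a * b, direct + a * b],
        }
    )


def _try_effects(result: PathFitResult):
    try:
        return effect_decomposition(result)
    except (ValueError, KeyError):
        return None


def bootstrap_ci(
    spec: PathModelSpec,
    data: pd.DataFrame,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for coefficients and mediation effects.

    Children (rows) are resampled with replacement, the model refitted
    (warm-started at the full-sample estimates), and the empirical
    ``(1-level)/2`` and ``1-(1-level)/2`` percentiles taken.  Failed
    replicates are dropped and counted; more than
    ``max_failure_rate`` failures raises.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)
    full = fit(spec, data, standard_errors=False, fit_statistics=False)
    coef_rows = full.table["role"].isin(["coef", "intercept"]).to_numpy()
    draws = []
    eff_draws = []
    failures = 0
    n = len(data)
    has_effects = full.effects is not None
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx]
        try:
            r = fit(
                spec, sample, standard_errors=False, fit_statistics=False,
                polish=False, max_iter=500, x0=full.params,
            )
            draws.append(r.params[coef_rows])
            if has_effects:
                eff_draws.append(r.effects["estimate"].to_numpy())
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise ConvergenceError(f"{failures}/{n_boot} bootstrap replicates failed")
    draws = np.asarray(draws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)], axis=0)
    out = full.table.loc[coef_rows, ["role", "child", "parent", "label", "estimate"]].copy()
    out["ci_lo"] = lo
    out["ci_hi"] = hi
    out["n_failed"] = failures
    if has_effects:
        eff = np.asarray(eff_draws)
        elo, ehi = np.percentile(eff, [100 * alpha, 100 * (1 - alpha)], axis=0)
        eff_rows = full.effects.copy()
        eff_rows.insert(0, "role", "effect")
        eff_rows.insert(1, "child", "")
        eff_rows.insert(2, "parent", "")
        eff_rows = eff_rows.rename(columns={"effect": "label"})
        eff_rows["ci_lo"] = elo
        eff_rows["ci_hi"] = ehi
        eff_rows["n_failed"] = failures
        out = pd.concat([out, eff_rows], ignore_index=True)
    return out.reset_index(drop=True)


def pearson_matrix(panel: pd.DataFrame, columns=None, *, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns ``(r, p, stars)`` DataFrames; stars follow the convention
    ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001.  Cells with fewer than
    ``min_pairs`` complete pairs, or a constant variable, are NaN with a
    warning.
    """
    cols = list(columns) if columns is not None else list(panel.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    arr = panel[cols].to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            m = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            n = m.sum()
            if n < min_pairs:
                warnings.warn(f"fewer than {min_pairs} complete pairs for {cols[i]}/{cols[j]}")
                continue
            x, y = arr[m, i], arr[m, j]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant variable in pair {cols[i]}/{cols[j]}")
                continue
            rij = np.corrcoef(x, y)[0, 1]
            r[i, j] = r[j, i] = rij
            if abs(rij) >= 1.0:
                p[i, j] = p[j, i] = 0.0
            else:
                tstat = rij * np.sqrt((n - 2) / (1.0 - rij * rij))
                p[i, j] = p[j, i] = 2.0 * t_dist.sf(abs(tstat), n - 2)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)

    def star(pv):
        if np.isnan(pv):
            return ""
        return "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""

    stars = pdf.map(star)
    return rdf, pdf, stars
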