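"""Synthetic birth-cohort generator.

The real cohort behind this analysis is not public, so every stage is
exercised against simulated data with the same statistical structure:

* newborn weights follow a population cubic curve in hours since birth
  plus a per-subject random intercept and slope, observed at t = 0
  (birthweight) and once more at an irregular time within the first
  four days;
* childhood cardio-metabolic traits at ages 4 and 7 are produced by the
  same structural equations the analysis fits (confounders and newborn
  weight change into the age-4 trait; those plus the age-4 trait into
  the age-7 trait), on a standardised scale, then mapped to natural
  units with realistic means and SDs;
* raw components are emitted, not derived quantities: total/HDL
  cholesterol and triglycerides rather than LDL, repeated blood-pressure
  readings rather than a summary, so the clinical-derivation stage has
  real work to do;
* a truth table records the generating parameters, per-subject random
  effects and noiseless weight change for recovery tests.

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import population_nadir
from .clinical import TRAITS

__all__ = [
    "GrowthSimParams",
    "TraitParams",
    "TrackingSimParams",
    "SyntheticTruth",
    "generate_newborns",
    "generate_child_outcomes",
    "simulate_path_cohort",
    "inject_missingness",
]

#: population fixed effects of the cubic growth curve (g, g/h, g/h^2, g/h^3)
DEFAULT_BETA = (3241.442, -9.378, 0.119, -0.0004)


@dataclass
class GrowthSimParams:
    """Generating parameters for the newborn weight data.

    The fixed cubic defaults to the population curve of the source
    cohort; the variance components are not reported anywhere, so the
    defaults are chosen to give a weight-change distribution of
    realistic spread (SD near 2.3% of birthweight).
    """

    beta0: float = DEFAULT_BETA[0]
    beta1: float = DEFAULT_BETA[1]
    beta2: float = DEFAULT_BETA[2]
    beta3: float = DEFAULT_BETA[3]
    sd_b0: float = 400.0
    sd_b1: float = 1.0
    corr_b0b1: float = -0.2
    sd_resid: float = 50.0
    t_min: float = 6.3
    t_max: float = 96.0
    n_newborns: int = 1500
    seed: int = 0
    round_grams: bool = True  # scale resolution: weights to the nearest gram

    def __post_init__(self):
        if min(self.sd_b0, self.sd_b1, self.sd_resid) < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.corr_b0b1) > 1:
            raise ValueError("|corr_b0b1| must be <= 1")
        if not (0 < self.t_min < self.t_max <= 96.0):
            raise ValueError("need 0 < t_min < t_max <= 96")
        if self.n_newborns <= 0:
            raise ValueError("n_newborns must be positive")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def curve(self, t):
        t = np.asarray(t, dtype=float)
        return self.beta0 + self.beta1 * t + self.beta2 * t**2 + self.beta3 * t**3


@dataclass
class TraitParams:
    """Natural-scale moments and structural effects for one trait."""

    mean4: float
    sd4: float
    mean7: float
    sd7: float
    tracking: float  # standardised age-4 -> age-7 path
    nwc_effect_4: float = 0.0
    nwc_effect_7: float = 0.0


def _default_traits() -> dict:
    # natural-scale targets and tracking coefficients of the source cohort
    return {
        "glucose": TraitParams(77.9, 7.9, 83.0, 5.7, 0.235),
        "ldl": TraitParams(107.0, 23.5, 99.8, 22.2, 0.655),
        "tg": TraitParams(61.0, 25.0 / 1.349, 55.0, 28.0 / 1.349, 0.281),
        "waist": TraitParams(52.0, 4.2, 58.3, 6.2, 0.725),
        "sbp": TraitParams(97.3, 7.6, 105.0, 8.7, 0.369),
        "dbp": TraitParams(56.1, 7.8, 69.2, 7.4, 0.153),
    }


def _corr_from_upper(vals) -> np.ndarray:
    m = np.eye(6)
    m[np.triu_indices(6, 1)] = vals
    return m + np.triu(m, 1).T


# residual cross-trait correlations (order: glucose, ldl, tg, waist, sbp, dbp)
DEFAULT_CORR_AGE4 = _corr_from_upper(
    [0.039, 0.036, 0.151, 0.039, 0.019,
     0.053, 0.031, 0.041, -0.027,
     0.053, 0.047, 0.086,
     0.226, 0.344,
     0.369]
)
DEFAULT_CORR_AGE7 = _corr_from_upper(
    [0.098, 0.089, 0.090, 0.154, 0.116,
     0.120, -0.020, 0.047, 0.078,
     0.135, 0.024, 0.015,
     0.262, 0.172,
     0.554]
)


@dataclass
class TrackingSimParams:
    """Generating parameters for the childhood-trait tables.

    NWC effects default to zero — the null the analysis is expected to
    recover.  Confounder effects (standardised units, applied to both
    ages) also default to zero; the estimation stage must adjust for
    them regardless.
    """

    traits: dict = field(default_factory=_default_traits)
    confounder_effects: dict = field(
        default_factory=lambda: {
            "maternal_education": 0.0,
            "pre_pregnancy_bmi": 0.0,
            "gestational_age": 0.0,
            "birthweight": 0.0,
        }
    )
    resid_corr_age4: np.ndarray = field(default_factory=lambda: DEFAULT_CORR_AGE4.copy())
    resid_corr_age7: np.ndarray = field(default_factory=lambda: DEFAULT_CORR_AGE7.copy())
    bp_reading_sd: float = 2.0  # within-visit measurement noise, mmHg
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name, m in (("age4", self.resid_corr_age4), ("age7", self.resid_corr_age7)):
            m = np.asarray(m, dtype=float)
            if m.shape != (6, 6) or not np.allclose(m, m.T):
                raise ValueError(f"residual correlation matrix ({name}) must be symmetric 6x6")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"residual correlation matrix ({name}) is not positive semi-definite")
        for tp in self.traits.values():
            if min(tp.sd4, tp.sd7) <= 0:
                raise ValueError("trait SDs must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Generating parameters paired with per-subject noiseless quantities."""

    growth_params: GrowthSimParams
    subjects: pd.DataFrame  # id, b0, b1, true_birthweight, true_min_weight, true_nwc
    nadir_time: float
    tracking_params: TrackingSimParams | None = None
    path_coefficients: pd.DataFrame | None = None

    def params_dict(self) -> dict:
        out = {"growth": asdict(self.growth_params), "nadir_time": self.nadir_time}
        if self.tracking_params is not None:
            tp = self.tracking_params
            out["tracking"] = {
                "traits": {k: asdict(v) for k, v in tp.traits.items()},
                "confounder_effects": dict(tp.confounder_effects),
                "resid_corr_age4": np.asarray(tp.resid_corr_age4).tolist(),
                "resid_corr_age7": np.asarray(tp.resid_corr_age7).tolist(),
                "bp_reading_sd": tp.bp_reading_sd,
                "missing_rate": tp.missing_rate,
                "seed": tp.seed,
            }
        return out


def _covariates(rng, n):
    """Maternal/pregnancy covariates from plausible full-term distributions."""
    return pd.DataFrame(
        {
            "sex": rng.choice(["female", "male"], n),
            "maternal_education": np.clip(rng.normal(11.9, 4.1, n), 2.0, 23.0).round(0),
            "pre_pregnancy_bmi": np.clip(rng.normal(24.4, 4.3, n), 15.0, 45.0).round(1),
            "gestational_age": np.clip(rng.normal(39.3, 1.2, n), 37.0, 42.0).round(1),
        }
    )


def generate_newborns(params: GrowthSimParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one newborn table from the cubic random-effects curve.

    Each newborn's birthweight is the subject curve at t = 0 plus
    measurement noise; the single later weight is the subject curve at a
    time drawn uniformly on [t_min, t_max] plus noise.  The truth table
    carries the realised random effects and the noiseless weight change
    at the population nadir of the generating curve.
    """
    n = params.n_newborns
    streams = np.random.SeedSequence(params.seed).spawn(3)
    rng_re, rng_obs, rng_cov = (np.random.default_rng(s) for s in streams)

    cov = np.array(
        [
            [params.sd_b0**2, params.corr_b0b1 * params.sd_b0 * params.sd_b1],
            [params.corr_b0b1 * params.sd_b0 * params.sd_b1, params.sd_b1**2],
        ]
    )
    re = rng_re.multivariate_normal([0.0, 0.0], cov, n)
    t = rng_obs.uniform(params.t_min, params.t_max, n)
    birthweight = params.curve(0.0) + re[:, 0] + rng_obs.normal(0.0, params.sd_resid, n)
    meas_weight = (
        params.curve(t) + re[:, 0] + re[:, 1] * t + rng_obs.normal(0.0, params.sd_resid, n)
    )

    newborns = _covariates(rng_cov, n)
    newborns.insert(0, "id", np.arange(1, n + 1))
    if params.round_grams:
        newborns["birthweight"] = np.round(birthweight)
        newborns["meas_time"] = np.round(t, 1)
        newborns["meas_weight"] = np.round(meas_weight)
    else:
        newborns["birthweight"] = birthweight
        newborns["meas_time"] = t
        newborns["meas_weight"] = meas_weight

    t_star = population_nadir(params.beta)
    bw_true = params.curve(0.0) + re[:, 0]
    min_true = params.curve(t_star) + re[:, 0] + re[:, 1] * t_star
    truth = SyntheticTruth(
        growth_params=params,
        nadir_time=t_star,
        subjects=pd.DataFrame(
            {
                "id": newborns["id"],
                "b0": re[:, 0],
                "b1": re[:, 1],
                "true_birthweight": bw_true,
                "true_min_weight": min_true,
                "true_nwc": (min_true - bw_true) / bw_true * 100.0,
            }
        ),
    )
    return newborns, truth


def _standardise(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def _structural_z(n, predictors, coefs, shared_resid):
    """One trait's z-score: structural part plus correlated unit residual,
    with the residual SD chosen so the marginal variance stays near 1."""
    struct = np.zeros(n)
    for x, c in zip(predictors, coefs):
        struct += c * x
    v = struct.var() if len(predictors) else 0.0
    resid_sd = np.sqrt(max(1.0 - v, 0.05))
    return struct + resid_sd * shared_resid


def generate_child_outcomes(
    newborns: pd.DataFrame,
    params: TrackingSimParams,
    *,
    nwc: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the age-4 and age-7 visit tables.

    The age-4 trait follows the total-association structural equation
    (confounders + NWC); the age-7 trait follows the mediation equation
    (confounders + NWC + same trait at age 4, the tracking edge).  Raw
    components are emitted: total/HDL cholesterol and triglycerides (the
    LDL inputs) and two or, when discordant, three blood-pressure
    readings.

    ``nwc`` supplies the per-child exposure (percent); when omitted the
    noiseless weight change implied by the newborn table's observed
    weights is used as a stand-in.

    Returns ``(age4, age7, coefficients)`` where the last frame lists
    every generating structural coefficient.
    """
    n = len(newborns)
    streams = np.random.SeedSequence(params.seed).spawn(4)
    rng_resid, rng_raw, rng_bp, rng_age = (np.random.default_rng(s) for s in streams)

    if nwc is None:
        nwc = (
            (newborns["meas_weight"] - newborns["birthweight"])
            / newborns["birthweight"]
            * 100.0
        ).to_numpy()
    conf_std = {
        c: _standardise(newborns[c].to_numpy(dtype=float))
        for c in ("maternal_education", "pre_pregnancy_bmi", "gestational_age", "birthweight")
    }
    nwc_std = _standardise(np.asarray(nwc, dtype=float))

    chol4 = np.linalg.cholesky(params.resid_corr_age4 + 1e-12 * np.eye(6))
    chol7 = np.linalg.cholesky(params.resid_corr_age7 + 1e-12 * np.eye(6))
    e4 = rng_resid.standard_normal((n, 6)) @ chol4.T
    e7 = rng_resid.standard_normal((n, 6)) @ chol7.T

    coef_rows = []
    z4 = {}
    z7 = {}
    for ti, trait in enumerate(TRAITS):
        tp = params.traits[trait]
        ce = params.confounder_effects
        preds4 = [nwc_std] + [conf_std[c] for c in ce]
        coefs4 = [tp.nwc_effect_4] + list(ce.values())
        z4[trait] = _structural_z(n, preds4, coefs4, e4[:, ti])
        # age-7 equation: no gestational age, plus the tracking edge
        ce7 = {c: v for c, v in ce.items() if c != "gestational_age"}
        preds7 = [nwc_std] + [conf_std[c] for c in ce7] + [z4[trait]]
        coefs7 = [tp.nwc_effect_7] + list(ce7.values()) + [tp.tracking]
        z7[trait] = _structural_z(n, preds7, coefs7, e7[:, ti])
        for c, v in zip(["nwc"] + list(ce), coefs4):
            coef_rows.append(dict(trait=trait, age=4, parent=c, coefficient=v))
        for c, v in zip(["nwc"] + list(ce7) + [f"{trait}_z4"], coefs7):
            coef_rows.append(dict(trait=trait, age=7, parent=c, coefficient=v))

    def visit_table(age, zmap):
        tp_all = params.traits
        if age == 4:
            ages = rng_age.uniform(3.9, 4.9, n)
            height = rng_raw.normal(104.3, 4.3, n)
            hdl = np.clip(rng_raw.normal(52.0, 10.5, n), 20.0, None)
            natural = {t: getattr(tp_all[t], "mean4") + getattr(tp_all[t], "sd4") * zmap[t] for t in TRAITS}
        else:
            ages = rng_age.uniform(6.9, 7.9, n)
            height = rng_raw.normal(123.7, 5.4, n)
            hdl = np.clip(rng_raw.normal(56.0, 11.0, n), 20.0, None)
            natural = {t: getattr(tp_all[t], "mean7") + getattr(tp_all[t], "sd7") * zmap[t] for t in TRAITS}
        tg = np.clip(natural["tg"], 10.0, None)
        tab = pd.DataFrame(
            {
                "id": newborns["id"].to_numpy(),
                "sex": newborns["sex"].to_numpy(),
                "visit_age": np.round(ages, 2),
                "height": np.round(height, 1),
                "waist": np.round(natural["waist"], 1),
                "glucose": np.round(natural["glucose"], 1),
                "hdl": np.round(hdl, 1),
                "tg": np.round(tg, 1),
            }
        )
        # total cholesterol built so the Friedewald identity recovers LDL
        tab["total_chol"] = np.round(natural["ldl"] + hdl + tg / 5.0, 1)
        for which in ("sbp", "dbp"):
            v = natural[which]
            r1 = np.round(v + rng_bp.normal(0.0, params.bp_reading_sd, n))
            r2 = np.round(v + rng_bp.normal(0.0, params.bp_reading_sd, n))
            # the protocol's third reading, taken when the first two disagree
            r3 = np.where(
                np.abs(r1 - r2) >= 5.0,
                np.round(v + rng_bp.normal(0.0, params.bp_reading_sd, n)),
                np.nan,
            )
            tab[f"{which}_1"] = r1
            tab[f"{which}_2"] = r2
            tab[f"{which}_3"] = r3
        return tab

    age4 = visit_table(4, z4)
    age7 = visit_table(7, z7)
    coeffs = pd.DataFrame(coef_rows)
    if params.missing_rate > 0:
        age4 = inject_missingness(
            age4,
            {t: params.missing_rate for t in ("glucose", "hdl", "tg", "total_chol", "waist")},
            seed=params.seed + 101,
        )
        age7 = inject_missingness(
            age7,
            {t: params.missing_rate for t in ("glucose", "hdl", "tg", "total_chol", "waist")},
            seed=params.seed + 202,
        )
    return age4, age7, coeffs


def simulate_path_cohort(
    trait: str,
    n: int,
    *,
    seed: int = 0,
    params: TrackingSimParams | None = None,
) -> pd.DataFrame:
    """Simulate one analysis table on the z-score scale for path-model
    parameter-recovery experiments.

    Exposure (NWC) and confounders are independent unit-variance
    normals; the age-4 and age-7 trait z-scores follow the structural
    equations with the residual variances chosen so every variable has
    population variance exactly 1.  Column names match
    :func:`nadirpath.pathmodel.build_model`.
    """
    if params is None:
        params = TrackingSimParams(seed=seed)
    tp = params.traits[trait]
    rng = np.random.default_rng(seed)
    cols = ["nwc", "maternal_education", "pre_pregnancy_bmi", "gestational_age", "birthweight"]
    X = rng.standard_normal((n, len(cols)))
    df = pd.DataFrame(X, columns=cols)

    ce = params.confounder_effects
    c4 = np.array([tp.nwc_effect_4] + [ce[c] for c in cols[1:]])
    v4 = float(c4 @ c4)  # exogenous predictors are independent
    if v4 >= 1:
        raise ValueError("age-4 structural variance exceeds 1; reduce effects")
    z4 = X @ c4 + np.sqrt(1.0 - v4) * rng.standard_normal(n)

    ce7_names = [c for c in cols[1:] if c != "gestational_age"]
    c7 = np.array([tp.nwc_effect_7] + [ce[c] for c in ce7_names] + [tp.tracking])
    # population covariance of (nwc, confs-without-ga, z4)
    k = len(c7)
    Sig = np.eye(k)
    z4_cov = {"nwc": c4[0], **{c: ce[c] for c in cols[1:]}}
    preds = ["nwc"] + ce7_names
    for i, name in enumerate(preds):
        Sig[i, -1] = Sig[-1, i] = z4_cov[name]
    v7 = float(c7 @ Sig @ c7)
    if v7 >= 1:
        raise ValueError("age-7 structural variance exceeds 1; reduce effects")
    struct7 = df[preds].to_numpy() @ c7[:-1] + c7[-1] * z4
    z7 = struct7 + np.sqrt(1.0 - v7) * rng.standard_normal(n)

    df[f"{trait}_z4"] = z4
    df[f"{trait}_z7"] = z7
    return df


def inject_missingness(
    table: pd.DataFrame,
    rates: dict,
    *,
    mechanism: str = "mcar",
    condition: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Delete values completely at random or at random given a covariate.

    ``rates`` maps column name -> marginal missingness probability.
    Under ``mechanism="mar"`` the probability varies across tertiles of
    the (fully observed) ``condition`` column with weights 0.5/1.0/1.5,
    keeping the marginal rate; observed values are never altered.
    """
    for col, rate in rates.items():
        if not (0 <= rate < 1):
            raise ValueError(f"rate for {col!r} must be in [0, 1)")
    out = table.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    if mechanism == "mcar":
        weights = np.ones(n)
    elif mechanism == "mar":
        if condition is None:
            raise ValueError("MAR requires a conditioning column")
        cond = out[condition]
        if cond.isna().any():
            raise ValueError("MAR conditioning variable has missing values")
        tertile = pd.qcut(cond.rank(method="first"), 3, labels=False).to_numpy()
        weights = np.array([0.5, 1.0, 1.5])[tertile]
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    for col, rate in rates.items():
        p = np.clip(rate * weights, 0.0, 0.999)
        out.loc[rng.uniform(size=n) < p, col] = np.nan
    return out
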