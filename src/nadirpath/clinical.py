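"""Derivation of childhood cardio-metabolic outcome variables.

Raw visit measurements become six analysis outcomes: fasting glucose,
Friedewald LDL-cholesterol, triglycerides, waist circumference, and
protocol-averaged systolic/diastolic blood pressure.  Each is expressed
as an age- and sex-specific z-score (blood pressure additionally
height-specific) against a cohort reference table of per-bin means and
SDs, and flagged "high" when strictly above the empirical 90th
percentile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "friedewald_ldl",
    "bp_summary",
    "build_reference",
    "zscore",
    "high_flag",
    "derive_outcome_panel",
    "TRAITS",
]

#: the six outcome traits, in reporting order
TRAITS = ("glucose", "ldl", "tg", "waist", "sbp", "dbp")

#: triglyceride bound (mg/dL) above which the Friedewald equation is invalid
FRIEDEWALD_TG_LIMIT = 400.0


def friedewald_ldl(total_chol, hdl, tg, *, tg_limit: float = FRIEDEWALD_TG_LIMIT):
    """LDL-cholesterol (mg/dL) by the Friedewald equation.

    ``LDL = TC - HDL - TG/5`` with all inputs in mg/dL; returns NaN where
    triglycerides exceed ``tg_limit`` (the equation's validity bound).
    """
    tc = np.asarray(total_chol, dtype=float)
    h = np.asarray(hdl, dtype=float)
    t = np.asarray(tg, dtype=float)
    for name, arr in (("total_chol", tc), ("hdl", h), ("tg", t)):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"negative {name}")
    ldl = tc - h - t / 5.0
    ldl = np.where(t > tg_limit, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def bp_summary(readings, *, tie: str = "lower_mean") -> float:
    """Summarise 2-3 blood-pressure readings (mmHg) per protocol.

    Two readings differing by less than 5 mmHg: their mean.  Otherwise a
    third reading is required and the mean of the two closest readings is
    used.  A difference of exactly 5 counts as "large" (the protocol
    defines "<5" and ">5"; the boundary is resolved conservatively).

    Parameters
    ----------
    readings : sequence of 2 or 3 floats; NaNs are dropped first.
    tie : how to break a tie when the third reading is equidistant from
        the first two: ``"lower_mean"`` (default) takes the pair with the
        lower mean, ``"higher_mean"`` the other.

    Returns NaN (with a warning) when two discordant readings have no
    third measurement.
    """
    vals = [float(v) for v in readings if not (isinstance(v, float) and np.isnan(v))]
    if len(vals) == 2:
        if abs(vals[0] - vals[1]) < 5.0:
            return (vals[0] + vals[1]) / 2.0
        warnings.warn("two discordant BP readings with no third measurement; returning NaN")
        return float("nan")
    if len(vals) == 3:
        pairs = [(vals[0], vals[1]), (vals[0], vals[2]), (vals[1], vals[2])]
        diffs = [abs(a - b) for a, b in pairs]
        best = min(diffs)
        candidates = [p for p, d in zip(pairs, diffs) if d == best]
        if len(candidates) > 1:
            key = (min if tie == "lower_mean" else max)
            chosen = key(candidates, key=lambda p: p[0] + p[1])
        else:
            chosen = candidates[0]
        return (chosen[0] + chosen[1]) / 2.0
    raise ValueError(f"expected 2 or 3 readings, got {len(vals)}")


def _age_bins(ages: np.ndarray, width: float) -> np.ndarray:
    """Left edges of fixed-width age bins anchored at 0."""
    return np.floor(np.asarray(ages, dtype=float) / width) * width


def build_reference(
    panel: pd.DataFrame,
    traits,
    *,
    bin_width: float = 0.5,
    sex_col: str = "sex",
    age_col: str = "visit_age",
    height_col: str | None = None,
    n_height_bands: int = 3,
    min_cell: int = 2,
) -> pd.DataFrame:
    """Cohort reference table of per-cell means and SDs.

    Cells are sex x age-bin (``bin_width`` years, default 6 months),
    optionally subdivided into ``n_height_bands`` within-cell height
    quantile bands (used for blood pressure so the z-scores are
    height-independent).  SDs use the n-1 denominator.

    Returns a frame with columns ``sex, age_lo, age_hi, height_lo,
    height_hi, trait, mean, sd, n`` (height bounds are -inf/inf when no
    height column is given).  Cells with fewer than ``min_cell``
    non-missing values raise an error naming them.
    """
    rows = []
    work = panel.copy()
    work["_bin"] = _age_bins(work[age_col], bin_width)
    for (sex, lo), sub in work.groupby([sex_col, "_bin"]):
        if height_col is not None:
            edges = np.quantile(
                sub[height_col].dropna(), np.linspace(0, 1, n_height_bands + 1)
            )
            edges[0], edges[-1] = -np.inf, np.inf
            bands = [(edges[i], edges[i + 1]) for i in range(n_height_bands)]
        else:
            bands = [(-np.inf, np.inf)]
        for h_lo, h_hi in bands:
            if height_col is not None:
                m = (sub[height_col] > h_lo) & (sub[height_col] <= h_hi)
                cell = sub.loc[m | (sub[height_col].isna() & False)]
            else:
                cell = sub
            for trait in traits:
                vals = cell[trait].dropna()
                rows.append(
                    dict(
                        sex=sex,
                        age_lo=lo,
                        age_hi=lo + bin_width,
                        height_lo=h_lo,
                        height_hi=h_hi,
                        trait=trait,
                        mean=vals.mean() if len(vals) else np.nan,
                        sd=vals.std(ddof=1) if len(vals) > 1 else np.nan,
                        n=len(vals),
                    )
                )
    ref = pd.DataFrame(rows)
    bad = ref[ref["n"] < min_cell]
    if len(bad):
        cells = bad[["sex", "age_lo", "trait"]].to_records(index=False).tolist()
        raise ValueError(f"reference cells with <{min_cell} observations: {cells[:10]}")
    return ref


def zscore(
    values,
    sex,
    age,
    reference: pd.DataFrame,
    *,
    height=None,
) -> np.ndarray | float:
    """Standardise values against the matching reference cell.

    ``(value - mean) / sd`` from the row matching the subject's sex, age
    bin and, when the reference carries height bands, height band.
    Subjects with no matching row get NaN with a warning, never a
    silently extrapolated score.

    ``reference`` must be a single-trait slice of a
    :func:`build_reference` table (filter on ``trait`` first).
    """
    if reference["trait"].nunique() > 1:
        raise ValueError("reference must be filtered to a single trait")
    v = np.atleast_1d(np.asarray(values, dtype=float))
    s = np.atleast_1d(np.asarray(sex))
    a = np.atleast_1d(np.asarray(age, dtype=float))
    h = None if height is None else np.atleast_1d(np.asarray(height, dtype=float))
    out = np.full(v.shape, np.nan)
    unmatched = 0
    for i in range(len(v)):
        m = (
            (reference["sex"] == s[i])
            & (reference["age_lo"] <= a[i])
            & (a[i] < reference["age_hi"])
        )
        if h is not None:
            m &= (reference["height_lo"] < h[i]) & (h[i] <= reference["height_hi"])
        rows = reference.loc[m]
        if len(rows) == 1:
            out[i] = (v[i] - rows["mean"].iloc[0]) / rows["sd"].iloc[0]
        elif len(rows) == 0:
            unmatched += 1
        else:
            raise ValueError("reference rows overlap: more than one match")
    if unmatched:
        warnings.warn(f"{unmatched} value(s) had no matching reference cell; z set to NaN")
    return float(out[0]) if np.isscalar(values) or np.asarray(values).ndim == 0 else out


def high_flag(values, *, q: float = 0.9, min_n: int = 10) -> np.ndarray:
    """Flag values strictly above the cohort's empirical ``q`` quantile.

    The quantile uses linear interpolation between order statistics
    (numpy's default); NaNs are ignored for the threshold and flagged
    False.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < min_n:
        raise ValueError(f"need at least {min_n} non-missing values, got {ok.sum()}")
    thr = np.quantile(v[ok], q)
    return (v > thr) & ok


def derive_outcome_panel(
    visits: pd.DataFrame,
    *,
    reference: pd.DataFrame | None = None,
    bp_reference: pd.DataFrame | None = None,
    bin_width: float = 0.5,
    flag_quantile: float = 0.9,
) -> pd.DataFrame:
    """Build the per-child outcome panel for one follow-up visit.

    Expects columns ``id, sex, visit_age, height, waist, glucose,
    total_chol, hdl, tg, sbp_1, sbp_2[, sbp_3], dbp_1, dbp_2[, dbp_3]``.
    Computes LDL (Friedewald), protocol-averaged SBP/DBP, then z-scores
    each trait against ``reference`` (cohort-internal when None; BP uses
    ``bp_reference`` with height bands, also cohort-internal when None)
    and adds >P90 high flags on the natural values.

    Returns one row per child: ``<trait>``, ``<trait>_z`` and
    ``<trait>_high`` per trait.
    """
    out = visits[["id", "sex", "visit_age", "height", "waist", "glucose", "tg"]].copy()
    out["ldl"] = friedewald_ldl(visits["total_chol"], visits["hdl"], visits["tg"])
    for which in ("sbp", "dbp"):
        cols = [c for c in (f"{which}_1", f"{which}_2", f"{which}_3") if c in visits.columns]
        out[which] = [
            bp_summary(row) for row in visits[cols].to_numpy()
        ]

    plain = [t for t in TRAITS if t not in ("sbp", "dbp")]
    if reference is None:
        reference = build_reference(out, plain, bin_width=bin_width)
    if bp_reference is None:
        bp_reference = build_reference(out, ["sbp", "dbp"], bin_width=bin_width, height_col="height")

    for trait in TRAITS:
        ref = (bp_reference if trait in ("sbp", "dbp") else reference)
        ref = ref[ref["trait"] == trait]
        out[f"{trait}_z"] = zscore(
            out[trait].to_numpy(),
            out["sex"].to_numpy(),
            out["visit_age"].to_numpy(),
            ref,
            height=out["height"].to_numpy() if trait in ("sbp", "dbp") else None,
        )
        out[f"{trait}_high"] = high_flag(out[trait].to_numpy(), q=flag_quantile)
    return out
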