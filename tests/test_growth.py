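"""Growth model, nadir location, NWC arithmetic and the exclusion cascade."""

import json
import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nadirpath import (
    GrowthSimParams,
    generate_newborns,
    fit_cubic_lmm,
    population_nadir,
    predict_weight,
    compute_nwc,
    hourly_change_rate,
    apply_exclusion_cascade,
    nwc_table,
)
from .conftest import PRINTED_BETA, cubic


# --------------------------------------------------------------------------
# nadir


def grid_nadir(beta, t_max=96.0, step=0.001):
    """Brute-force minimiser of the fixed cubic on a fine grid."""
    t = np.arange(step, t_max + step, step)
    return t[np.argmin(cubic(beta, t))]


def grid_interior_minima(beta, t_max=96.0, step=0.001):
    """Brute force: grid points strictly lower than both neighbours."""
    t = np.arange(step, t_max + step, step)
    w = cubic(beta, t)
    is_min = (w[1:-1] < w[:-2]) & (w[1:-1] < w[2:])
    return t[1:-1][is_min]


@pytest.mark.parametrize(
    "beta, expected",
    [
        ((0.0, -2.0, 1.0, 0.0), 1.0),  # parabola vertex
        (tuple(PRINTED_BETA), 54.2331),  # quadratic formula on the population curve
    ],
)
def test_population_nadir_closed_form(beta, expected):
    assert population_nadir(np.array(beta)) == pytest.approx(expected, abs=1e-3)


@given(
    b1=st.floats(-20.0, -0.5),
    b2=st.floats(0.01, 0.5),
    b3=st.floats(-0.002, -1e-5),
)
@settings(max_examples=40, deadline=None)
def test_population_nadir_matches_grid_search(b1, b2, b3):
    beta = np.array([3000.0, b1, b2, b3])
    try:
        t_star = population_nadir(beta)
    except ValueError:
        return  # no interior minimum for this curve
    minima = grid_interior_minima(beta)
    assert minima.size and np.min(np.abs(minima - t_star)) < 0.01


def test_population_nadir_is_grid_minimum_for_population_curve():
    assert abs(population_nadir(PRINTED_BETA) - grid_nadir(PRINTED_BETA)) < 0.01


def test_population_nadir_rejects_curve_without_minimum():
    with pytest.raises(ValueError, match="no interior minimum"):
        population_nadir(np.array([3000.0, 5.0, 0.1, 0.001]))


# --------------------------------------------------------------------------
# NWC arithmetic


@pytest.mark.parametrize(
    "bw, est, expected",
    [
        (100.0, 93.14, -6.86),
        (3241.442, cubic(PRINTED_BETA, 52.3), -6.8547),
        (2500.0, 2500.0, 0.0),
    ],
)
def test_compute_nwc(bw, est, expected):
    assert compute_nwc(bw, est) == pytest.approx(expected, abs=1e-3)


def test_compute_nwc_rejects_nonpositive_birthweight():
    with pytest.raises(ValueError):
        compute_nwc(0.0, 100.0)


@pytest.mark.parametrize(
    "bw, w, t, expected",
    [(1000, 900, 20, -0.5), (1000, 1000, 48, 0.0), (3000, 2820, 12, -0.5)],
)
def test_hourly_change_rate(bw, w, t, expected):
    assert hourly_change_rate(bw, w, t) == pytest.approx(expected)


# --------------------------------------------------------------------------
# mixed-model fitting


def test_noise_free_data_recover_cubic_exactly(noise_free_records):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cubic_lmm(noise_free_records)
    rel = np.abs(fit.beta - PRINTED_BETA) / np.abs(PRINTED_BETA)
    assert rel.max() < 1e-6


def test_fit_matches_lme4_oracle(tmp_path):
    """Independent oracle: R/lme4 ML fit of the same two-level model."""
    nb, _ = generate_newborns(GrowthSimParams(n_newborns=250, seed=7))
    long = pd.DataFrame(
        {
            "id": np.repeat(nb["id"].to_numpy(), 2),
            "t": np.column_stack([np.zeros(len(nb)), nb["meas_time"]]).ravel(),
            "w": np.column_stack([nb["birthweight"], nb["meas_weight"]]).ravel(),
        }
    )
    csv = tmp_path / "long.csv"
    long.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        f"""
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        d <- read.csv("{csv}"); d$t2 <- d$t^2; d$t3 <- d$t^3
        m <- lmer(w ~ t + t2 + t3 + (1 + t | id), data=d, REML=FALSE,
                  control=lmerControl(check.nobs.vs.nRE="ignore"))
        cat(toJSON(list(beta=as.numeric(fixef(m)), loglik=as.numeric(logLik(m)))))
        """
    )
    out = subprocess.run(
        ["Rscript", str(rscript)], capture_output=True, text=True, check=True
    )
    oracle = json.loads(out.stdout)
    fit = fit_cubic_lmm(nb)
    # the profiled-ML optimum should match (or slightly exceed) lme4's
    assert fit.loglik >= oracle["loglik"][0] - 0.05
    np.testing.assert_allclose(fit.beta, oracle["beta"], rtol=5e-3, atol=1e-3)


def test_predict_weight_matches_truth_in_noise_free_limit():
    params = GrowthSimParams(
        n_newborns=200, seed=9, sd_b0=0.0, sd_b1=0.0, corr_b0b1=0.0, sd_resid=0.0,
        round_grams=False,
    )
    nb, truth = generate_newborns(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cubic_lmm(nb)
    # fully deterministic data: fixed curve recovered exactly, subject
    # effects shrink to zero, so the prediction equals the generating curve
    t_star = truth.nadir_time
    pred = predict_weight(fit, nb["id"].to_numpy(), t_star)
    np.testing.assert_allclose(pred, truth.subjects["true_min_weight"], atol=1e-5)


def test_predict_weight_unknown_id(small_cohort):
    nb, _ = small_cohort
    fit = fit_cubic_lmm(nb)
    with pytest.raises(KeyError):
        predict_weight(fit, ["not-a-subject"], 50.0)
    # t = 0 returns the intercept plus the subject effect
    first = nb["id"].iloc[0]
    expected = fit.beta[0] + fit.ranef.loc[first, "b0"]
    assert predict_weight(fit, [first], 0.0) == pytest.approx(expected)


def test_nwc_pipeline_recovers_truth(small_cohort):
    """Estimated NWC tracks the noiseless truth within noise-driven error."""
    nb, truth = small_cohort
    fit = fit_cubic_lmm(nb)
    tab = nwc_table(fit, nb)
    merged = tab.merge(truth.subjects, on="id")
    err = merged["nwc"] - merged["true_nwc"]
    assert abs(err.mean()) < 0.25
    assert err.abs().mean() < 1.5


# --------------------------------------------------------------------------
# exclusion cascade


def test_cascade_conserves_counts(small_cohort):
    nb, _ = small_cohort
    kept, report = apply_exclusion_cascade(nb)
    n = report.n_input
    for _, n_exc, n_rem in report.stages:
        assert n_rem == n - n_exc
        n = n_rem
    assert len(kept) == report.n_remaining
    assert sum(s[1] for s in report.stages) + report.n_remaining == report.n_input


def test_cascade_no_triggers_keeps_all():
    times = np.linspace(20, 60, 10)
    rates = np.linspace(-0.17, -0.13, 10)  # spread keeps the 3*IQR fences wide
    rec = pd.DataFrame(
        {
            "id": range(10),
            "birthweight": [3000.0] * 10,
            "meas_time": times,
            "meas_weight": 3000.0 * (1 + rates * times / 100.0),
            "maternal_education": [12.0] * 10,
            "pre_pregnancy_bmi": [24.0] * 10,
            "gestational_age": [39.0] * 10,
        }
    )
    kept, report = apply_exclusion_cascade(rec)
    assert len(kept) == 10
    assert all(s[1] == 0 for s in report.stages)


def test_cascade_flags_single_extreme_rate():
    times = np.full(10, 20.0)
    rates = np.array([-0.16, -0.14, -0.15, -0.13, -0.17, -0.15, -0.16, -0.14, -0.15, -0.9])
    weights = 3000.0 * (1 + rates * times / 100.0)
    rec = pd.DataFrame(
        {
            "id": range(10),
            "birthweight": [3000.0] * 10,
            "meas_time": times,
            "meas_weight": weights,
            "maternal_education": [12.0] * 10,
            "pre_pregnancy_bmi": [24.0] * 10,
            "gestational_age": [39.0] * 10,
        }
    )
    # hand-computed Tukey fences on the ten rates
    q1, q3 = np.quantile(rates, [0.25, 0.75])
    lo = q1 - 3 * (q3 - q1)
    assert rates.min() < lo <= -0.17
    kept, report = apply_exclusion_cascade(rec)
    assert report.outlier_counts == (1, 0)
    assert len(kept) == 9


def test_cascade_empty_input():
    with pytest.raises(ValueError):
        apply_exclusion_cascade(pd.DataFrame(columns=["id", "meas_time"]))
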