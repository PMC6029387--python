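"""Path-model specification, FIML likelihood, fitting, bootstrap and indices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from nadirpath import (
    Edge,
    PathModelSpec,
    build_model,
    implied_moments,
    fiml_loglik,
    fit,
    bootstrap_ci,
    fit_indices,
    effect_decomposition,
    pearson_matrix,
    simulate_path_cohort,
)
from nadirpath.pathmodel import saturated_spec


# --------------------------------------------------------------------------
# model construction


@pytest.mark.parametrize(
    "variant, n_regressors, has_ga",
    [
        ("model1_age4", 5, True),
        ("model1_age7", 4, False),
        ("model2_age7", 5, False),
    ],
)
def test_build_model_regressors(variant, n_regressors, has_ga):
    spec = build_model("glucose", variant)
    (child,) = spec.endogenous
    parents = [e.parent for e in spec.equations[child]]
    assert len(parents) == n_regressors
    assert ("gestational_age" in parents) is has_ga


def test_build_model_tracking_edge_label():
    spec = build_model("waist", "model2_age7")
    edge = [e for e in spec.equations["waist_z7"] if e.parent == "waist_z4"]
    assert len(edge) == 1 and edge[0].label == "b5"


def test_spec_yaml_roundtrip(tmp_path):
    spec = build_model("waist", "joint")
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = PathModelSpec.from_yaml(path)
    assert back.exogenous == spec.exogenous
    assert back.equations == spec.equations


def test_cyclic_spec_rejected():
    with pytest.raises(ValueError, match="cyclic"):
        PathModelSpec(
            exogenous=["x"],
            equations={
                "a": [Edge("b", "a")],
                "b": [Edge("a", "b")],
            },
        )


# --------------------------------------------------------------------------
# implied moments


def _pack_simple(mu, log_sd, eqs):
    """Parameters for a spec with one exogenous variable."""
    return np.concatenate([[mu, log_sd], *eqs])


def test_implied_moments_single_edge_closed_form():
    spec = PathModelSpec(exogenous=["x"], equations={"y": [Edge("x", "y")]})
    beta = 0.7
    # x ~ N(0, 1); y = 0 + beta x + e, Var(e) = 1
    params = _pack_simple(0.0, 0.0, [[0.0, beta, 0.0]])
    mu, Sig = implied_moments(spec, params)
    assert mu == pytest.approx([0.0, 0.0])
    assert Sig[0, 0] == pytest.approx(1.0, abs=1e-6)
    assert Sig[0, 1] == pytest.approx(beta, abs=1e-6)
    assert Sig[1, 1] == pytest.approx(beta**2 + 1.0, abs=1e-6)


def test_implied_moments_zero_coefficients_block_diagonal():
    spec = build_model("waist", "model2_age7")
    x0 = np.zeros(spec.n_parameters())
    mu, Sig = implied_moments(spec, x0)
    k = len(spec.exogenous)
    assert np.allclose(Sig[:k, k:], 0.0)


def test_implied_moments_match_structural_simulation():
    """Monte-Carlo oracle: simulate the structural equations directly."""
    spec = PathModelSpec(
        exogenous=["x1", "x2"],
        equations={
            "m": [Edge("x1", "m"), Edge("x2", "m")],
            "y": [Edge("x1", "y"), Edge("m", "y")],
        },
    )
    # mu_x = (0.5, -1); chol = [[1,0],[0.3, exp(0)=1]] -> cov [[1,.3],[.3,1.09]]
    params = np.array(
        [0.5, -1.0,  # exogenous means
         0.0, 0.3, 0.0,  # cholesky (log-diagonal)
         0.2, 0.4, -0.3, 0.0,  # m: intercept, coefs, log resid sd
         -0.1, 0.25, 0.6, np.log(0.8)]  # y
    )
    mu, Sig = implied_moments(spec, params)
    rng = np.random.default_rng(0)
    n = 1_000_000
    L = np.array([[1.0, 0.0], [0.3, 1.0]])
    X = np.array([0.5, -1.0]) + rng.standard_normal((n, 2)) @ L.T
    m = 0.2 + 0.4 * X[:, 0] - 0.3 * X[:, 1] + rng.standard_normal(n)
    y = -0.1 + 0.25 * X[:, 0] + 0.6 * m + (0.8 + 1e-10) * rng.standard_normal(n)
    sim = np.column_stack([X, m, y])
    np.testing.assert_allclose(mu, sim.mean(0), atol=4 * 2.0 / np.sqrt(n))
    np.testing.assert_allclose(Sig, np.cov(sim.T), atol=4 * 4.0 / np.sqrt(n))


# --------------------------------------------------------------------------
# FIML likelihood


def test_fiml_complete_data_equals_mvn_loglik(complete_path_data):
    spec = build_model("waist", "model2_age7")
    res = fit(spec, complete_path_data, standard_errors=False, fit_statistics=False)
    mu, Sig = implied_moments(spec, res.params)
    direct = multivariate_normal(mu, Sig).logpdf(
        complete_path_data[spec.variables].to_numpy()
    ).sum()
    assert fiml_loglik(spec, res.params, complete_path_data) == pytest.approx(
        direct, abs=1e-8
    )


def test_fiml_duplicated_rows_double_loglik(complete_path_data):
    spec = build_model("waist", "model2_age7")
    params = fit(
        spec, complete_path_data, standard_errors=False, fit_statistics=False
    ).params
    ll = fiml_loglik(spec, params, complete_path_data)
    doubled = pd.concat([complete_path_data, complete_path_data], ignore_index=True)
    assert fiml_loglik(spec, params, doubled) == pytest.approx(2 * ll, rel=1e-12)


def test_fiml_fully_missing_variable_equals_marginal_spec(complete_path_data):
    """Dropping a variable entirely must equal marginalising it out."""
    spec = PathModelSpec(
        exogenous=["nwc", "waist_z4"],
        equations={"waist_z7": [Edge("nwc", "waist_z7"), Edge("waist_z4", "waist_z7")]},
    )
    data = complete_path_data[["nwc", "waist_z4", "waist_z7"]].copy()
    data["nwc"] = np.nan
    res = fit(spec, data.assign(nwc=complete_path_data["nwc"]),
              standard_errors=False, fit_statistics=False)
    # evaluate the same parameters on data where nwc is never observed,
    # and compare against the analytic marginal over the remaining pair
    mu, Sig = implied_moments(spec, res.params)
    keep = [1, 2]
    marg = multivariate_normal(mu[keep], Sig[np.ix_(keep, keep)]).logpdf(
        data[["waist_z4", "waist_z7"]].to_numpy()
    ).sum()
    assert fiml_loglik(spec, res.params, data) == pytest.approx(marg, abs=1e-8)


# --------------------------------------------------------------------------
# fitting


def test_fit_equals_least_squares_on_complete_data(complete_path_data):
    spec = build_model("waist", "model2_age7")
    res = fit(spec, complete_path_data, standard_errors=False, fit_statistics=False)
    child = "waist_z7"
    parents = [e.parent for e in spec.equations[child]]
    X = np.column_stack(
        [np.ones(len(complete_path_data)), complete_path_data[parents].to_numpy()]
    )
    ols = np.linalg.lstsq(X, complete_path_data[child].to_numpy(), rcond=None)[0]
    fiml = [res.coefficient(child, p) for p in parents]
    np.testing.assert_allclose(fiml, ols[1:], atol=1e-6)


def test_saturated_model_has_perfect_fit(complete_path_data):
    spec = build_model("waist", "model2_age7")  # single equation: saturated
    res = fit(spec, complete_path_data, standard_errors=False)
    assert res.df == 0
    assert res.chi2 == pytest.approx(0.0, abs=1e-6)
    assert res.cfi == pytest.approx(1.0, abs=1e-9)
    assert res.rmsea == 0.0


def test_fit_with_mcar_missingness_recovers_tracking():
    rng = np.random.default_rng(13)
    frames = []
    spec = build_model("waist", "model2_age7")
    est = []
    for s in range(10):
        df = simulate_path_cohort("waist", 600, seed=100 + s)
        mask = rng.uniform(size=(len(df), 2)) < 0.25
        df.loc[mask[:, 0], "waist_z4"] = np.nan
        df.loc[mask[:, 1], "waist_z7"] = np.nan
        res = fit(spec, df, standard_errors=False, fit_statistics=False)
        est.append(res.coefficient("waist_z7", "waist_z4"))
    assert np.mean(est) == pytest.approx(0.725, abs=0.04)


# --------------------------------------------------------------------------
# bootstrap


def test_bootstrap_deterministic_and_brackets_estimate(complete_path_data):
    spec = build_model("waist", "model2_age7")
    ci1 = bootstrap_ci(spec, complete_path_data, n_boot=200, seed=7)
    ci2 = bootstrap_ci(spec, complete_path_data, n_boot=200, seed=7)
    pd.testing.assert_frame_equal(ci1, ci2)
    coefs = ci1[ci1["role"] == "coef"]
    assert (coefs["ci_lo"] <= coefs["estimate"]).all()
    assert (coefs["estimate"] <= coefs["ci_hi"]).all()


def test_bootstrap_degenerate_data_gives_zero_width():
    rng = np.random.default_rng(2)
    n = 150
    df = pd.DataFrame(
        {c: rng.standard_normal(n) for c in
         ["nwc", "maternal_education", "pre_pregnancy_bmi", "birthweight"]}
    )
    df["waist_z4"] = rng.standard_normal(n)
    df["waist_z7"] = 0.725 * df["waist_z4"]  # exactly, no residual noise
    spec = build_model("waist", "model2_age7")
    ci = bootstrap_ci(spec, df, n_boot=200, seed=1)
    row = ci[(ci["parent"] == "waist_z4")].iloc[0]
    assert float(row["ci_hi"] - row["ci_lo"]) < 1e-4


# --------------------------------------------------------------------------
# fit indices


@pytest.mark.parametrize(
    "args, expected_cfi, expected_rmsea",
    [
        ((20.0, 20, 200.0, 30, 301), 1.0, 0.0),  # chi2 == df
        ((30.0, 20, 30.0, 20, 301), 0.0, None),  # model no better than baseline
    ],
)
def test_fit_indices_anchors(args, expected_cfi, expected_rmsea):
    cfi, tli, rmsea = fit_indices(*args)
    assert cfi == pytest.approx(expected_cfi)
    if expected_rmsea is not None:
        assert rmsea == pytest.approx(expected_rmsea)


def test_fit_indices_rmsea_formula():
    cfi, tli, rmsea = fit_indices(30.0, 20, 200.0, 30, 301)
    assert rmsea == pytest.approx(np.sqrt(10.0 / 6000.0), abs=1e-6)


# --------------------------------------------------------------------------
# mediation


def test_effect_decomposition_identity():
    df = simulate_path_cohort("waist", 500, seed=77)
    spec = build_model("waist", "joint")
    res = fit(spec, df, standard_errors=False, fit_statistics=False)
    eff = res.effects.set_index("effect")["estimate"]
    a = res.coefficient("waist_z4", "nwc")
    b = res.coefficient("waist_z7", "waist_z4")
    direct = res.coefficient("waist_z7", "nwc")
    assert eff["indirect"] == pytest.approx(a * b, abs=1e-12)
    assert eff["total"] == pytest.approx(direct + a * b, abs=1e-12)


def test_total_effect_equals_marginal_coefficient():
    """For a linear recursive system with a shared conditioning set, the
    joint-model total effect equals the no-mediator regression coefficient."""
    df = simulate_path_cohort("waist", 400, seed=88)
    z4, z7 = "waist_z4", "waist_z7"
    confs = ["maternal_education", "pre_pregnancy_bmi", "gestational_age", "birthweight"]
    eq4 = [Edge("nwc", z4)] + [Edge(c, z4) for c in confs]
    eq7 = [Edge("nwc", z7)] + [Edge(c, z7) for c in confs] + [Edge(z4, z7)]
    joint = PathModelSpec(exogenous=["nwc"] + confs, equations={z4: eq4, z7: eq7})
    res = fit(joint, df, standard_errors=False, fit_statistics=False)
    total = res.effects.set_index("effect")["estimate"]["total"]

    marginal = PathModelSpec(
        exogenous=["nwc"] + confs,
        equations={z7: [Edge("nwc", z7)] + [Edge(c, z7) for c in confs]},
    )
    res_m = fit(marginal, df, standard_errors=False, fit_statistics=False)
    assert total == pytest.approx(res_m.coefficient(z7, "nwc"), abs=1e-6)


def test_effect_decomposition_requires_mediation_structure(complete_path_data):
    spec = build_model("waist", "model2_age7")
    res = fit(spec, complete_path_data, standard_errors=False, fit_statistics=False)
    with pytest.raises(ValueError):
        effect_decomposition(res)


# --------------------------------------------------------------------------
# correlations


def test_pearson_matrix_properties():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.standard_normal((1000, 4)), columns=list("abcd"))
    df.loc[rng.uniform(size=1000) < 0.1, "c"] = np.nan
    r, p, stars = pearson_matrix(df)
    assert np.allclose(np.diag(r), 1.0)
    assert np.allclose(r, r.T)
    off = r.to_numpy()[np.triu_indices(4, 1)]
    assert np.all(np.abs(off) < 0.1)  # independent variables


def test_pearson_matrix_recovers_generating_correlation():
    rng = np.random.default_rng(9)
    n = 2000
    x = rng.standard_normal(n)
    y = 0.776 * x + np.sqrt(1 - 0.776**2) * rng.standard_normal(n)
    r, p, stars = pearson_matrix(pd.DataFrame({"wc4": x, "wc7": y}))
    assert r.loc["wc4", "wc7"] == pytest.approx(0.776, abs=0.03)
    assert stars.loc["wc4", "wc7"] == "***"
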