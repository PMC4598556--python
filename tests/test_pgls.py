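"""PGLS against OLS/GLS oracles, lambda profiling, r^2, AIC and ranking."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cladediv as cd
from cladediv.pgls import PGLSError, PGLSFit


def _dataset(tree, rng, k=2, b=None):
    """Random design + response on the tree's taxa."""
    taxa = list(tree.tip_labels)
    n = len(taxa)
    X = pd.DataFrame(
        rng.normal(size=(n, k)), index=taxa,
        columns=[f"x{i}" for i in range(k)],
    )
    beta = b if b is not None else rng.normal(size=k)
    y = pd.Series(
        1.0 + X.to_numpy() @ beta + rng.normal(size=n), index=taxa, name="y"
    )
    return y, X


def test_lambda_zero_matches_ols_exactly(yule20, rng):
    """At lambda = 0 on an ultrametric tree, PGLS is OLS: coefficients,
    SEs, t P-values and model F P agree to 1e-8."""
    C = cd.vcv_matrix(yule20)
    for _ in range(20):
        y, X = _dataset(yule20, rng)
        fit = cd.gls_fit_fixed_lambda(y, X, C, 0.0)
        Xo = sm.add_constant(X.loc[list(C.taxa)].to_numpy())
        ols = sm.OLS(y.loc[list(C.taxa)].to_numpy(), Xo).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.bse.to_numpy(), ols.bse, atol=1e-8)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ols.pvalues, atol=1e-8)
        assert fit.model_P == pytest.approx(ols.f_pvalue, abs=1e-8)
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-8)


def test_lambda_one_matches_gls_whitening_oracle(yule20, rng):
    """At lambda = 1, coefficients match explicit Cholesky whitening + OLS
    and statsmodels GLS with sigma = C."""
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng)
    fit = cd.gls_fit_fixed_lambda(y, X, C, 1.0)

    yv = y.loc[list(C.taxa)].to_numpy()
    Xv = sm.add_constant(X.loc[list(C.taxa)].to_numpy())
    Linv = np.linalg.inv(np.linalg.cholesky(C.matrix))
    beta_oracle = np.linalg.lstsq(Linv @ Xv, Linv @ yv, rcond=None)[0]
    np.testing.assert_allclose(fit.params.to_numpy(), beta_oracle, atol=1e-8)

    gls = sm.GLS(yv, Xv, sigma=C.matrix).fit()
    np.testing.assert_allclose(fit.params.to_numpy(), gls.params, atol=1e-8)
    np.testing.assert_allclose(fit.bse.to_numpy(), gls.bse, atol=1e-8)


def test_constant_response_gives_zero_slopes_and_r2(yule20, rng):
    C = cd.vcv_matrix(yule20)
    _, X = _dataset(yule20, rng)
    y = pd.Series(3.14, index=list(yule20.tip_labels))
    fit = cd.gls_fit_fixed_lambda(y, X, C, 0.5)
    assert np.allclose(fit.params.drop("Intercept"), 0.0, atol=1e-10)
    assert fit.r_squared == 0.0


def test_perfect_linear_fit_r2_one(yule20):
    taxa = list(yule20.tip_labels)
    X = pd.DataFrame({"x0": np.arange(len(taxa), dtype=float)}, index=taxa)
    y = 2.0 + 3.0 * X["x0"]
    fit = cd.gls_fit_fixed_lambda(y, X, cd.vcv_matrix(yule20), 1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_collinear_design_names_columns(yule20, rng):
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng, k=1)
    X["dup"] = X["x0"]
    with pytest.raises(PGLSError, match="dup"):
        cd.gls_fit_fixed_lambda(y, X, C, 0.0)


def test_taxa_mismatch_rejected(yule20, rng):
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng)
    y.index = [f"zz_{t}" for t in y.index]
    with pytest.raises(PGLSError, match="mismatch"):
        cd.gls_fit_fixed_lambda(y, X, C, 0.0)


# -- lambda profiling -------------------------------------------------------

def test_star_phylogeny_ties_toward_lambda_one(rng):
    star_newick = "(" + ",".join(f"t{i}:10" for i in range(12)) + ");"
    star = cd.TimeTree.from_string(star_newick)
    C = cd.vcv_matrix(star, resolve_polytomies=True)
    y, X = _dataset(star, rng, k=1)
    fit = cd.profile_lambda_ml(y, X, C)
    assert fit.lambda_hat == 1.0  # likelihood flat in lambda: tie-break


def test_profiled_logl_at_least_endpoint_logl(yule20, rng):
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng)
    ml = cd.profile_lambda_ml(y, X, C)
    for lam in (0.0, 1.0):
        assert ml.logL >= cd.gls_fit_fixed_lambda(y, X, C, lam).logL - 1e-6


@pytest.mark.parametrize("lam_true,accept", [(1.0, lambda l: l >= 0.8),
                                             (0.0, lambda l: l <= 0.2)])
def test_lambda_recovery_calibration(lam_true, accept):
    """Strong-signal (lambda=1) and no-signal (lambda=0) data on a 100-tip
    tree recover the generating lambda in >= 90% of 30 replicates."""
    tree = cd.simulate_yule_tree(100, 100.0, seed=5)
    C = cd.vcv_matrix(tree)
    rng = np.random.default_rng(99)
    taxa = list(tree.tip_labels)
    noise = cd.simulate_brownian(tree, 1.0, lam_true, rng, size=30)
    hits = 0
    for i in range(30):
        y = pd.Series(noise[i], index=taxa)
        X = pd.DataFrame({"x0": rng.normal(size=len(taxa))}, index=taxa)
        fit = cd.profile_lambda_ml(y, X, C)
        hits += accept(fit.lambda_hat)
    assert hits >= 27


# -- r^2, AIC, comparison ---------------------------------------------------

def test_r_squared_single_predictor_equals_ols_closed_form(yule20, rng):
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng, k=1)
    fit = cd.gls_fit_fixed_lambda(y, X, C, 0.0)
    xv = X.loc[list(C.taxa), "x0"].to_numpy()
    yv = y.loc[list(C.taxa)].to_numpy()
    r = np.corrcoef(xv, yv)[0, 1]
    assert cd.r_squared(fit) == pytest.approx(r ** 2, abs=1e-10)


def test_aic_definition_and_recompute(yule20, rng):
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng)
    fixed = cd.gls_fit_fixed_lambda(y, X, C, 0.5)
    # k = 3 coefficients + sigma^2
    assert cd.aic(fixed) == pytest.approx(2 * 4 - 2 * fixed.logL)
    ml = cd.profile_lambda_ml(y, X, C)
    # lambda estimated: one more parameter
    assert cd.aic(ml) == pytest.approx(2 * 5 - 2 * ml.logL)


def _stub_fit(logL, k_coef, lambda_estimated=False, taxa=("a", "b", "c")):
    idx = pd.Index([f"c{i}" for i in range(k_coef)])
    z = pd.Series(np.zeros(k_coef), index=idx)
    return PGLSFit(
        params=z, bse=z, tvalues=z, pvalues=z, lambda_hat=1.0,
        lambda_estimated=lambda_estimated, sigma2_hat=1.0, logL=logL,
        r_squared=0.5, model_P=0.5, n=len(taxa), k_coef=k_coef,
        rss=1.0, tss=2.0, taxa=tuple(taxa), response="y",
    )


def test_model_compare_delta_two_for_one_extra_parameter():
    table = cd.model_compare([_stub_fit(-10.0, 2), _stub_fit(-10.0, 3)])
    assert table["delta_aic"].tolist() == pytest.approx([0.0, 2.0])


def test_model_compare_single_fit_delta_zero():
    assert cd.model_compare([_stub_fit(-1.0, 2)])["delta_aic"].iloc[0] == 0.0


def test_model_compare_rejects_mismatched_taxa():
    with pytest.raises(PGLSError, match="taxa"):
        cd.model_compare([_stub_fit(-1.0, 2), _stub_fit(-1.0, 2, taxa=("a", "b", "z"))])


def test_model_compare_orders_by_recomputed_aic(yule20, rng):
    C = cd.vcv_matrix(yule20)
    y, X = _dataset(yule20, rng, k=3)
    fits = [
        cd.profile_lambda_ml(y, X[cols], C)
        for cols in (["x0"], ["x1"], ["x2"], ["x0", "x1"], ["x0", "x1", "x2"])
    ]
    table = cd.model_compare(fits)
    oracle = sorted(2 * f.k_params - 2 * f.logL for f in fits)
    assert table["aic"].tolist() == pytest.approx(oracle)


# -- sampling properties ----------------------------------------------------

def test_slope_recovery_and_ci_coverage_on_brownian_data():
    """y = a + b*h + BM(lambda=1) on a 100-tip tree: over 200 replicates the
    mean slope estimate is within 2 Monte-Carlo SEs of truth and the 95% CI
    covers it at 0.95 +/- 0.04."""
    from scipy import stats as sps

    tree = cd.simulate_yule_tree(100, 100.0, seed=12)
    C = cd.vcv_matrix(tree)
    taxa = list(tree.tip_labels)
    rng = np.random.default_rng(2024)
    a, b, n_rep = 1.0, 0.5, 200
    noise = cd.simulate_brownian(tree, 0.02, 1.0, rng, size=n_rep)
    b_hats, covered = [], 0
    for i in range(n_rep):
        h = rng.beta(0.5, 0.5, size=len(taxa))
        y = pd.Series(a + b * h + noise[i], index=taxa)
        X = pd.DataFrame({"h": h}, index=taxa)
        fit = cd.profile_lambda_ml(y, X, C)
        b_hats.append(fit.params["h"])
        half = sps.t.ppf(0.975, fit.df_resid) * fit.bse["h"]
        covered += abs(fit.params["h"] - b) <= half
    b_hats = np.asarray(b_hats)
    mc_se = b_hats.std(ddof=1) / np.sqrt(n_rep)
    assert abs(b_hats.mean() - b) <= 2 * mc_se
    assert covered / n_rep == pytest.approx(0.95, abs=0.04)
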