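"""Phylogenetic generalized least squares with maximum-likelihood Pagel's lambda.

The model is y = X beta + e, e ~ N(0, sigma^2 * C_lambda), where C_lambda is
the tree's Brownian covariance with off-diagonal entries scaled by Pagel's
lambda (kappa and delta fixed at 1). lambda is either fixed or profiled by
maximum likelihood over [0, 1], evaluating both endpoints and breaking exact
ties toward lambda = 1 (ties arise only on star phylogenies, where the
likelihood is flat in lambda).

Conventions, stated because software differs:

* sigma^2 for the likelihood (hence logL and AIC) is the ML estimate
  RSS/n in the whitened space.
* Coefficient standard errors, t and F tests use the unbiased residual
  variance RSS/(n - k), so a fit at lambda = 0 on an ultrametric tree
  reproduces ordinary least squares exactly.
* r^2 = 1 - RSS/TSS in the lambda-hat-whitened space, with TSS taken from
  the intercept-only GLS fit at the same lambda.
* AIC = 2k - 2 logL with k = #coefficients + 1 (sigma^2) + 1 more when
  lambda is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloCovariance, apply_lambda

_LAMBDA_XATOL = 1e-8
_TIE_TOL = 1e-9


class PGLSError(ValueError):
    """Invalid input to, or numerical failure of, a PGLS fit."""


@dataclass
class PGLSFit:
    """A fitted phylogenetic regression."""

    params: pd.Series            # coefficient estimates, index = column names
    bse: pd.Series               # standard errors (unbiased variance)
    tvalues: pd.Series
    pvalues: pd.Series           # two-sided t tests on n - k df
    lambda_hat: float
    lambda_estimated: bool       # True when lambda was profiled by ML
    sigma2_hat: float            # ML residual variance (RSS/n, whitened)
    logL: float
    r_squared: float
    model_P: float               # F test of all non-intercept terms
    n: int
    k_coef: int                  # number of regression coefficients
    rss: float
    tss: float
    taxa: tuple[str, ...]
    response: str = "y"

    @property
    def df_resid(self) -> int:
        return self.n - self.k_coef

    @property
    def k_params(self) -> int:
        """Parameters counted by AIC: coefficients + sigma^2 (+ lambda if ML)."""
        return self.k_coef + 1 + (1 if self.lambda_estimated else 0)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.logL

    def formula(self) -> str:
        terms = [c for c in self.params.index if c != "Intercept"]
        return f"{self.response} ~ " + (" + ".join(terms) if terms else "1")


def _prepare(y, X, C: PhyloCovariance):
    """Align y, X, C on the same taxa; return arrays + column names."""
    if isinstance(y, pd.Series) and isinstance(X, pd.DataFrame):
        if set(y.index) != set(X.index) or set(y.index) != set(C.taxa):
            raise PGLSError(
                "taxa mismatch between y, X and C: "
                f"y-only={sorted(set(y.index) - set(C.taxa))}, "
                f"C-only={sorted(set(C.taxa) - set(y.index))}"
            )
        X = X.loc[list(C.taxa)]
        y = y.loc[list(C.taxa)]
        cols = list(X.columns)
        Xv, yv = X.to_numpy(float), y.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        yv = np.asarray(y, float)
        if Xv.shape[0] != len(C.taxa) or yv.shape[0] != len(C.taxa):
            raise PGLSError("y/X length does not match number of taxa in C")
        cols = [f"x{i}" for i in range(Xv.shape[1])]
    if "Intercept" not in cols:
        Xv = np.column_stack([np.ones(len(yv)), Xv])
        cols = ["Intercept"] + cols
    n, k = Xv.shape
    if n <= k:
        raise PGLSError(f"need n > k, got n={n}, k={k}")
    return yv, Xv, cols


def _whiten(V: np.ndarray):
    """Cholesky factor of V and its log-determinant."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise PGLSError(f"covariance not positive definite: {exc}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return L, logdet


def gls_fit_fixed_lambda(
    y,
    X,
    C: PhyloCovariance,
    lam: float,
    *,
    lambda_estimated: bool = False,
    response: str = "y",
) -> PGLSFit:
    """GLS fit at a fixed Pagel's lambda.

    ``y`` and ``X`` may be pandas objects indexed by taxon label (aligned to
    ``C.taxa``) or plain arrays already in ``C.taxa`` order. An intercept
    column is added if absent.
    """
    if not (0.0 <= lam <= 1.0):
        raise PGLSError(f"lambda must be in [0, 1], got {lam}")
    yv, Xv, cols = _prepare(y, X, C)
    n, k = Xv.shape

    V = apply_lambda(C, lam).matrix if C.lambda_applied == "raw" else C.matrix
    L, logdetV = _whiten(V)
    z = linalg.solve_triangular(L, yv, lower=True)
    W = linalg.solve_triangular(L, Xv, lower=True)

    if np.linalg.matrix_rank(W) < k:
        # name the offending columns for the error message
        _, R = np.linalg.qr(W)
        bad = [cols[i] for i in range(k) if abs(R[i, i]) < 1e-10 * max(1, abs(R[0, 0]))]
        raise PGLSError(f"singular design matrix; collinear columns: {bad}")

    beta, _, _, _ = np.linalg.lstsq(W, z, rcond=None)
    resid = z - W @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logL = _mvn_logl(n, sigma2_ml, logdetV)

    s2_unb = rss / (n - k)
    XtX_inv = np.linalg.inv(W.T @ W)
    bse = np.sqrt(s2_unb * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    # intercept-only fit at the same lambda for TSS / r^2 / model F
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ z) / float(ones_w @ ones_w)
    tss = float(np.sum((z - mu * ones_w) ** 2))

    r2 = _r_squared_from_ss(rss, tss)
    q = k - 1
    if q > 0 and rss > 0:
        F = ((tss - rss) / q) / (rss / (n - k))
        model_P = float(stats.f.sf(F, q, n - k))
    elif q > 0:
        model_P = 0.0  # perfect fit
    else:
        model_P = float("nan")

    idx = pd.Index(cols)
    return PGLSFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        lambda_hat=lam,
        lambda_estimated=lambda_estimated,
        sigma2_hat=sigma2_ml,
        logL=logL,
        r_squared=r2,
        model_P=model_P,
        n=n,
        k_coef=k,
        rss=rss,
        tss=tss,
        taxa=tuple(C.taxa),
        response=response,
    )


def _mvn_logl(n: int, sigma2_ml: float, logdetV: float) -> float:
    if sigma2_ml <= 0:
        # degenerate perfect fit: likelihood unbounded; report +inf logL
        return float("inf")
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdetV + n)


def _r_squared_from_ss(rss: float, tss: float) -> float:
    if tss <= 0:
        if rss <= 1e-30:
            return 0.0  # constant response fitted exactly by the intercept
        raise PGLSError("zero whitened response variance; r^2 undefined")
    return float(np.clip(1.0 - rss / tss, 0.0, 1.0))


def profile_lambda_ml(y, X, C: PhyloCovariance, *, response: str = "y") -> PGLSFit:
    """Profile the likelihood over lambda in [0, 1] and return the ML fit.

    Bounded scalar optimization plus explicit evaluation of both endpoints;
    exact ties (likelihood flat, e.g. star phylogeny) resolve toward
    lambda = 1.
    """
    if C.lambda_applied != "raw":
        raise PGLSError("profile_lambda_ml needs the raw (untransformed) covariance")
    yv, Xv, cols = _prepare(y, X, C)
    n, k = Xv.shape

    def negll(lam: float) -> float:
        V = apply_lambda(C, lam).matrix
        L, logdetV = _whiten(V)
        z = linalg.solve_triangular(L, yv, lower=True)
        W = linalg.solve_triangular(L, Xv, lower=True)
        beta, _, _, _ = np.linalg.lstsq(W, z, rcond=None)
        rss = float(np.sum((z - W @ beta) ** 2))
        ll = _mvn_logl(n, rss / n, logdetV)
        if np.isnan(ll):
            raise PGLSError(f"non-finite log-likelihood at lambda={lam}")
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": _LAMBDA_XATOL},
    )
    candidates = [float(res.x), 0.0, 1.0]
    lls = [-negll(lam) for lam in candidates]
    best = max(lls)
    # among candidates within tie tolerance of the max, take the largest lambda
    lam_hat = max(
        lam for lam, ll in zip(candidates, lls) if ll >= best - _TIE_TOL
    )
    return gls_fit_fixed_lambda(
        y, X, C, lam_hat, lambda_estimated=True, response=response
    )


def r_squared(fit: PGLSFit) -> float:
    """Proportion of whitened variance explained, recomputed from stored SS."""
    return _r_squared_from_ss(fit.rss, fit.tss)


def aic(fit: PGLSFit) -> float:
    """AIC = 2k - 2 logL; k counts coefficients, sigma^2, and lambda if ML."""
    return fit.aic


def model_compare(fits: list[PGLSFit]) -> pd.DataFrame:
    """Rank fits of the same response on the same taxa by AIC.

    Returns a table sorted by AIC ascending with a delta-AIC column.
    """
    if not fits:
        raise PGLSError("no fits to compare")
    taxa0, resp0 = set(fits[0].taxa), fits[0].response
    for f in fits[1:]:
        if set(f.taxa) != taxa0:
            raise PGLSError(
                "fits are on different taxa sets: "
                f"{sorted(taxa0 ^ set(f.taxa))}"
            )
        if f.response != resp0:
            raise PGLSError(
                f"fits have different responses: {resp0!r} vs {f.response!r}"
            )
    rows = [{
        "formula": f.formula(),
        "n": f.n,
        "lambda_hat": f.lambda_hat,
        "r_squared": f.r_squared,
        "model_P": f.model_P,
        "logL": f.logL,
        "k": f.k_params,
        "aic": f.aic,
    } for f in fits]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
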