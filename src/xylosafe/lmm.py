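"""Linear mixed-effects trait models with random site intercepts.

One model per hydraulic response (P12, P50, P88, log slope, Ks):

.. math::

    y_{ij} = \\beta_0 + \\sum_k \\beta_k z(x_{k,ij}) + b_i + e_{ij},
    \\qquad b_i \\sim N(0, \\sigma_b^2),\\; e_{ij} \\sim N(0, \\sigma_e^2)

with tree *j* in site *i*, predictors z-scored (branch age on the
natural-log scale) so that fixed effects are per-SD effect sizes and the
intercept equals the response mean.  Estimation is REML; the base fit
comes from :class:`statsmodels` ``MixedLM`` and is then polished by
maximizing the closed-form profiled REML criterion for the
random-intercept model (grouped Woodbury identities), which this module
also uses for Satterthwaite degrees of freedom.

Inference per coefficient is a Wald t test with Satterthwaite's
approximation: df = 2·Var(β̂_k)² / Var̂(Var(β̂_k)), with the variance of
the coefficient variance obtained from the gradient of Var(β̂_k) with
respect to (σ_b², σ_e²) and the inverse observed REML information.

Variance decomposition follows Nakagawa & Schielzeth: with
σ_f² = var(Xβ̂) the marginal R² is σ_f²/(σ_f²+σ_b²+σ_e²), the
conditional R² adds σ_b² to the numerator, and the three shares of
(σ_f², σ_b², σ_e²) sum to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from xylosafe.errors import DomainError, InputError

__all__ = [
    "ScalingRecord",
    "LMMResult",
    "prepare_model_frame",
    "fit_lmm",
    "wald_t_tests",
    "nakagawa_r2",
    "variance_fractions",
    "correlation_screen",
    "fit_trait_models",
    "TRAIT_RESPONSES",
    "TRAIT_PREDICTORS",
]

TRAIT_PREDICTORS = ("CWB", "AWC", "height", "log_branch_age", "CI")
TRAIT_RESPONSES = ("P12", "P50", "P88", "log_slope", "Ks")


# ---------------------------------------------------------------------------
# model frame preparation
# ---------------------------------------------------------------------------

@dataclass
class ScalingRecord:
    """Centring/scaling constants used to standardize predictors."""

    means: dict[str, float]
    sds: dict[str, float]
    n_dropped: int = 0

    def back_transform(self, predictor: str, beta_scaled: float) -> float:
        """Per-SD coefficient back to the raw predictor scale."""
        return beta_scaled / self.sds[predictor]


def prepare_model_frame(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = ("CWB", "AWC", "height", "branch_age", "CI"),
    log_predictors: tuple[str, ...] = ("branch_age",),
    log_responses: tuple[str, ...] = ("slope",),
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Design table: log transforms, then centre and SD-scale predictors.

    Branch age enters the design on the natural-log scale (column
    renamed ``log_branch_age``), the slope response is natural-log
    transformed (``log_slope``).  Every numeric predictor is centred on
    zero and scaled by its sample SD; the constants are returned so that
    per-SD coefficients can be mapped back to raw units.  Rows with any
    missing modelled value are dropped listwise and counted.
    """
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise InputError(f"model table missing predictor columns: {missing}")

    frame = table.copy()
    used_cols = list(predictors) + [c for c in log_responses if c in frame.columns]
    n0 = len(frame)
    frame = frame.dropna(subset=[c for c in used_cols if c in frame.columns])
    n_dropped = n0 - len(frame)

    for col in log_responses:
        if col in frame.columns:
            if (frame[col] <= 0).any():
                raise DomainError(f"response {col!r} must be positive before log transform")
            frame[f"log_{col}"] = np.log(frame[col].astype(float))

    means, sds = {}, {}
    out_predictors = []
    for col in predictors:
        vals = frame[col].astype(float)
        name = col
        if col in log_predictors:
            if (vals <= 0).any():
                raise DomainError(f"predictor {col!r} must be positive before log transform")
            vals = np.log(vals)
            name = f"log_{col}"
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise InputError(f"predictor {col!r} has zero variance; cannot be scaled")
        frame[name] = (vals - mu) / sd
        means[name], sds[name] = mu, sd
        out_predictors.append(name)

    frame.attrs["predictors"] = tuple(out_predictors)
    return frame, ScalingRecord(means=means, sds=sds, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# closed-form REML machinery for the random-intercept model
# ---------------------------------------------------------------------------

class _GroupedData:
    """Sufficient statistics for a random-intercept LMM."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        codes, _ = pd.factorize(groups)
        order = np.argsort(codes, kind="mergesort")
        Xs, ys, cs = X[order], y[order], codes[order]
        self.ng = np.bincount(cs).astype(float)
        self.G = self.ng.size
        bounds = np.concatenate([[0], np.cumsum(self.ng).astype(int)])
        self.S = np.add.reduceat(Xs, bounds[:-1], axis=0)          # (G, p) column sums
        self.sy = np.add.reduceat(ys, bounds[:-1])                  # (G,)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _whitened(self, c: np.ndarray):
        """X'WX, X'Wy, y'Wy for W = I − diag-blocks c_g J (up to 1/σ²)."""
        A = self.XtX - self.S.T @ (c[:, None] * self.S)
        b = self.Xty - self.S.T @ (c * self.sy)
        yWy = self.yty - float(np.sum(c * self.sy**2))
        return A, b, yWy

    def profiled_m2ll(self, lam: float) -> float:
        """−2·REML log-likelihood profiled over β and σ_e², given λ = σ_b²/σ_e²."""
        c = lam / (1.0 + self.ng * lam)
        A, b, yWy = self._whitened(c)
        beta = np.linalg.solve(A, b)
        rss_w = yWy - float(beta @ b)
        if rss_w <= 0:
            return np.inf
        npp = self.n - self.p
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        s2e = rss_w / npp
        return (
            npp * math.log(2.0 * math.pi)
            + npp * math.log(s2e)
            + float(np.sum(np.log1p(self.ng * lam)))
            + logdetA
            + npp
        )

    def reml_loglik(self, s2b: float, s2e: float) -> float:
        """REML log-likelihood at given variance components."""
        if s2e <= 0 or s2b < 0:
            return -np.inf
        c = s2b / (s2e + self.ng * s2b)
        A, b, yWy = self._whitened(c)  # these are σ_e²·(X'V⁻¹X) etc.
        XtViX = A / s2e
        XtViy = b / s2e
        yViy = yWy / s2e
        beta = np.linalg.solve(XtViX, XtViy)
        quad = yViy - float(beta @ XtViy)
        logdetV = float(np.sum((self.ng - 1.0) * math.log(s2e) + np.log(s2e + self.ng * s2b)))
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (
            (self.n - self.p) * math.log(2.0 * math.pi) + logdetV + logdetXtViX + quad
        )

    def gls(self, lam: float):
        """β̂, cov(β̂), σ̂_e² at a given variance ratio λ."""
        c = lam / (1.0 + self.ng * lam)
        A, b, yWy = self._whitened(c)
        beta = np.linalg.solve(A, b)
        rss_w = yWy - float(beta @ b)
        s2e = rss_w / (self.n - self.p)
        cov_beta = s2e * np.linalg.inv(A)
        return beta, cov_beta, s2e

    def var_beta(self, s2b: float, s2e: float) -> np.ndarray:
        """diag of (X'V⁻¹X)⁻¹ as a function of the variance components."""
        c = s2b / (s2e + self.ng * s2b)
        A, _, _ = self._whitened(c)
        return np.diag(np.linalg.inv(A / s2e)).copy()


def _maximize_reml(gd: _GroupedData, lam_start: float | None = None) -> float:
    """Maximize the profiled REML criterion over λ = σ_b²/σ_e² ≥ 0.

    The criterion is unimodal in log λ for the random-intercept model; a
    bounded scalar search in log space (in a window around ``lam_start``
    when one is supplied, e.g. from a statsmodels base fit) locates the
    optimum to machine precision, with an explicit check of the λ = 0
    boundary (singular fit).
    """
    f = gd.profiled_m2ll
    if lam_start is not None and lam_start > 1e-10:
        lo, hi = math.log(lam_start) - 6.0, math.log(lam_start) + 6.0
    else:
        lo, hi = math.log(1e-12), math.log(1e6)
    res = optimize.minimize_scalar(
        lambda t: f(math.exp(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    lam = math.exp(res.x)
    # a seeded window may miss the optimum if the seed was poor; widen once
    if lam_start is not None and (hi - res.x < 1e-3 or res.x - lo < 1e-3):
        return _maximize_reml(gd, None)
    # boundary: a singular fit (σ_b² → 0) wins if it has a lower criterion
    if f(0.0) <= f(lam) + 1e-12:
        return 0.0
    return lam


# ---------------------------------------------------------------------------
# result container and the fit itself
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Fitted random-intercept model for one trait response."""

    response: str
    coefs: pd.DataFrame           # estimate, se, df, t, p per fixed effect
    site_sd: float
    residual_sd: float
    marginal_r2: float
    conditional_r2: float
    var_fractions: tuple[float, float, float]  # fixed, site, residual
    n_used: int
    n_groups: int
    loglik: float
    singular: bool = False
    df_fallback: bool = False
    design: np.ndarray = field(repr=False, default=None)
    scaling: "ScalingRecord | None" = field(repr=False, default=None)
    _grouped: _GroupedData = field(repr=False, default=None)


def _satterthwaite_df(gd: _GroupedData, s2b: float, s2e: float) -> tuple[np.ndarray, bool]:
    """Satterthwaite df per coefficient; returns (df, used_fallback)."""
    n, p = gd.n, gd.p
    resid_df = float(n - p)
    theta = np.array([s2b, s2e])
    try:
        # gradient of each coefficient variance wrt the variance components
        grads = np.empty((p, 2))
        v0 = gd.var_beta(s2b, s2e)
        for j in range(2):
            h = max(1e-7, 1e-5 * theta[j])
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] = max(tm[j] - h, 0.0 if j == 0 else 1e-12)
            vp = gd.var_beta(tp[0], tp[1])
            vm = gd.var_beta(tm[0], tm[1])
            grads[:, j] = (vp - vm) / (tp[j] - tm[j])
        # observed information of the REML log-likelihood
        H = np.empty((2, 2))
        hs = [max(1e-6, 1e-4 * theta[j]) for j in range(2)]

        def ll(a, b):
            return gd.reml_loglik(max(a, 0.0), b)

        for j in range(2):
            e = np.zeros(2)
            e[j] = hs[j]
            H[j, j] = (ll(*(theta + e)) - 2.0 * ll(*theta) + ll(*(theta - e))) / hs[j] ** 2
        e0 = np.array([hs[0], 0.0])
        e1 = np.array([0.0, hs[1]])
        H[0, 1] = H[1, 0] = (
            ll(*(theta + e0 + e1))
            - ll(*(theta + e0 - e1))
            - ll(*(theta - e0 + e1))
            + ll(*(theta - e0 - e1))
        ) / (4.0 * hs[0] * hs[1])
        info = -H
        cov_theta = np.linalg.inv(info)
        if not np.all(np.isfinite(cov_theta)):
            raise np.linalg.LinAlgError
        denom = np.einsum("pj,jk,pk->p", grads, cov_theta, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * v0**2 / denom
        bad = ~np.isfinite(df) | (df <= 0)
        if bad.any():
            df[bad] = resid_df
            return df, True
        return np.minimum(df, resid_df * 10), False
    except (np.linalg.LinAlgError, ValueError):
        return np.full(p, resid_df), True


def fit_lmm(
    frame: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = TRAIT_PREDICTORS,
    group: str = "site_id",
) -> LMMResult:
    """REML random-intercept fit of one trait response.

    The statsmodels ``MixedLM`` REML estimate seeds the variance ratio,
    which is then polished against the closed-form profiled REML
    criterion so the optimum is located to machine precision.  A
    boundary solution (site variance 0) is returned with
    ``singular=True`` rather than raised.
    """
    cols = [response, group, *predictors]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise InputError(f"model frame missing columns: {missing}")
    data = frame.dropna(subset=cols)
    groups = data[group].to_numpy()
    if len(np.unique(groups)) < 2:
        raise InputError("need at least 2 groups for a random-intercept model")

    y = data[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors])
    names = ["(Intercept)", *predictors]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("design matrix is rank deficient")

    gd = _GroupedData(X, y, groups)

    # base REML fit via statsmodels; its variance ratio seeds the
    # closed-form polish, which reaches machine precision and handles
    # the σ_b² = 0 boundary explicitly
    from statsmodels.regression.mixed_linear_model import MixedLM

    lam_start = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            sm_fit = MixedLM(y, X, groups=groups).fit(reml=True)
            if sm_fit.scale > 0:
                lam_start = float(np.squeeze(sm_fit.cov_re)) / float(sm_fit.scale)
        except Exception:
            pass
    lam = _maximize_reml(gd, lam_start)

    beta, cov_beta, s2e = gd.gls(lam)
    s2b = lam * s2e
    singular = lam <= 1e-10
    se = np.sqrt(np.diag(cov_beta))
    df, fallback = _satterthwaite_df(gd, s2b, s2e)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)

    coefs = pd.DataFrame(
        {"estimate": beta, "se": se, "df": df, "t": t, "p": pvals}, index=names
    )

    var_fixed = float(np.var(X @ beta, ddof=1))
    total = var_fixed + s2b + s2e
    if total <= 0:
        raise DomainError("total variance is zero; R² undefined")
    marginal = var_fixed / total
    conditional = (var_fixed + s2b) / total
    fractions = (var_fixed / total, s2b / total, s2e / total)

    return LMMResult(
        response=response,
        coefs=coefs,
        site_sd=math.sqrt(s2b),
        residual_sd=math.sqrt(s2e),
        marginal_r2=marginal,
        conditional_r2=conditional,
        var_fractions=fractions,
        n_used=len(data),
        n_groups=gd.G,
        loglik=gd.reml_loglik(s2b, s2e),
        singular=singular,
        df_fallback=fallback,
        design=X,
        _grouped=gd,
    )


def wald_t_tests(result: LMMResult) -> pd.DataFrame:
    """Per-coefficient Wald t statistics with Satterthwaite df.

    t = estimate / SE with two-sided p from the t distribution; the df
    come from Satterthwaite's variance-ratio approximation evaluated at
    the REML variance-component estimates.
    """
    if (result.coefs["se"] <= 0).any():
        zero = result.coefs.index[result.coefs["se"] <= 0].tolist()
        raise DomainError(f"zero standard error for {zero}; inference degenerate")
    return result.coefs[["t", "df", "p"]].copy()


def nakagawa_r2(result: LMMResult) -> tuple[float, float]:
    """(marginal R², conditional R²) of a fitted random-intercept model."""
    return result.marginal_r2, result.conditional_r2


def variance_fractions(result: LMMResult) -> tuple[float, float, float]:
    """Shares of fixed-effect, site and residual variance (sum to 1)."""
    return result.var_fractions


def correlation_screen(
    table: pd.DataFrame,
    columns: tuple[str, ...] | None = None,
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among predictors with a collinearity flag.

    Returns the correlation matrix and the list of pairs with
    |r| ≥ ``threshold``.  A constant column makes its correlations
    undefined and is reported as an error.
    """
    if columns is None:
        columns = tuple(table.select_dtypes(include=[np.number]).columns)
    if len(table) < 3:
        raise InputError("need at least 3 rows for a correlation screen")
    sub = table[list(columns)].astype(float)
    constant = [c for c in columns if sub[c].std(ddof=1) == 0]
    if constant:
        raise DomainError(f"correlation undefined for constant column(s): {constant}")
    corr = sub.corr(method="pearson")
    flags = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(columns)
        for b in columns[i + 1 :]
        if abs(corr.loc[a, b]) >= threshold
    ]
    return corr, flags


def fit_trait_models(
    trait_table: pd.DataFrame,
    responses: tuple[str, ...] = TRAIT_RESPONSES,
    group: str = "site_id",
) -> dict[str, LMMResult]:
    """The five standard trait models (P12, P50, P88, log slope, Ks).

    Prepares the design (log branch age, log slope, z-scored predictors)
    and fits one REML random-intercept model per response.  No
    multiple-testing correction is applied across the five models.
    """
    frame, scaling = prepare_model_frame(trait_table)
    results: dict[str, LMMResult] = {}
    for resp in responses:
        if resp not in frame.columns:
            raise InputError(f"response column {resp!r} missing from trait table")
        results[resp] = fit_lmm(frame, resp, TRAIT_PREDICTORS, group=group)
        results[resp].scaling = scaling
    return results
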