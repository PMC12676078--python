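"""Mixed-effects models for plant traits and diversity-environment analyses.

Gaussian responses are fit by REML through statsmodels' MixedLM with crossed
random intercepts (genotype, glasshouse block) expressed as variance
components. Binomial responses (tillering status) are fit by a Laplace
approximation to the maximum likelihood of a logistic mixed model, since the
contracts here need likelihood-ratio chi-square term tests that no installed
Python solver provides.

Per-term tests
--------------
* gaussian, marginal: Wald F on the term's coefficient block using the REML
  fixed-effect covariance; denominator df follow a containment rule (terms
  constant within genotype are tested against genotype-level df, all others
  against residual df after subtracting random-intercept df).
* gaussian, sequential: Type-I F from sequential projections of the
  GLS-whitened design (whitening by the estimated marginal covariance), which
  reduces to classical sequential ANOVA when the random variances are zero.
* binomial: likelihood-ratio chi-square comparing the full model to the model
  with the term removed (marginal) or terms added in order (sequential),
  always respecting marginality (a term is only removable if no higher-order
  interaction contains it).

A fitted random-effect variance near zero is reported as a singular fit and
retained, not dropped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "FittedMixedModel",
    "fit_mixed_model",
    "anova_table",
    "fit_env_diversity_model",
    "full_factorial",
    "signif_code",
]

SINGULAR_TOL = 1e-6


def full_factorial(factors: Sequence[str]) -> list[str]:
    """All main effects and interactions of the given factors, in marginal
    order (mains, then two-way, then three-way, ...)."""
    from itertools import combinations

    terms = []
    for k in range(1, len(factors) + 1):
        for combo in combinations(factors, k):
            terms.append(":".join(combo))
    return terms


@dataclass
class ModelSpec:
    """Declares a mixed model: response, family, ordered fixed terms and
    random-intercept grouping factors."""

    response: str
    fixed: list[str]
    random: list[str] = field(default_factory=lambda: ["genotype", "block"])
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Patsy design matrices plus per-term column slices (intercept excluded)."""
    y, X = patsy.dmatrices(spec.formula(), data, return_type="dataframe")
    info = X.design_info
    slices = {
        term.name(): info.term_name_slices[term.name()]
        for term in info.terms
        if term.name() != "Intercept"
    }
    return np.asarray(y).ravel(), np.asarray(X), list(X.columns), slices


def _term_key(term: str) -> frozenset:
    return frozenset(p.strip() for p in term.split(":"))


def _ordered_terms(fit: "FittedMixedModel") -> list[str]:
    """Patsy term names in the order the model spec declared them."""
    by_key = {_term_key(t): t for t in fit.term_slices}
    out = []
    for term in fit.spec.fixed:
        key = _term_key(term)
        if key in by_key:
            out.append(by_key[key])
    return out


def _random_indicators(data: pd.DataFrame, random: Sequence[str]):
    mats, levels = [], []
    for g in random:
        if g not in data.columns:
            raise KeyError(f"random grouping {g!r} not a data column")
        dummies = pd.get_dummies(data[g].astype(str))
        if dummies.shape[1] < 2:
            raise ValueError(f"random factor {g!r} needs >= 2 levels")
        mats.append(dummies.to_numpy(float))
        levels.append(list(dummies.columns))
    return mats, levels


@dataclass
class FittedMixedModel:
    spec: ModelSpec
    data: pd.DataFrame
    params: pd.Series                 # fixed-effect estimates
    cov_params: pd.DataFrame          # covariance of fixed effects
    vcomp: dict[str, float]           # random-intercept variances
    scale: float                      # residual variance (gaussian) / 1.0
    loglike: float                    # ML log-likelihood (binomial: Laplace)
    singular: bool
    term_slices: dict[str, slice]
    X: np.ndarray
    y: np.ndarray
    converged: bool = True

    @property
    def singular_terms(self) -> list[str]:
        return [g for g, v in self.vcomp.items() if v < SINGULAR_TOL * max(self.scale, 1e-12)]


# ---------------------------------------------------------------------------
# Gaussian: REML via statsmodels MixedLM with variance components
# ---------------------------------------------------------------------------

def _fit_ols(data: pd.DataFrame, spec: ModelSpec) -> FittedMixedModel:
    import statsmodels.formula.api as smf

    res = smf.ols(spec.formula(), data).fit()
    y, X, colnames, slices = _design(data, spec)
    return FittedMixedModel(
        spec=spec, data=data,
        params=pd.Series(np.asarray(res.params), index=colnames),
        cov_params=pd.DataFrame(np.asarray(res.cov_params()),
                                index=colnames, columns=colnames),
        vcomp={}, scale=float(res.mse_resid), loglike=float(res.llf),
        singular=False, term_slices=slices, X=X, y=y,
    )


def _fit_gaussian(data: pd.DataFrame, spec: ModelSpec) -> FittedMixedModel:
    import statsmodels.formula.api as smf

    if not spec.random:
        return _fit_ols(data, spec)
    vc = {g: f"0 + C({g})" for g in spec.random}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            spec.formula(), data, groups=np.ones(len(data)), vc_formula=vc
        )
        try:
            res = model.fit(reml=True, method="lbfgs")
            if not res.converged:
                res = model.fit(reml=True, method="powell")
        except Exception:
            res = model.fit(reml=True, method="powell")
    if not res.converged:
        raise RuntimeError(
            f"gaussian mixed model did not converge for {spec.response!r}; "
            f"optimizer message: {getattr(res, 'optim_message', '<none>')}"
        )
    y, X, colnames, slices = _design(data, spec)
    k = X.shape[1]
    params = pd.Series(np.asarray(res.fe_params), index=colnames)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=colnames, columns=colnames
    )
    vcomp = {g: float(v) for g, v in zip(spec.random, res.vcomp)}
    scale = float(res.scale)
    singular = any(v < SINGULAR_TOL * scale for v in vcomp.values())
    return FittedMixedModel(
        spec=spec, data=data, params=params, cov_params=cov, vcomp=vcomp,
        scale=scale, loglike=float(res.llf), singular=singular,
        term_slices=slices, X=X, y=y,
    )


# ---------------------------------------------------------------------------
# Binomial: Laplace-approximate ML logistic mixed model
# ---------------------------------------------------------------------------

def _laplace_logistic(y, X, Zs, log_sigmas, beta_u0=None, max_iter=200):
    """Joint penalized Newton for (beta, u) at fixed variances; returns the
    Laplace log-marginal-likelihood and components."""
    n, p = X.shape
    qs = [Z.shape[1] for Z in Zs]
    q = sum(qs)
    A = np.hstack([X] + list(Zs))
    sigma2 = np.repeat(np.exp(2.0 * np.asarray(log_sigmas)), qs)
    pen = np.concatenate([np.zeros(p), 1.0 / np.maximum(sigma2, 1e-12)])
    theta = np.zeros(p + q) if beta_u0 is None else beta_u0.copy()
    for _ in range(max_iter):
        eta = A @ theta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = A.T @ (y - mu) - pen * theta
        H = (A.T * w) @ A + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # halving line search on the penalized objective
        def obj(t):
            e = A @ t
            return float(
                y @ e - np.sum(np.logaddexp(0.0, e)) - 0.5 * np.sum(pen * t * t)
            )
        f0 = obj(theta)
        lam = 1.0
        while lam > 1e-6:
            cand = theta + lam * step
            if obj(cand) >= f0 - 1e-12:
                break
            lam /= 2.0
        theta = theta + lam * step
        if np.max(np.abs(lam * step)) < 1e-9:
            break
    eta = A @ theta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    u = theta[p:]
    ll_cond = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    penalty = 0.5 * float(np.sum(pen[p:] * u * u))
    Zall = A[:, p:]
    M = (Zall.T * w) @ Zall * sigma2[None, :]  # Z'WZ D
    sign, logdet = np.linalg.slogdet(np.eye(q) + M)
    ll = ll_cond - penalty - 0.5 * logdet
    H_beta = (X.T * w) @ X  # for Wald covariance (conditional on u-hat)
    return dict(theta=theta, loglike=ll, H_beta=H_beta, mu=mu)


def _fit_binomial(data: pd.DataFrame, spec: ModelSpec) -> FittedMixedModel:
    y, X, colnames, slices = _design(data, spec)
    y = np.asarray(y, float)
    Zs, _ = _random_indicators(data, spec.random)
    if not Zs:
        res = _laplace_logistic(y, X, Zs, np.empty(0))
        log_sig = np.empty(0)
        converged = True
    else:
        state = {"theta0": None}

        def negll(log_sigmas):
            r = _laplace_logistic(y, X, Zs, log_sigmas, beta_u0=state["theta0"])
            state["theta0"] = r["theta"]
            return -r["loglike"]

        opt = optimize.minimize(
            negll, x0=np.full(len(Zs), -1.0), method="Nelder-Mead",
            options=dict(xatol=1e-4, fatol=1e-7, maxiter=400),
        )
        log_sig = np.clip(opt.x, -8.0, 4.0)
        res = _laplace_logistic(y, X, Zs, log_sig, beta_u0=state["theta0"])
        converged = bool(opt.success or np.isfinite(opt.fun))
    p = X.shape[1]
    beta = res["theta"][:p]
    try:
        cov = np.linalg.inv(res["H_beta"])
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(res["H_beta"])
    vcomp = {g: float(np.exp(2 * s)) for g, s in zip(spec.random, log_sig)}
    singular = any(v < SINGULAR_TOL for v in vcomp.values())
    return FittedMixedModel(
        spec=spec, data=data,
        params=pd.Series(beta, index=colnames),
        cov_params=pd.DataFrame(cov, index=colnames, columns=colnames),
        vcomp=vcomp, scale=1.0, loglike=float(res["loglike"]),
        singular=singular, term_slices=slices, X=X, y=y,
        converged=converged,
    )


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> FittedMixedModel:
    """Fit a mixed model with random intercepts for each grouping in
    ``spec.random`` (REML for gaussian, Laplace ML for binomial).

    Zero-variance random effects are flagged (``.singular``) but retained in
    the model, keeping the design's pseudoreplication structure explicit.
    """
    cols = set(data.columns)
    needed = {spec.response, *spec.random}
    for term in spec.fixed:
        needed.update(p.strip() for p in term.split(":"))
    missing = needed - cols
    if missing:
        raise KeyError(f"model columns missing from data: {sorted(missing)}")
    data = data.dropna(subset=sorted(needed)).reset_index(drop=True)
    for g in spec.random:
        if data[g].nunique() < 2:
            raise ValueError(f"random factor {g!r} needs >= 2 levels")
    if spec.family == "gaussian":
        return _fit_gaussian(data, spec)
    return _fit_binomial(data, spec)


# ---------------------------------------------------------------------------
# ANOVA tables
# ---------------------------------------------------------------------------

def signif_code(p: float) -> str:
    if np.isnan(p):
        return ""
    for thr, code in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, ".")):
        if p <= thr:
            return code
    return ""


def _constant_within(X_cols: np.ndarray, groups: pd.Series) -> bool:
    df = pd.DataFrame(X_cols)
    df["__g"] = groups.to_numpy()
    return bool((df.groupby("__g").nunique() <= 1).all().all())


def _containment_df(fit: FittedMixedModel, term: str) -> float:
    """Denominator df by a containment rule.

    A term whose columns are constant within a random grouping is tested at
    that grouping's level: df = (#levels) - rank of the grouping-level fixed
    design. Terms varying within all groupings use residual df:
    n - rank(X) - sum_k (levels_k - 1).
    """
    X = fit.X
    sl = fit.term_slices[term]
    rank_X = np.linalg.matrix_rank(X)
    n = X.shape[0]
    best = None
    for g in fit.spec.random:
        groups = fit.data[g].astype(str).reset_index(drop=True)
        if _constant_within(X[:, sl], groups):
            # grouping-level design: unique rows of the genotype-constant columns
            const_cols = [
                j for j in range(X.shape[1])
                if _constant_within(X[:, [j]], groups)
            ]
            collapsed = (
                pd.DataFrame(X[:, const_cols]).assign(__g=groups.to_numpy())
                .groupby("__g").first().to_numpy()
            )
            df = groups.nunique() - np.linalg.matrix_rank(collapsed)
            best = df if best is None else min(best, df)
    if best is not None:
        return float(max(best, 1))
    df_res = n - rank_X - sum(
        fit.data[g].nunique() - 1 for g in fit.spec.random
    )
    return float(max(df_res, 1))


def _gaussian_marginal(fit: FittedMixedModel) -> list[dict]:
    rows = []
    V = fit.cov_params.to_numpy()
    beta = fit.params.to_numpy()
    for term in _ordered_terms(fit):
        sl = fit.term_slices[term]
        idx = list(range(*sl.indices(len(beta))))
        b = beta[idx]
        Vb = V[np.ix_(idx, idx)]
        q = len(idx)
        try:
            stat = float(b @ np.linalg.solve(Vb, b)) / q
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(Vb) @ b) / q
        dfd = _containment_df(fit, term)
        p = float(stats.f.sf(stat, q, dfd))
        rows.append(dict(term=term, df=q, df_denom=dfd, statistic=stat, p=p))
    return rows


def _gaussian_sequential(fit: FittedMixedModel) -> list[dict]:
    # marginal covariance V = scale*I + sum_k vcomp_k Z_k Z_k'
    n = fit.X.shape[0]
    V = fit.scale * np.eye(n)
    Zs, _ = _random_indicators(fit.data, fit.spec.random)
    for g, Z in zip(fit.spec.random, Zs):
        V += fit.vcomp[g] * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, fit.X)
    yw = np.linalg.solve(L, fit.y)
    from scipy.linalg import orth

    terms = _ordered_terms(fit)
    cum = orth(Xw[:, :1])  # whitened intercept column
    incr = []
    for term in terms:
        sl = fit.term_slices[term]
        new = orth(np.hstack([cum, Xw[:, sl]]))
        incr.append((term, sl, new, cum))
        cum = new
    resid = yw - cum @ (cum.T @ yw)
    df_res = n - cum.shape[1] - sum(
        fit.data[g].nunique() - 1 for g in fit.spec.random
    )
    df_res = max(df_res, 1)
    ms_res = float(resid @ resid) / df_res
    rows = []
    for term, sl, new, old in incr:
        proj_new = new.T @ yw
        proj_old = old.T @ yw
        ss = float(proj_new @ proj_new - proj_old @ proj_old)
        q = new.shape[1] - old.shape[1]
        stat = (ss / q) / ms_res
        dfd = _containment_df(fit, term)
        p = float(stats.f.sf(stat, q, dfd))
        rows.append(dict(term=term, df=q, df_denom=dfd, statistic=stat, p=p))
    return rows


def _binomial_lrt(fit: FittedMixedModel, kind: str) -> list[dict]:
    terms = _ordered_terms(fit)

    def refit(term_list: list[str]) -> float:
        m = fit_mixed_model(
            fit.data,
            ModelSpec(fit.spec.response, term_list, fit.spec.random, "binomial"),
        )
        return m.loglike

    rows = []
    if kind == "marginal":
        # Type-II: each term tested against the model of all terms that do
        # not contain it (marginality respected)
        for term in terms:
            key = _term_key(term)
            reduced = [t for t in terms if t != term and not key <= _term_key(t)]
            ll_red = refit(reduced)
            ll_full = refit(reduced + [term])
            df = fit.term_slices[term].stop - fit.term_slices[term].start
            chi2 = max(2.0 * (ll_full - ll_red), 0.0)
            rows.append(dict(
                term=term, df=df, df_denom=np.nan, statistic=chi2,
                p=float(stats.chi2.sf(chi2, df)),
            ))
    else:
        prev_ll = refit([])
        included: list[str] = []
        for term in terms:
            included.append(term)
            ll = refit(list(included))
            df = fit.term_slices[term].stop - fit.term_slices[term].start
            chi2 = max(2.0 * (ll - prev_ll), 0.0)
            rows.append(dict(
                term=term, df=df, df_denom=np.nan, statistic=chi2,
                p=float(stats.chi2.sf(chi2, df)),
            ))
            prev_ll = ll
    return rows


def anova_table(fit: FittedMixedModel, type: str = "marginal") -> pd.DataFrame:
    """Per-term test statistics: F for gaussian fits, likelihood-ratio
    chi-square for binomial fits, with significance codes."""
    if type not in ("marginal", "sequential"):
        raise ValueError("type must be 'marginal' or 'sequential'")
    if fit.spec.family == "gaussian":
        rows = _gaussian_marginal(fit) if type == "marginal" else _gaussian_sequential(fit)
        stat_name = "F"
    else:
        rows = _binomial_lrt(fit, type)
        stat_name = "chi2"
    df = pd.DataFrame(rows)
    df = df.rename(columns={"statistic": stat_name})
    df["signif"] = [signif_code(p) for p in df["p"]]
    df.attrs["singular_fit"] = fit.singular
    df.attrs["singular_terms"] = fit.singular_terms
    return df


# ---------------------------------------------------------------------------
# Diversity / relative-abundance vs historic environment
# ---------------------------------------------------------------------------

def fit_env_diversity_model(
    metric: pd.DataFrame,
    metric_col: str,
    metadata: pd.DataFrame,
    env: pd.Series,
    random: Sequence[str] = ("genotype", "block"),
) -> dict:
    """Mixed model of a per-sample community metric on a standardized
    genotype-level environmental covariate.

    ``metric`` must carry ``sample_id``; ``env`` is indexed by genotype.
    Returns the slope (per SD of the covariate), its SE, test statistics and
    the full fit.
    """
    merged = metric.merge(metadata, on="sample_id", how="inner")
    if merged[metric_col].nunique() <= 1:
        raise ValueError(f"metric {metric_col!r} is constant; no model to fit")
    envz = (env - env.mean()) / env.std(ddof=0)
    merged["env_z"] = envz.loc[merged["genotype"].astype(str)].to_numpy()
    spec = ModelSpec(response=metric_col, fixed=["env_z"], random=list(random))
    fit = fit_mixed_model(merged, spec)
    tab = anova_table(fit, type="marginal")
    slope = float(fit.params["env_z"])
    se = float(np.sqrt(fit.cov_params.loc["env_z", "env_z"]))
    return dict(
        slope=slope,
        se=se,
        p=float(tab.loc[tab["term"] == "env_z", "p"].iloc[0]),
        anova=tab,
        fit=fit,
    )
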