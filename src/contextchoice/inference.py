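"""Mixed-effects regressions and the concordance analysis.

Every analysis model takes all fixed effects as random effects over users
(or participants).  Two fitting paths share one output schema:

``fast``
    Pooled maximum likelihood (statsmodels GLM/OLS) with cluster-robust
    standard errors by user, plus empirical-Bayes one-step shrinkage to
    recover per-user coefficients: a penalized Newton step from the pooled
    fit per user, shrunk elementwise by a method-of-moments estimate of the
    between-user variance.

``mcmc``
    A Gibbs / Metropolis-within-Gibbs sampler for the full random-slopes
    hierarchy: per-user coefficient vectors beta_u ~ Normal(mu, diag(tau^2)),
    weak Normal(0, 10^2) priors on the fixed effects mu (predictors are
    standardized internally) and half-Normal(5) priors on the random-effect
    SDs tau.  Gaussian responses use conjugate updates; logistic user blocks
    and the tau's use random-walk Metropolis.  Split-R-hat and effective
    sample size come from arviz; fits with R-hat > 1.05 are flagged.

Coefficients are reported on the original predictor scale.  The reported
``tail_prob`` is 2 * min(P(beta > 0), P(beta < 0)) — a two-sided posterior
tail probability on the MCMC path, and the Wald p-value on the fast path.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "ConcordanceResult",
    "fit_mixed",
    "choice_context_model",
    "rating_deviation_model",
    "distractor_model",
    "expectation_rating_model",
    "subject_effects",
    "concordance",
    "catch_trial_exclusion",
]

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "log1p": np.log1p,
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-effects regression."""

    response: str
    family: str  # "bernoulli-logit" | "gaussian-identity"
    terms: tuple  # of (column, transform) pairs
    grouping: str | None = None
    method: str = "fast"  # "fast" | "mcmc"
    n_chains: int = 2
    n_draws: int = 400
    n_warmup: int = 400
    seed: int = 0
    prior_scale: float = 10.0
    re_sd_scale: float = 5.0

    def validate(self) -> None:
        if self.family not in ("bernoulli-logit", "gaussian-identity"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.method not in ("fast", "mcmc"):
            raise ValueError(f"unknown method {self.method!r}")
        for col, tr in self.terms:
            if tr not in _TRANSFORMS:
                raise ValueError(f"unknown transform {tr!r} for {col!r}")


@dataclass
class RegressionFit:
    """Posterior (or asymptotic) summary of one regression.

    ``summary`` is indexed by term with columns estimate / ci_low / ci_high /
    tail_prob, on the original predictor scale.  ``user_effects`` holds the
    conditional per-user coefficients (one row per user) when the model had
    a grouping column.
    """

    summary: pd.DataFrame
    user_effects: pd.DataFrame | None
    diagnostics: dict
    spec: ModelSpec

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def term(self, name: str) -> pd.Series:
        if name not in self.summary.index:
            raise KeyError(f"term {name!r} not in fit; have {list(self.summary.index)}")
        return self.summary.loc[name]

    def to_dict(self) -> dict:
        return {
            "terms": {
                t: {
                    "estimate": float(r["estimate"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                    "tail_prob": float(r["tail_prob"]),
                }
                for t, r in self.summary.iterrows()
            },
            "diagnostics": {
                k: (v if not isinstance(v, (np.floating, np.integer)) else float(v))
                for k, v in self.diagnostics.items()
            },
        }


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------


def _build_design(table: pd.DataFrame, spec: ModelSpec):
    cols = [spec.response] + [c for c, _ in spec.terms]
    if spec.grouping:
        cols.append(spec.grouping)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
    df = table[cols].dropna()
    y = df[spec.response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"response {spec.response!r} has zero variance")
    names = ["(Intercept)"]
    X = [np.ones(len(df))]
    means, scales = [0.0], [1.0]
    for col, tr in spec.terms:
        x = df[col].to_numpy(dtype=float)
        if tr == "log" and np.any(x <= 0):
            raise ValueError(f"log transform needs strictly positive {col!r}")
        x = _TRANSFORMS[tr](x)
        m, s = float(x.mean()), float(x.std())
        if s == 0:
            # a constant predictor carries no information; drop it rather
            # than fail (small datasets can degenerate, e.g. one price tier)
            logger.warning("dropping constant predictor %r", col)
            continue
        X.append((x - m) / s)
        names.append(col if tr == "identity" else f"log_{col}" if tr == "log" else f"log1p_{col}")
        means.append(m)
        scales.append(s)
    X = np.column_stack(X)
    groups = None
    if spec.grouping:
        groups, _ = pd.factorize(df[spec.grouping])
    return y, X, names, np.array(means), np.array(scales), groups, df


def _back_transform(beta_std: np.ndarray, means: np.ndarray, scales: np.ndarray):
    """Map coefficients on standardized predictors back to the input scale."""
    beta = beta_std / scales
    beta[0] = beta_std[0] - float(np.sum(beta_std[1:] * means[1:] / scales[1:]))
    return beta


# --------------------------------------------------------------------------
# fast path: pooled ML + cluster-robust errors + EB per-user effects
# --------------------------------------------------------------------------


def _fit_pooled(y, X, family, groups):
    kwargs = (
        {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
        if groups is not None and len(np.unique(groups)) > 1
        else {"cov_type": "HC1"}
    )
    if family == "gaussian-identity":
        return sm.OLS(y, X).fit(**kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.GLM(y, X, family=sm.families.Binomial()).fit(**kwargs)
        except Exception:
            # separation or non-convergence: light ridge regularization
            logger.warning("pooled logit failed; refitting with ridge penalty")
            return _ridge_logit(y, X, alpha=1e-3)


class _RidgeLogitResult:
    """Minimal result shim for a ridge-penalized logistic fit."""

    def __init__(self, params, cov):
        self.params = params
        self._cov = cov
        self.bse = np.sqrt(np.diag(cov))

    def conf_int(self):
        z = 1.959963984540054
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    @property
    def pvalues(self):
        from scipy import stats as _st

        z = self.params / self.bse
        return 2 * _st.norm.sf(np.abs(z))


def _ridge_logit(y, X, alpha=1e-3, max_iter=100):
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + alpha * np.eye(p)
        g = X.T @ (y - mu) - alpha * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None]) + alpha * np.eye(p)
    return _RidgeLogitResult(beta, np.linalg.inv(H))


def _eb_user_effects(y, X, beta_std, family, groups, sigma2=1.0):
    """One-step empirical-Bayes per-user deltas around the pooled fit.

    For each user, a single penalized Newton step from the pooled
    coefficients gives a raw per-user deviation with sampling variance from
    the local Fisher information; deviations are then shrunk elementwise by
    tau^2 / (tau^2 + V) where tau^2 is the method-of-moments between-user
    variance (observed spread minus mean sampling variance).
    """
    p = X.shape[1]
    uids = np.unique(groups)
    deltas = np.zeros((len(uids), p))
    varis = np.zeros((len(uids), p))
    eps = 1e-6
    if family == "gaussian-identity":
        # the one-step delta (X'X)^-1 X'r is free of sigma^2; estimate the
        # *within*-user residual variance afterwards so between-user
        # heterogeneity does not inflate the sampling variances
        inv_xtx = []
        rss, ndof = 0.0, 0
        for i, u in enumerate(uids):
            m = groups == u
            Xu, yu = X[m], y[m]
            Hr = Xu.T @ Xu + eps * np.eye(p)
            inv_xtx.append(np.linalg.inv(Hr))
            deltas[i] = inv_xtx[i] @ (Xu.T @ (yu - Xu @ beta_std))
            resid = yu - Xu @ (beta_std + deltas[i])
            rss += float(resid @ resid)
            ndof += max(1, len(yu) - p)
        sigma2_within = rss / ndof
        for i in range(len(uids)):
            varis[i] = sigma2_within * np.diag(inv_xtx[i])
    else:
        for i, u in enumerate(uids):
            m = groups == u
            Xu, yu = X[m], y[m]
            eta = Xu @ beta_std
            mu = 1.0 / (1.0 + np.exp(-eta))
            W = mu * (1 - mu)
            H = Xu.T @ (Xu * W[:, None])
            s = Xu.T @ (yu - mu)
            Hr = H + eps * np.eye(p)
            deltas[i] = np.linalg.solve(Hr, s)
            varis[i] = np.diag(np.linalg.inv(Hr))
    # floor at 2% of the mean sampling variance: an exact zero would collapse
    # every subject effect onto the fixed effect and leave downstream
    # individual-difference analyses degenerate
    vbar = varis.mean(axis=0)
    tau2 = np.maximum(deltas.var(axis=0) - vbar, 0.02 * vbar)
    shrink = tau2 / (tau2 + varis)
    return uids, beta_std[None, :] + shrink * deltas


# --------------------------------------------------------------------------
# MCMC path: random-slopes hierarchy
# --------------------------------------------------------------------------


def _log_lik_logit(beta, Xu, yu):
    eta = Xu @ beta
    return float(yu @ eta - np.sum(np.logaddexp(0.0, eta)))


def _mcmc_hierarchical(y, X, groups, spec: ModelSpec):
    p = X.shape[1]
    gaussian = spec.family == "gaussian-identity"
    pooled = _fit_pooled(y, X, spec.family, groups)
    beta0 = np.asarray(pooled.params)
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
        pooled_only = True
    else:
        pooled_only = len(np.unique(groups)) == 1
    uids = np.unique(groups)
    G = len(uids)
    idx = [np.flatnonzero(groups == u) for u in uids]
    Xg = [X[m] for m in idx]
    yg = [y[m] for m in idx]
    # per-user proposal covariances from local curvature at the pooled fit
    chols = []
    for Xu in Xg:
        if gaussian:
            H = Xu.T @ Xu
        else:
            eta = Xu @ beta0
            mu = 1.0 / (1.0 + np.exp(-eta))
            H = Xu.T @ (Xu * (mu * (1 - mu))[:, None])
        chols.append(np.linalg.cholesky(np.linalg.inv(H + 0.5 * np.eye(p))))

    n_iter = spec.n_warmup + spec.n_draws
    mu_chains = np.zeros((spec.n_chains, spec.n_draws, p))
    beta_u_sum = np.zeros((G, p))
    prior_prec = 1.0 / spec.prior_scale**2

    for chain in range(spec.n_chains):
        rng = np.random.default_rng(spec.seed + 1000 * chain)
        mu = beta0.copy()
        tau = np.full(p, 0.3)
        tau_step = np.full(p, 0.3)  # adapted during warmup toward ~40% acceptance
        tau_acc = np.zeros(p)
        beta_u = np.tile(beta0, (G, 1))
        sigma2 = float(np.var(y - X @ beta0)) if gaussian else 1.0
        kept = 0
        for it in range(n_iter):
            D_inv = 1.0 / tau**2
            if pooled_only:
                # no hierarchy: beta_u == mu, sampled directly from the data
                if gaussian:
                    P = X.T @ X / sigma2 + prior_prec * np.eye(p)
                    m = np.linalg.solve(P, X.T @ y / sigma2)
                    L = np.linalg.cholesky(np.linalg.inv(P))
                    mu = m + L @ rng.standard_normal(p)
                else:
                    prop = mu + 0.6 * (chols[0] @ rng.standard_normal(p))
                    cur = _log_lik_logit(mu, X, y) - 0.5 * prior_prec * mu @ mu
                    new = _log_lik_logit(prop, X, y) - 0.5 * prior_prec * prop @ prop
                    if math.log(rng.random()) < new - cur:
                        mu = prop
                beta_u[0] = mu
            else:
                if gaussian:
                    # collapsed update: mu | y, tau, sigma2 with beta_u
                    # integrated out (Woodbury), then beta_u | mu conjugate;
                    # collapsing removes the centered-parametrization funnel
                    P_mu = prior_prec * np.eye(p)
                    b_mu = np.zeros(p)
                    for g in range(G):
                        A = Xg[g].T @ Xg[g] / sigma2
                        a = Xg[g].T @ yg[g] / sigma2
                        C = np.linalg.inv(np.diag(D_inv) + A)
                        P_mu += A - A @ C @ A
                        b_mu += a - A @ C @ a
                    cov_mu = np.linalg.inv(P_mu)
                    mu = cov_mu @ b_mu + np.linalg.cholesky(cov_mu) @ rng.standard_normal(p)
                for g in range(G):
                    if gaussian:
                        P = Xg[g].T @ Xg[g] / sigma2 + np.diag(D_inv)
                        m = np.linalg.solve(
                            P, Xg[g].T @ yg[g] / sigma2 + D_inv * mu
                        )
                        L = np.linalg.cholesky(np.linalg.inv(P))
                        beta_u[g] = m + L @ rng.standard_normal(p)
                    else:
                        b = beta_u[g]
                        prop = b + 0.8 * (chols[g] @ rng.standard_normal(p))
                        cur = _log_lik_logit(b, Xg[g], yg[g]) - 0.5 * np.sum(
                            D_inv * (b - mu) ** 2
                        )
                        new = _log_lik_logit(prop, Xg[g], yg[g]) - 0.5 * np.sum(
                            D_inv * (prop - mu) ** 2
                        )
                        if math.log(rng.random()) < new - cur:
                            beta_u[g] = prop
                if not gaussian:
                    # fixed effects mu | beta_u, tau
                    P = G * D_inv + prior_prec
                    m = (D_inv * beta_u.sum(axis=0)) / P
                    mu = m + rng.standard_normal(p) / np.sqrt(P)
                # random-effect SDs tau_j | beta_u, mu  (half-normal prior);
                # tau floored at 1e-3 to avoid the degenerate funnel when a
                # random effect is absent
                for j in range(p):
                    lt = math.log(tau[j])
                    lt_new = lt + tau_step[j] * rng.standard_normal()
                    t_new = max(math.exp(lt_new), 1e-3)
                    dev = beta_u[:, j] - mu[j]

                    def _lp(t):
                        return (
                            -G * math.log(t)
                            - 0.5 * float(dev @ dev) / t**2
                            - 0.5 * t**2 / spec.re_sd_scale**2
                            + math.log(t)  # Jacobian of the log transform
                        )

                    if math.log(rng.random()) < _lp(t_new) - _lp(tau[j]):
                        tau[j] = t_new
                        tau_acc[j] += 1
                if it < spec.n_warmup and (it + 1) % 50 == 0:
                    rate = tau_acc / 50.0
                    tau_step *= np.where(rate < 0.25, 0.7, np.where(rate > 0.6, 1.4, 1.0))
                    tau_acc[:] = 0
            if gaussian:
                resid = np.concatenate(
                    [yg[g] - Xg[g] @ beta_u[g] for g in range(G)]
                ) if not pooled_only else y - X @ mu
                a = 0.001 + 0.5 * len(y)
                b = 0.001 + 0.5 * float(resid @ resid)
                sigma2 = 1.0 / rng.gamma(a, 1.0 / b)
            if it >= spec.n_warmup:
                mu_chains[chain, it - spec.n_warmup] = mu
                beta_u_sum += beta_u
                kept += 1
    beta_u_mean = beta_u_sum / (spec.n_chains * spec.n_draws)
    return mu_chains, uids, beta_u_mean


def _mcmc_summary(mu_chains):
    import arviz as az

    flat = mu_chains.reshape(-1, mu_chains.shape[-1])
    est = flat.mean(axis=0)
    lo = np.percentile(flat, 2.5, axis=0)
    hi = np.percentile(flat, 97.5, axis=0)
    n = len(flat)
    pos = (flat > 0).mean(axis=0)
    tail = np.clip(2 * np.minimum(pos, 1 - pos), 1.0 / n, 1.0)
    idata = az.from_dict(posterior={"mu": mu_chains})
    rhat = np.asarray(az.rhat(idata)["mu"])
    ess = np.asarray(az.ess(idata)["mu"])
    return est, lo, hi, tail, float(np.nanmax(rhat)), float(np.nanmin(ess))


# --------------------------------------------------------------------------
# the public fitting entry point
# --------------------------------------------------------------------------


def fit_mixed(table: pd.DataFrame, spec: ModelSpec) -> RegressionFit:
    """Fit one mixed-effects regression per the model specification."""
    spec.validate()
    y, X, names, means, scales, groups, df = _build_design(table, spec)
    diagnostics: dict = {
        "method": spec.method,
        "n_obs": int(len(y)),
        "n_groups": int(len(np.unique(groups))) if groups is not None else None,
        "converged": True,
    }
    if spec.method == "fast":
        res = _fit_pooled(y, X, spec.family, groups)
        beta_std = np.asarray(res.params)
        ci_std = np.asarray(res.conf_int())
        tail = np.asarray(res.pvalues)
        est = _back_transform(beta_std, means, scales)
        lo = _back_transform(ci_std[:, 0].copy(), means, scales)
        hi = _back_transform(ci_std[:, 1].copy(), means, scales)
        # back-transform can flip interval ordering for the intercept
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        user_eff = None
        if groups is not None and len(np.unique(groups)) > 1:
            sigma2 = float(np.var(y - X @ beta_std)) if spec.family == "gaussian-identity" else 1.0
            uids, eff_std = _eb_user_effects(y, X, beta_std, spec.family, groups, sigma2)
            eff = np.vstack([_back_transform(e.copy(), means, scales) for e in eff_std])
            labels = pd.unique(df[spec.grouping])
            user_eff = pd.DataFrame(eff, index=pd.Index(labels, name=spec.grouping), columns=names)
    else:
        mu_chains, uids, beta_u = _mcmc_hierarchical(y, X, groups, spec)
        est_s, lo_s, hi_s, tail, rhat_max, ess_min = _mcmc_summary(mu_chains)
        est = _back_transform(est_s.copy(), means, scales)
        lo = _back_transform(lo_s.copy(), means, scales)
        hi = _back_transform(hi_s.copy(), means, scales)
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        diagnostics.update(rhat_max=rhat_max, ess_min=ess_min, converged=rhat_max <= 1.05)
        if not diagnostics["converged"]:
            logger.warning("MCMC fit flagged: max R-hat %.3f > 1.05", rhat_max)
        user_eff = None
        if groups is not None and len(np.unique(groups)) > 1:
            eff = np.vstack([_back_transform(e.copy(), means, scales) for e in beta_u])
            labels = pd.unique(df[spec.grouping])
            user_eff = pd.DataFrame(eff, index=pd.Index(labels, name=spec.grouping), columns=names)
    summary = pd.DataFrame(
        {"estimate": est, "ci_low": lo, "ci_high": hi, "tail_prob": tail},
        index=pd.Index(names, name="term"),
    )
    return RegressionFit(summary=summary, user_effects=user_eff, diagnostics=diagnostics, spec=spec)


# --------------------------------------------------------------------------
# the named analysis models
# --------------------------------------------------------------------------


def _grouping_or_none(table: pd.DataFrame, col: str) -> str | None:
    if col in table.columns and table[col].notna().all() and table[col].nunique() > 1:
        return col
    return None


def choice_context_model(
    choice_table: pd.DataFrame, method: str = "fast", seed: int = 0, **kw
) -> RegressionFit:
    """Ratings-maximizing choice vs the set's rating composition.

    Logistic regression of the target indicator on the set mean (the context
    effect), log set size, log review count and price of the top option, and
    the set's rating variance, with per-user random effects.
    """
    spec = ModelSpec(
        response="is_target",
        family="bernoulli-logit",
        terms=(
            ("mean_set", "identity"),
            ("n_options", "log"),
            ("n_reviews_top", "log"),
            ("price_top", "identity"),
            ("var_set", "identity"),
        ),
        grouping=_grouping_or_none(choice_table, "user_id"),
        method=method,
        seed=seed,
        **kw,
    )
    return fit_mixed(choice_table, spec)


def rating_deviation_model(
    choice_table: pd.DataFrame, method: str = "fast", seed: int = 0, **kw
) -> RegressionFit:
    """Post-choice rating deviation vs the context (set mean excluding chosen)."""
    spec = ModelSpec(
        response="rating_deviation",
        family="gaussian-identity",
        terms=(
            ("raw_prior_mean_chosen", "identity"),
            ("review_text_length", "log1p"),
            ("n_reviews_chosen", "log"),
            ("price_chosen", "identity"),
            ("mean_set_excl_chosen", "identity"),
            ("n_options", "log"),
        ),
        grouping=_grouping_or_none(choice_table, "user_id"),
        method=method,
        seed=seed,
        **kw,
    )
    return fit_mixed(choice_table, spec)


def distractor_model(
    distractor_table: pd.DataFrame,
    include_gap: bool = True,
    method: str = "fast",
    seed: int = 0,
    **kw,
) -> RegressionFit:
    """Top-vs-second choice vs distractor quality (IIA test), top-two subset.

    ``gap12`` (the top-two rating difference) and the log count of options
    tied at the second-highest rating are included by default: under an
    IIA-satisfying chooser the top-vs-second log-odds equal
    gap/temperature − log(k2), and both quantities correlate with the
    distractor mean across sets, so omitting them biases the null.
    ``include_gap=False`` drops both for the covariate-free variant.
    """
    terms = [
        ("distractor_mean", "identity"),
        ("n_options", "log"),
        ("n_reviews_top", "log"),
        ("price_top", "identity"),
    ]
    if include_gap:
        terms.append(("gap12", "identity"))
        if "n_second_ties" in distractor_table.columns:
            terms.append(("n_second_ties", "log"))
    spec = ModelSpec(
        response="is_target",
        family="bernoulli-logit",
        terms=tuple(terms),
        grouping=_grouping_or_none(distractor_table, "user_id"),
        method=method,
        seed=seed,
        **kw,
    )
    return fit_mixed(distractor_table, spec)


def expectation_rating_model(
    rating_table: pd.DataFrame, method: str = "fast", seed: int = 0, **kw
) -> RegressionFit:
    """Expected-satisfaction ratings vs the context mean (experiment)."""
    spec = ModelSpec(
        response="satisfaction",
        family="gaussian-identity",
        terms=(
            ("r_highlighted", "identity"),
            ("n_reviews_highlighted", "log"),
            ("price_highlighted", "identity"),
            ("mean_set_excl_highlighted", "identity"),
            ("n_options", "log"),
        ),
        grouping=_grouping_or_none(rating_table, "participant_id"),
        method=method,
        seed=seed,
        **kw,
    )
    return fit_mixed(rating_table, spec)


def subject_effects(fit: RegressionFit, term: str) -> pd.Series:
    """Conditional per-user coefficients for one term."""
    if fit.user_effects is None:
        raise ValueError("fit has no per-user effects (no grouping column)")
    if term not in fit.user_effects.columns:
        raise KeyError(f"term {term!r} not in fit; have {list(fit.user_effects.columns)}")
    return fit.user_effects[term]


# --------------------------------------------------------------------------
# Study-2-style concordance
# --------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    median_split: pd.DataFrame
    robust_slope: float
    robust_intercept: float
    bootstrap_p: float
    slope_ci: tuple

    def to_dict(self) -> dict:
        return {
            "robust_slope": self.robust_slope,
            "bootstrap_p": self.bootstrap_p,
            "slope_ci": list(self.slope_ci),
            "median_split": self.median_split.to_dict(orient="list"),
        }


def _huber_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:  # fully shrunk subject effects: no slope identified
        return 0.0, float(np.median(y))
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    return float(res.params[1]), float(res.params[0])


def concordance(
    choice_effects: pd.Series,
    rating_effects: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> ConcordanceResult:
    """Relate per-subject choice context effects to rating context effects.

    Median-splits subjects on the choice context effect and reports the mean
    rating effect per half, then fits a Huber robust regression of rating
    effects on choice effects; the slope's two-sided p-value and 95% CI come
    from a case-resampling bootstrap.
    """
    joined = pd.concat(
        {"choice": choice_effects, "rating": rating_effects}, axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 subjects with both effects")
    x = joined["choice"].to_numpy()
    y = joined["rating"].to_numpy()
    med = float(np.median(x))
    weak = x >= med  # closer to zero for negative context effects
    split = pd.DataFrame(
        {
            "group": ["weak_choice_effect", "strong_choice_effect"],
            "n": [int(weak.sum()), int((~weak).sum())],
            "mean_choice_effect": [float(x[weak].mean()), float(x[~weak].mean())],
            "mean_rating_effect": [float(y[weak].mean()), float(y[~weak].mean())],
        }
    )
    slope, intercept = _huber_slope(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        i = rng.integers(0, n, size=n)
        if np.ptp(x[i]) == 0:
            boots[b] = 0.0
            continue
        boots[b], _ = _huber_slope(x[i], y[i])
    p = 2 * min((boots <= 0).mean(), (boots >= 0).mean())
    p = float(min(1.0, max(p, 1.0 / (n_boot + 1))))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return ConcordanceResult(
        median_split=split,
        robust_slope=slope,
        robust_intercept=intercept,
        bootstrap_p=p,
        slope_ci=ci,
    )


def catch_trial_exclusion(
    trials: Sequence, min_accuracy: float = 0.6
) -> tuple[list, dict]:
    """Retain participants answering >= 60% of catch trials correctly.

    A catch response is correct when the chosen option's displayed rating
    ties the set maximum.  Returns (retained participant ids, accuracy per
    participant).  A participant with no catch trials is an input error.
    """
    participants = sorted({t.participant_id for t in trials})
    correct: dict[str, list] = {p: [] for p in participants}
    for t in trials:
        if t.trial_type != "catch":
            continue
        disp = t.snapshot.displayed
        chosen = t.snapshot.option(t.response_choice)
        correct[t.participant_id].append(chosen.displayed_rating == disp.max())
    accuracy = {}
    for p in participants:
        if not correct[p]:
            raise ValueError(f"participant {p!r} has no catch trials")
        accuracy[p] = float(np.mean(correct[p]))
    retained = [p for p in participants if accuracy[p] >= min_accuracy]
    return retained, accuracy
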