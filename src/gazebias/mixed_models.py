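"""Random-intercept mixed models for trial-level gaze outcomes.

Two engines, both written directly against the single-random-intercept
structure of a repeated-trials design (trials nested in subjects):

* :func:`fit_lmm` — linear mixed model y = X b + Z u + e, u_i ~ N(0, s_b^2),
  estimated by REML.  The fixed effects and residual variance are profiled
  out analytically, leaving a one-dimensional search over the variance
  ratio theta = s_b^2 / s_e^2; with one random intercept per subject every
  REML quantity has a closed block form, so no general-purpose mixed-model
  optimizer is needed.  Fixed-effect t tests use Satterthwaite degrees of
  freedom obtained from the observed information of the variance
  components.

* :func:`fit_glmm` — binomial-logit mixed model, maximizing the exact
  marginal likelihood with each subject's random-effect integral
  approximated by adaptive Gauss-Hermite quadrature recentered at the
  subject's conditional mode.  Wald z tests; odds ratios are exp(beta).

Both report AIC/BIC and marginal/conditional R^2 computed by the standard
variance-partition definition (with the logistic residual constant pi^2/3
for the binomial model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .errors import DataError, UndefinedValueError

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0
SEPARATION_THRESHOLD = 15.0


@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effect design: condition, cohort and their interaction.

    Treatment contrasts with the reference cell fixed to
    (adolescent, aggressive): the intercept is that cell's mean and each
    remaining coefficient is a difference from it.
    """

    response: str
    grouping: str = "participant_id"
    cohort_col: str = "cohort"
    condition_col: str = "condition"
    reference: tuple[str, str] = ("adolescent", "aggressive")

    @property
    def term_names(self) -> list[str]:
        return [
            "(Intercept)",
            "condition[non_aggressive]",
            "cohort[child]",
            "condition[non_aggressive]:cohort[child]",
        ]


def build_design(table: pd.DataFrame, spec: DesignSpec):
    """Return (X, y, group_index, names) for the modeled rows.

    Rows with a missing response are dropped (e.g. trials whose first-look
    direction could not be determined).
    """
    df = table.dropna(subset=[spec.response])
    y = df[spec.response].to_numpy(float)
    ref_cohort, ref_cond = spec.reference
    cond = (df[spec.condition_col] != ref_cond).to_numpy(float)
    cohort = (df[spec.cohort_col] != ref_cohort).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), cond, cohort, cond * cohort])
    if len(df) >= 4 and np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("design matrix is rank deficient (empty design cell?)")
    groups, _ = pd.factorize(df[spec.grouping], sort=True)
    return X, y, groups, spec.term_names


@dataclass
class FixedEffectEstimate:
    """One row of the fixed-effect table."""

    name: str
    beta: float
    se: float
    stat: float  # t (LMM) or z (GLMM)
    p: float
    df: float = float("nan")  # Satterthwaite df, LMM only
    odds_ratio: float = float("nan")  # GLMM only


@dataclass
class MixedModelFit:
    """Fitted mixed model: coefficient table, variance components, fit indices."""

    kind: str  # 'lmm' or 'glmm'
    names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    coefficients: list[FixedEffectEstimate]
    sigma_b2: float
    sigma_e2: float  # residual variance (LMM) or pi^2/3 (GLMM)
    loglik: float
    aic: float
    bic: float
    k_params: int
    n_obs: int
    n_subjects: int
    converged: bool
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")
    messages: list[str] = field(default_factory=list)
    _stats: dict = field(default_factory=dict, repr=False)

    def coef_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": c.name,
                "beta": c.beta,
                "se": c.se,
                "stat": c.stat,
                "df": c.df,
                "p": c.p,
                "odds_ratio": c.odds_ratio,
            }
            for c in self.coefficients
        ]
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "kind": self.kind,
            "sigma_b2": self.sigma_b2,
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "messages": list(self.messages),
        }


# ---------------------------------------------------------------------------
# Linear mixed model (REML)
# ---------------------------------------------------------------------------


def _lmm_suffstats(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> dict:
    n, p = X.shape
    n_groups = int(groups.max()) + 1 if len(groups) else 0
    sX = np.zeros((n_groups, p))
    np.add.at(sX, groups, X)
    sy = np.zeros(n_groups)
    np.add.at(sy, groups, y)
    ng = np.bincount(groups, minlength=n_groups).astype(float)
    return {
        "n": n,
        "p": p,
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
        "sX": sX,
        "sy": sy,
        "ng": ng,
        "n_groups": n_groups,
    }


def _lmm_theta_pieces(theta: float, st: dict):
    """Blockwise GLS pieces at variance ratio theta (V = I + theta Z Z')."""
    c = theta * st["ng"] / (1.0 + theta * st["ng"])  # = theta/(1+theta n_g) * n_g
    w = c / st["ng"]
    XtVX = st["XtX"] - (st["sX"] * w[:, None]).T @ st["sX"]
    XtVy = st["Xty"] - st["sX"].T @ (w * st["sy"])
    ytVy = st["yty"] - float(np.sum(w * st["sy"] ** 2))
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    logdetV = float(np.sum(np.log1p(theta * st["ng"])))
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise DataError("X'V^-1X not positive definite")
    return beta, rss, logdetV, logdetXtVX, XtVX


def _reml_profiled_deviance(theta: float, st: dict) -> float:
    n, p = st["n"], st["p"]
    _, rss, logdetV, logdetXtVX, _ = _lmm_theta_pieces(theta, st)
    sigma_e2 = rss / (n - p)
    return (n - p) * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + logdetV + logdetXtVX


def _reml_deviance_vc(sigma_b2: float, sigma_e2: float, st: dict) -> float:
    """Unprofiled REML deviance at the variance components (sb2, se2).

    Extends smoothly to slightly negative sb2 (as long as V stays positive
    definite), which permits central finite differences at a boundary
    optimum.
    """
    if sigma_e2 <= 0:
        return np.inf
    theta = sigma_b2 / sigma_e2
    if np.any(1.0 + theta * st["ng"] <= 0):
        return np.inf
    n, p = st["n"], st["p"]
    _, rss, logdetV, logdetXtVX, _ = _lmm_theta_pieces(theta, st)
    return (
        (n - p) * np.log(sigma_e2)
        + logdetV
        + logdetXtVX
        + rss / sigma_e2
        + (n - p) * np.log(2.0 * np.pi)
    )


def fit_lmm(table: pd.DataFrame, spec: DesignSpec) -> MixedModelFit:
    """REML fit of the random-intercept LMM with Satterthwaite t tests."""
    X, y, groups, names = build_design(table, spec)
    return fit_lmm_arrays(X, y, groups, names)


def fit_lmm_arrays(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, names: list[str] | None = None
) -> MixedModelFit:
    """REML fit for an arbitrary fixed-effect design matrix.

    Array-level entry point behind :func:`fit_lmm`; useful for designs other
    than the standard cohort-by-condition layout (e.g. intercept-only
    variance-component models).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    st = _lmm_suffstats(X, y, groups)
    n, p = st["n"], st["p"]
    if st["n_groups"] < 2:
        raise DataError("need at least 2 subjects")
    if n <= p:
        raise DataError("not enough observations for the fixed-effect design")

    # profile theta = sigma_b^2/sigma_e^2 on a log grid, then refine
    obj = lambda psi: _reml_profiled_deviance(np.exp(psi), st)
    res = optimize.minimize_scalar(
        obj, bounds=(-15.0, 10.0), method="bounded", options={"xatol": 1e-10}
    )
    theta = float(np.exp(res.x))
    dev = float(res.fun)
    dev0 = _reml_profiled_deviance(0.0, st)
    converged = bool(res.success)
    if dev0 <= dev:
        theta, dev = 0.0, float(dev0)

    beta, rss, _, _, XtVX = _lmm_theta_pieces(theta, st)
    sigma_e2 = rss / (n - p)
    sigma_b2 = theta * sigma_e2
    vcov = sigma_e2 * np.linalg.inv(XtVX)

    k = p + 2  # fixed effects + two variance components
    loglik = -dev / 2.0
    aic = dev + 2.0 * k
    bic = dev + k * np.log(n)

    fit = MixedModelFit(
        kind="lmm",
        names=names,
        beta=beta,
        vcov=vcov,
        coefficients=[],
        sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2),
        loglik=float(loglik),
        aic=float(aic),
        bic=float(bic),
        k_params=k,
        n_obs=n,
        n_subjects=st["n_groups"],
        converged=converged,
        _stats={"suff": st, "X": X, "y": y, "groups": groups},
    )
    for j, name in enumerate(names):
        c = np.zeros(p)
        c[j] = 1.0
        t, df, pval = satterthwaite_test(fit, c)
        fit.coefficients.append(
            FixedEffectEstimate(
                name=name,
                beta=float(beta[j]),
                se=float(np.sqrt(vcov[j, j])),
                stat=t,
                df=df,
                p=pval,
            )
        )
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, X)
    return fit


def _contrast_variance(sigma_b2: float, sigma_e2: float, c: np.ndarray, st: dict) -> float:
    theta = sigma_b2 / sigma_e2
    _, _, _, _, XtVX = _lmm_theta_pieces(theta, st)
    return sigma_e2 * float(c @ np.linalg.solve(XtVX, c))


def satterthwaite_test(fit: MixedModelFit, contrast) -> tuple[float, float, float]:
    """Satterthwaite-approximated t test of a fixed-effect contrast c'beta.

    df = 2 [Var(c'beta)]^2 / Var[Var(c'beta)], with the variance of the
    variance from the observed information of (sigma_b^2, sigma_e^2) and
    the gradient of Var(c'beta) obtained by central finite differences.
    Falls back to the residual df (n - p) with a warning when the
    information matrix has non-positive curvature, and uses n - p directly
    in the no-clustering limit sigma_b^2 ~ 0.
    """
    if fit.kind != "lmm":
        raise DataError("Satterthwaite tests apply to the LMM only")
    c = np.asarray(contrast, float)
    st = fit._stats["suff"]
    n, p = st["n"], st["p"]
    sb2, se2 = fit.sigma_b2, fit.sigma_e2
    g_val = _contrast_variance(sb2, se2, c, st)
    est = float(c @ fit.beta)
    t = est / np.sqrt(g_val)
    resid_df = float(n - p)

    if sb2 / se2 < 1e-8:
        return float(t), resid_df, float(2.0 * stats.t.sf(abs(t), resid_df))

    phi = np.array([sb2, se2])
    h = 1e-4 * np.maximum(np.abs(phi), 1e-3 * se2)

    def dev(v):
        return _reml_deviance_vc(v[0], v[1], st)

    # observed information of the variance components: I = 0.5 * Hessian of
    # the REML deviance; Var(phi-hat) ~ I^-1 = 2 H^-1
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            f_pp = dev(phi + ei + ej)
            f_pm = dev(phi + ei - ej)
            f_mp = dev(phi - ei + ej)
            f_mm = dev(phi - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * h[i] * h[j])
    try:
        eigvals = np.linalg.eigvalsh(H)
        if eigvals.min() <= 0 or not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError
        A = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("non-positive curvature of the REML criterion; "
                      "falling back to residual df")
        return float(t), resid_df, float(2.0 * stats.t.sf(abs(t), resid_df))

    grad = np.zeros(2)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        grad[i] = (
            _contrast_variance(*(phi + ei), c, st)
            - _contrast_variance(*(phi - ei), c, st)
        ) / (2.0 * h[i])

    denom = float(grad @ A @ grad)
    if denom <= 0:
        warnings.warn("degenerate Satterthwaite denominator; using residual df")
        df = resid_df
    else:
        df = 2.0 * g_val**2 / denom
        df = min(df, resid_df)
    return float(t), float(df), float(2.0 * stats.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# Binomial-logit GLMM (adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------


def _pad_by_group(values: np.ndarray, groups: np.ndarray):
    n_groups = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=n_groups)
    m = int(counts.max())
    order = np.argsort(groups, kind="stable")
    pos = np.concatenate([np.arange(k) for k in counts[counts > 0]])
    out = np.zeros((n_groups, m))
    mask = np.zeros((n_groups, m), dtype=bool)
    out[groups[order], pos] = values[order]
    mask[groups[order], pos] = True
    return out, mask


class _AGQ:
    """Adaptive Gauss-Hermite marginal log-likelihood for one random intercept."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, n_quad: int):
        if n_quad < 1:
            raise ValueError("n_quad must be >= 1")
        self.X = X
        self.y = y
        self.groups = groups
        self.y_pad, self.mask = _pad_by_group(y, groups)
        self.n_groups = self.y_pad.shape[0]
        nodes, weights = hermgauss(n_quad)
        self.nodes = nodes
        self.logw = np.log(weights) + nodes**2
        self.b = np.zeros(self.n_groups)  # warm-started conditional modes

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta_pad, mask = _pad_by_group(self.X @ beta, self.groups)
        mask = self.mask
        s2 = sigma * sigma
        b = self.b.copy()
        # Newton iterations for the conditional modes (vectorized over subjects)
        for _ in range(100):
            mu = expit(eta_pad + b[:, None])
            score = ((self.y_pad - mu) * mask).sum(axis=1) - b / s2
            W = (mu * (1.0 - mu) * mask).sum(axis=1) + 1.0 / s2
            step = score / W
            step = np.clip(step, -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-11:
                break
        self.b = b
        mu = expit(eta_pad + b[:, None])
        h = (mu * (1.0 - mu) * mask).sum(axis=1) + 1.0 / s2
        tau = np.sqrt(2.0 / h)
        bk = b[:, None] + tau[:, None] * self.nodes[None, :]  # (G, K)
        eta_b = eta_pad[:, :, None] + bk[:, None, :]
        ll_obs = (
            (self.y_pad[:, :, None] * eta_b - np.logaddexp(0.0, eta_b))
            * mask[:, :, None]
        ).sum(axis=1)
        log_prior = -(bk**2) / (2.0 * s2) - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        ll_i = np.log(tau) + logsumexp(
            ll_obs + log_prior + self.logw[None, :], axis=1
        )
        return float(ll_i.sum())


def glmm_marginal_loglik(
    beta, sigma: float, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
    n_quad: int = 25,
) -> float:
    """Marginal log-likelihood of the binomial-logit random-intercept model.

    Standalone entry point (used, e.g., to compare the adaptive quadrature
    against brute-force integration on small data sets).
    """
    return _AGQ(X, y, np.asarray(groups), n_quad).loglik(np.asarray(beta, float), sigma)


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = X @ beta + (y - mu) / W
        beta_new = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
        if np.max(np.abs(beta)) > 2 * SEPARATION_THRESHOLD:
            break
    return beta


def fit_glmm(table: pd.DataFrame, spec: DesignSpec, n_quad: int = 25) -> MixedModelFit:
    """ML fit of the binomial-logit random-intercept GLMM via adaptive GHQ."""
    if n_quad < 1:
        raise ValueError("n_quad must be >= 1")
    X, y, groups, names = build_design(table, spec)
    return fit_glmm_arrays(X, y, groups, names, n_quad=n_quad)


def fit_glmm_arrays(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_quad: int = 25,
) -> MixedModelFit:
    """AGQ ML fit for an arbitrary design matrix (see :func:`fit_glmm`)."""
    if n_quad < 1:
        raise ValueError("n_quad must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("GLMM response must be binary 0/1")
    agq = _AGQ(X, y, groups, n_quad)
    p = X.shape[1]
    n = len(y)

    beta0 = _logistic_irls(X, y)
    x0 = np.concatenate([beta0, [0.3]])
    bounds = [(None, None)] * p + [(1e-4, 5.0)]

    def nll(v):
        return -agq.loglik(v[:p], v[p])

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    beta = res.x[:p]
    sigma = float(res.x[p])
    loglik = -float(res.fun)
    converged = bool(res.success)
    messages: list[str] = []
    if np.max(np.abs(beta)) > SEPARATION_THRESHOLD:
        converged = False
        messages.append(
            "possible complete separation: a coefficient exceeded "
            f"|beta| > {SEPARATION_THRESHOLD} on the logit scale"
        )

    # Wald covariance of beta conditional on the estimated sigma
    Hb = np.zeros((p, p))
    hstep = 1e-4 * (1.0 + np.abs(beta))

    def nll_beta(b):
        return -agq.loglik(b, sigma)

    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = hstep[i]
            ej[j] = hstep[j]
            f_pp = nll_beta(beta + ei + ej)
            f_pm = nll_beta(beta + ei - ej)
            f_mp = nll_beta(beta - ei + ej)
            f_mm = nll_beta(beta - ei - ej)
            Hb[i, j] = Hb[j, i] = (f_pp - f_pm - f_mp + f_mm) / (
                4.0 * hstep[i] * hstep[j]
            )
    try:
        vcov = np.linalg.inv(Hb)
    except np.linalg.LinAlgError:
        vcov = np.full((p, p), np.nan)
        converged = False
        messages.append("singular observed information for the fixed effects")

    sigma_b2 = sigma * sigma if sigma > 2e-4 else 0.0
    k = p + 1  # fixed effects + random-intercept SD
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n)

    fit = MixedModelFit(
        kind="glmm",
        names=names,
        beta=beta,
        vcov=vcov,
        coefficients=[],
        sigma_b2=float(sigma_b2),
        sigma_e2=LOGIT_RESIDUAL_VARIANCE,
        loglik=loglik,
        aic=float(aic),
        bic=float(bic),
        k_params=k,
        n_obs=n,
        n_subjects=agq.n_groups,
        converged=converged,
        messages=messages,
        _stats={"X": X, "y": y, "groups": groups, "n_quad": n_quad, "sigma": sigma},
    )
    for j, name in enumerate(names):
        se = float(np.sqrt(vcov[j, j])) if np.isfinite(vcov[j, j]) else float("nan")
        z = beta[j] / se if se > 0 else float("nan")
        fit.coefficients.append(
            FixedEffectEstimate(
                name=name,
                beta=float(beta[j]),
                se=se,
                stat=float(z),
                p=float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
                odds_ratio=float(np.exp(beta[j])),
            )
        )
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, X)
    return fit


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------


def information_criteria(fit: MixedModelFit) -> tuple[float, float]:
    """(AIC, BIC) from the maximized (restricted) log-likelihood."""
    aic = -2.0 * fit.loglik + 2.0 * fit.k_params
    bic = -2.0 * fit.loglik + fit.k_params * np.log(fit.n_obs)
    return float(aic), float(bic)


def nakagawa_r2(fit: MixedModelFit, X: np.ndarray | None = None) -> tuple[float, float]:
    """Variance-partition (marginal, conditional) R^2.

    marginal = s_f^2 / (s_f^2 + s_b^2 + s_res^2) with s_f^2 the variance of
    the fixed-effect linear predictor over the sample; conditional adds
    s_b^2 to the numerator.  s_res^2 is the residual variance for the LMM
    and pi^2/3 for the binomial-logit GLMM.
    """
    if X is None:
        X = fit._stats.get("X")
        if X is None:
            raise UndefinedValueError("design matrix required for R^2")
    eta = X @ fit.beta
    sigma_f2 = float(np.var(eta))
    denom = sigma_f2 + fit.sigma_b2 + fit.sigma_e2
    if denom <= 0:
        raise UndefinedValueError("zero total variance")
    return sigma_f2 / denom, (sigma_f2 + fit.sigma_b2) / denom
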