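"""Binomial logit mixed model for sentinel-prey removal counts.

Each transect contributes a count of larvae removed out of five stations.
The model is

    y_t | u_b ~ Binomial(n_t, logit^-1(x_t' beta + u_{b(t)}))
    u_b ~ Normal(0, sigma_b^2)   independently per spatial block,

with categorical fixed effects (treatment group, site, and optionally
their interaction) and one random intercept per spatial block (site x
vineyard half in the original design).  The marginal likelihood integrates
the block random effects out by adaptive Gauss-Hermite quadrature: per
block the integrand is recentred at its mode and rescaled by the curvature
there, so a modest number of nodes (default 15) is accurate; order 1
reproduces the Laplace approximation.  Estimation is by maximum likelihood
(not REML-like), since the interest is in likelihood-ratio tests between
fixed-effect specifications; sigma_b is optimised on the log scale with an
explicit profile check against the sigma_b = 0 boundary fit.

Inference helpers: likelihood-ratio tests between nested fits, and all
pairwise treatment contrasts with Wald z statistics and single-step
(max-|Z| multivariate-normal), Bonferroni, or no multiplicity adjustment.
"""

from __future__ import annotations

import dataclasses
import functools
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_types import SENTINEL_GROUPS, SentinelTransect

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "LrtResult",
    "ContrastResult",
    "SeparationError",
    "fit_binomial_glmm",
    "likelihood_ratio_test",
    "pairwise_contrasts",
    "transects_to_frame",
]

VALID_TERMS = ("treatment", "site", "treatment:site")


class SeparationError(ValueError):
    """Complete separation: a treatment group with all-0 or all-n outcomes."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms, random-intercept grouping and reference levels."""

    fixed: tuple[str, ...] = ("treatment", "site", "treatment:site")
    random: str = "block"
    treatment_reference: str = "control"

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(VALID_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}; "
                             f"valid terms are {VALID_TERMS}")
        if "treatment:site" in self.fixed and not {"treatment", "site"} <= set(self.fixed):
            raise ValueError("interaction requires both main effects")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (set(self.fixed) <= set(other.fixed)
                and self.random == other.random)


@dataclasses.dataclass(frozen=True)
class GlmmFit:
    """A fitted binomial logit mixed model."""

    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma_b: float
    loglik: float
    cov_beta: np.ndarray
    converged: bool
    spec: ModelSpec
    treatment_levels: tuple[str, ...]
    site_levels: tuple[str, ...]
    n_obs: int
    method: str
    order: int

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # sigma_b counted even when estimated at 0

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        z = self.beta / se
        return pd.DataFrame(
            {
                "term": self.beta_names,
                "estimate": self.beta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


@dataclasses.dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


@dataclasses.dataclass(frozen=True)
class ContrastResult:
    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_adjusted: float
    adjust: str


def transects_to_frame(transects: Sequence[SentinelTransect]) -> pd.DataFrame:
    """Tidy frame (site, block, group, removed, n) from transect records."""
    return pd.DataFrame(
        [
            {"site": t.site, "block": t.block, "group": t.group,
             "removed": t.removed, "n": t.n_stations}
            for t in transects
        ]
    )


# ---------------------------------------------------------------------------
# design matrix

def _build_design(frame: pd.DataFrame, spec: ModelSpec):
    trt_levels = [l for l in SENTINEL_GROUPS if l in set(frame["group"])]
    if spec.treatment_reference in trt_levels:
        trt_levels.remove(spec.treatment_reference)
        trt_levels.insert(0, spec.treatment_reference)
    site_levels = sorted(set(frame["site"].astype(str)))

    cols: list[np.ndarray] = [np.ones(len(frame))]
    names: list[str] = ["(Intercept)"]
    trt_dummies = {
        l: (frame["group"] == l).to_numpy(float) for l in trt_levels[1:]
    }
    site_dummies = {
        s: (frame["site"].astype(str) == s).to_numpy(float) for s in site_levels[1:]
    }
    if "treatment" in spec.fixed:
        for l, d in trt_dummies.items():
            cols.append(d)
            names.append(f"treatment[{l}]")
    if "site" in spec.fixed:
        for s, d in site_dummies.items():
            cols.append(d)
            names.append(f"site[{s}]")
    if "treatment:site" in spec.fixed:
        for l, dt in trt_dummies.items():
            for s, ds in site_dummies.items():
                cols.append(dt * ds)
                names.append(f"treatment[{l}]:site[{s}]")
    X = np.column_stack(cols)
    # drop structurally empty columns (e.g. a treatment level absent at a site)
    keep = X.any(axis=0)
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    return X, tuple(names), tuple(trt_levels), tuple(site_levels)


def _check_separation(frame: pd.DataFrame) -> None:
    for g, sub in frame.groupby("group"):
        if (sub["removed"] == 0).all():
            raise SeparationError(
                f"complete separation: group {g!r} has no removals; "
                "the logit MLE is unbounded")
        if (sub["removed"] == sub["n"]).all():
            raise SeparationError(
                f"complete separation: group {g!r} has every larva removed; "
                "the logit MLE is unbounded")


# ---------------------------------------------------------------------------
# marginal log-likelihood

@functools.lru_cache(maxsize=None)
def _gh_nodes(order: int):
    t, w = np.polynomial.hermite.hermgauss(order)
    return t, np.log(w) + t**2  # log(w_k * exp(t_k^2))


def _binom_const(y: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                        - special.gammaln(n - y + 1)))


def _binom_loglik_terms(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    # y*eta - n*log(1+e^eta), numerically stable via log1p(exp(-|eta|))
    return y * eta - n * (np.logaddexp(0.0, eta))


def marginal_loglik(beta: np.ndarray, sigma_b: float, X: np.ndarray,
                    y: np.ndarray, n: np.ndarray, block_idx: np.ndarray,
                    n_blocks: int, order: int = 15) -> float:
    """Marginal log-likelihood, random intercepts integrated out by
    adaptive Gauss-Hermite quadrature (order 1 = Laplace).

    At ``sigma_b = 0`` this is exactly the independent-binomial
    log-likelihood.  The binomial normalizing constant is included, so the
    value is comparable with external fitters.
    """
    eta0 = X @ beta
    const = _binom_const(y, n)
    if sigma_b == 0.0:
        return float(np.sum(_binom_loglik_terms(eta0, y, n))) + const

    inv_var = 1.0 / sigma_b**2

    def joint(u_b: np.ndarray) -> np.ndarray:
        # log p(y_b | u_b) + log phi(u_b; 0, sigma^2), vectorised over blocks
        eta = eta0 + u_b[block_idx]
        terms = _binom_loglik_terms(eta, y, n)
        per_block = np.bincount(block_idx, weights=terms, minlength=n_blocks)
        return per_block - 0.5 * u_b**2 * inv_var - np.log(sigma_b) - 0.5 * np.log(2 * np.pi)

    # block-wise Newton for the conditional mode
    u = np.zeros(n_blocks)
    for _ in range(50):
        eta = eta0 + u[block_idx]
        p = special.expit(eta)
        grad = (np.bincount(block_idx, weights=y - n * p, minlength=n_blocks)
                - u * inv_var)
        hess = -(np.bincount(block_idx, weights=n * p * (1 - p), minlength=n_blocks)
                 + inv_var)
        step = -grad / hess
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[block_idx]
    p = special.expit(eta)
    h = np.bincount(block_idx, weights=n * p * (1 - p), minlength=n_blocks) + inv_var
    scale = 1.0 / np.sqrt(h)

    t, logwt = _gh_nodes(order)
    # nodes: u_k = u_hat + sqrt(2)*scale*t_k; integral = sqrt(2)*scale * sum w_k e^{t^2} f(u_k)
    g_hat = joint(u)
    acc = np.zeros(n_blocks)
    for t_k, lw in zip(t, logwt):
        g_k = joint(u + np.sqrt(2.0) * scale * t_k)
        acc += np.exp(lw + g_k - g_hat)
    ll_blocks = g_hat + 0.5 * np.log(2.0) + np.log(scale) + np.log(acc)
    return float(np.sum(ll_blocks)) + const


def _glm_fit(X: np.ndarray, y: np.ndarray, n: np.ndarray):
    """Plain binomial-logit ML fit (Fisher scoring); used for starts and
    the sigma_b = 0 boundary fit."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        p = special.expit(eta)
        W = n * p * (1 - p)
        grad = X.T @ (y - n * p)
        info = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = X @ beta
    p = special.expit(eta)
    info = X.T @ (X * (n * p * (1 - p))[:, None])
    ll = float(np.sum(_binom_loglik_terms(eta, y, n))) + _binom_const(y, n)
    return beta, ll, info


def fit_binomial_glmm(data: Sequence[SentinelTransect] | pd.DataFrame,
                      spec: ModelSpec = ModelSpec(),
                      method: str = "agq", order: int = 15,
                      fix_sigma_b: float | None = None) -> GlmmFit:
    """Fit the binomial logit mixed model by maximum marginal likelihood.

    ``method`` is ``"agq"`` (adaptive Gauss-Hermite at ``order`` nodes) or
    ``"laplace"`` (order-1 comparability mode).  ``fix_sigma_b`` pins the
    random-intercept standard deviation (0 gives the plain GLM).  Raises
    :class:`SeparationError` when a treatment group is all-0 or all-n; a
    fit that fails the optimizer's convergence test is returned with
    ``converged=False``, never silently.
    """
    frame = data if isinstance(data, pd.DataFrame) else transects_to_frame(data)
    if len(frame) < 2:
        raise ValueError("need at least 2 transects")
    if method == "laplace":
        order = 1
    elif method != "agq":
        raise ValueError(f"unknown method {method!r}")
    _check_separation(frame)

    X, names, trt_levels, site_levels = _build_design(frame, spec)
    y = frame["removed"].to_numpy(float)
    n = frame["n"].to_numpy(float)
    blocks = pd.Categorical(frame[spec.random].astype(str))
    block_idx = np.asarray(blocks.codes)
    n_blocks = len(blocks.categories)

    beta0, ll0, info0 = _glm_fit(X, y, n)

    if fix_sigma_b == 0.0:
        cov = np.linalg.inv(info0)
        return GlmmFit(beta=beta0, beta_names=names, sigma_b=0.0, loglik=ll0,
                       cov_beta=cov, converged=True, spec=spec,
                       treatment_levels=trt_levels, site_levels=site_levels,
                       n_obs=len(frame), method=method, order=order)

    if fix_sigma_b is not None:
        def nll_fixed(b):
            return -marginal_loglik(b, fix_sigma_b, X, y, n, block_idx, n_blocks, order)
        res = optimize.minimize(nll_fixed, beta0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        H = _num_hessian(nll_fixed, res.x)
        cov = np.linalg.inv(H)
        return GlmmFit(beta=res.x, beta_names=names, sigma_b=float(fix_sigma_b),
                       loglik=-float(res.fun), cov_beta=cov, converged=bool(res.success),
                       spec=spec, treatment_levels=trt_levels, site_levels=site_levels,
                       n_obs=len(frame), method=method, order=order)

    k = X.shape[1]

    def nll(theta: np.ndarray) -> float:
        return -marginal_loglik(theta[:k], float(np.exp(theta[k])), X, y, n,
                                block_idx, n_blocks, order)

    theta0 = np.append(beta0, np.log(0.3))
    # derivative-free sweep to leave any flat start region, then quasi-Newton polish
    pre = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
    res = optimize.minimize(nll, pre.x, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    theta = res.x if res.fun <= pre.fun else pre.x
    ll = -float(min(res.fun, pre.fun))
    converged = bool(res.success or pre.success)

    # profile check against the sigma_b = 0 boundary
    if ll <= ll0 + 1e-8 or np.exp(theta[k]) < 1e-4:
        cov = np.linalg.inv(info0)
        return GlmmFit(beta=beta0, beta_names=names, sigma_b=0.0, loglik=ll0,
                       cov_beta=cov, converged=True, spec=spec,
                       treatment_levels=trt_levels, site_levels=site_levels,
                       n_obs=len(frame), method=method, order=order)

    H = _num_hessian(nll, theta)
    try:
        cov_full = np.linalg.inv(H)
        cov = cov_full[:k, :k]
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return GlmmFit(beta=theta[:k], beta_names=names, sigma_b=float(np.exp(theta[k])),
                   loglik=ll, cov_beta=cov, converged=converged, spec=spec,
                   treatment_levels=trt_levels, site_levels=site_levels,
                   n_obs=len(frame), method=method, order=order)


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (observed information when f = -loglik)."""
    k = len(x)
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                val = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                       + f(x - ei - ej)) / (4 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    return H


def likelihood_ratio_test(full: GlmmFit, null: GlmmFit) -> LrtResult:
    """Deviance comparison of nested fits against the chi-square law."""
    if not null.spec.is_nested_in(full.spec):
        raise ValueError(
            f"null fixed effects {null.spec.fixed} not nested in {full.spec.fixed}")
    if not (full.converged and null.converged):
        raise ValueError("both fits must have converged")
    df = len(full.beta) - len(null.beta)
    chi2 = max(0.0, null.deviance - full.deviance)
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else 1.0
    return LrtResult(chi2=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# pairwise treatment contrasts

def _level_row(fit: GlmmFit, level: str) -> np.ndarray:
    """Design row for one treatment level averaged over site levels
    (equal weights), on the fitted coefficient basis."""
    row = np.zeros(len(fit.beta))
    n_sites = len(fit.site_levels)
    for i, name in enumerate(fit.beta_names):
        if name == "(Intercept)":
            row[i] = 1.0
        elif name == f"treatment[{level}]":
            row[i] = 1.0
        elif name.startswith("site["):
            row[i] = 1.0 / n_sites
        elif name.startswith(f"treatment[{level}]:site["):
            row[i] = 1.0 / n_sites
    return row


def pairwise_contrasts(fit: GlmmFit, adjust: str = "single_step",
                       n_mc: int = 200_000, seed: int = 0) -> list[ContrastResult]:
    """All pairwise treatment differences on the logit scale.

    ``single_step`` adjusts each P to P(max_k |Z_k| >= |z|) under the joint
    normal law of the contrasts implied by the fitted covariance (seeded
    Monte-Carlo integration); ``bonferroni`` and ``none`` are also
    available.  Adjusted P never falls below the unadjusted two-sided
    normal P.
    """
    if "treatment" not in fit.spec.fixed:
        raise ValueError("fit has no treatment fixed effect")
    if adjust not in ("single_step", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    levels = list(fit.treatment_levels)
    pairs = [(levels[j], levels[i])
             for i in range(len(levels)) for j in range(i + 1, len(levels))]
    C = np.array([_level_row(fit, a) - _level_row(fit, b) for a, b in pairs])
    V = C @ fit.cov_beta @ C.T
    se = np.sqrt(np.diag(V))
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("singular contrast covariance")
    est = C @ fit.beta
    z = est / se
    p_raw = 2 * stats.norm.sf(np.abs(z))
    k = len(pairs)
    if adjust == "none" or k == 1:
        p_adj = p_raw
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, k * p_raw)
    else:
        R = V / np.outer(se, se)
        # jittered Cholesky guards exact colinearity of contrasts
        try:
            L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        except np.linalg.LinAlgError:
            raise ValueError("singular contrast correlation matrix") from None
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n_mc, k)) @ L.T
        maxabs = np.abs(Z).max(axis=1)
        p_adj = np.array([np.mean(maxabs >= abs(zk)) for zk in z])
        p_adj = np.maximum(p_adj, p_raw)
    return [
        ContrastResult(pair=pairs[i], estimate=float(est[i]), se=float(se[i]),
                       z=float(z[i]), p_adjusted=float(p_adj[i]), adjust=adjust)
        for i in range(k)
    ]


def contrasts_to_frame(contrasts: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pair": f"{c.pair[0]} - {c.pair[1]}", "estimate": c.estimate,
             "se": c.se, "z": c.z, "p_adjusted": c.p_adjusted, "adjust": c.adjust}
            for c in contrasts
        ]
    )
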