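"""Random-intercept proportional-odds regression for ordinal quality scores.

The model: rating ``y_ij`` of image ``i`` by row ``j`` takes category ``c``
(of ``q`` ordered categories) with

    P(y_ij <= c | u_i) = F(tau_c - x_ij' beta - u_i),   u_i ~ N(0, sigma_u^2)

where ``F`` is the standard logistic CDF and ``tau_1 < ... < tau_{q-1}`` are
cutpoints.  Covariates shift every cumulative log-odds equally (proportional
odds), so ``exp(beta)`` is the odds ratio of a *better* score for that term
versus its reference level.  The image-level random intercept absorbs the
clustering of the many ratings of the same image.

Estimation is maximum likelihood with the random effect integrated out by
adaptive Gauss-Hermite quadrature: each group's integrand is re-centred at
its conditional mode and rescaled by its curvature before applying the
quadrature rule, which keeps a modest number of nodes accurate even for the
large, sharply-peaked per-image likelihoods that arise here (dozens of
ratings per image).  Cutpoints are optimized as (tau_1, log-gaps) and
sigma_u on the log scale so the ordering and positivity constraints are
built into the parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .ratings import STRATIFY_FACTORS, RatingDataset

DEFAULT_REFERENCES = {
    "method": "manual",
    "contour_type": "lv_epi",
    "slice_level": "mid",
    "pathology": "healthy",
}

_LN2 = math.log(2.0)


class FitError(Exception):
    """Design or optimization failure with a stage-addressed message."""


# ----------------------------------------------------------------- spec/fit
@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the fixed/random structure to fit."""

    fixed_effects: tuple[str, ...] = ("method", "rater")
    interactions: tuple[tuple[str, str], ...] = ()
    reference_levels: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCES)
    )
    random_intercept: str | None = "image_id"
    n_quadrature: int = 15
    max_iter: int = 200
    tol: float = 1e-5  # outer re-centering stopping rule, sup-norm on raw params

    def without_interactions(self) -> "ModelSpec":
        return replace(self, interactions=())


@dataclass
class ModelFit:
    """Maximum-likelihood proportional-odds fit."""

    thresholds: np.ndarray
    beta: pd.Series
    sigma_u: float
    loglik: float
    vcov: pd.DataFrame  # natural scale: tau's, beta's, sigma_u
    converged: bool
    n_obs: int
    n_groups: int
    spec: ModelSpec

    def se(self, term: str) -> float:
        return float(np.sqrt(self.vcov.loc[term, term]))

    @property
    def n_params(self) -> int:
        return len(self.thresholds) + len(self.beta) + (1 if self.sigma_u > 0 or self.spec.random_intercept else 0)


# ------------------------------------------------------------ design matrix
def build_design(
    ds: RatingDataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray, int]:
    """Outcome codes, dummy design matrix, term names, group codes, q."""
    df = ds.df
    cats = list(ds.categories)
    y = pd.Categorical(df["score"], categories=cats, ordered=True).codes.astype(np.int64)
    if (y < 0).any():
        raise FitError("scores outside the declared categories")
    if len(np.unique(y)) < 2:
        raise FitError("need at least two observed score categories")

    def factor_dummies(factor: str) -> tuple[list[str], list[np.ndarray]]:
        col = STRATIFY_FACTORS.get(factor, factor)
        if col not in df.columns:
            raise FitError(f"unknown factor {factor!r}")
        levels = sorted(df[col].unique())
        ref = spec.reference_levels.get(factor)
        if ref is None or ref not in levels:
            ref = levels[0]
        names, cols = [], []
        for lev in levels:
            if lev == ref:
                continue
            names.append(f"{factor}[{lev}]")
            cols.append((df[col] == lev).to_numpy(dtype=float))
        return names, cols

    names: list[str] = []
    columns: list[np.ndarray] = []
    per_factor: dict[str, tuple[list[str], list[np.ndarray]]] = {}
    for f in spec.fixed_effects:
        nm, cl = factor_dummies(f)
        per_factor[f] = (nm, cl)
        names.extend(nm)
        columns.extend(cl)
    for f1, f2 in spec.interactions:
        for f in (f1, f2):
            if f not in per_factor:
                per_factor[f] = factor_dummies(f)
        for n1, c1 in zip(*per_factor[f1]):
            for n2, c2 in zip(*per_factor[f2]):
                names.append(f"{n1}:{n2}")
                columns.append(c1 * c2)

    X = np.column_stack(columns) if columns else np.empty((len(df), 0))
    if X.shape[1]:
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            raise FitError("design matrix is rank deficient (collinear factors)")
    if spec.random_intercept is not None:
        groups = pd.Categorical(df[spec.random_intercept]).codes.astype(np.int64)
    else:
        groups = np.zeros(len(df), dtype=np.int64)
    return y, X, names, groups, len(cats)


# ------------------------------------------------------------ core numerics
def _log_logistic_cdf(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x < 0, stable near both ends."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x > -_LN2
    with np.errstate(divide="ignore"):
        out[small] = np.log(-np.expm1(x[small]))
        out[~small] = np.log1p(-np.exp(x[~small]))
    return out


class _OrdinalCore:
    """Vectorized likelihood machinery shared by the fixed and mixed fits."""

    def __init__(self, y, X, groups, q, n_quad=15, random=True):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.g = groups[order]
        self.q = q
        self.random = random
        self.n = len(y)
        self.G = int(self.g.max()) + 1 if self.n else 0
        self.starts = np.searchsorted(self.g, np.arange(self.G))
        self.has_up = self.y < q - 1
        self.has_lo = self.y > 0
        nodes, wts = special.roots_hermite(n_quad)
        self.nodes = nodes
        self.logw = np.log(wts) + nodes**2

    # -- per-observation pieces -------------------------------------------
    def _bounds(self, tau, eta):
        """(a, b) cutpoint distances; dummy values where the bound is open."""
        up = np.where(self.has_up, tau[np.minimum(self.y, self.q - 2)], 0.0)
        lo = np.where(self.has_lo, tau[np.maximum(self.y - 1, 0)], 0.0)
        if eta.ndim == 2:
            up, lo = up[:, None], lo[:, None]
        return up - eta, lo - eta

    def _gaps(self, tau):
        """tau_{y-1} - tau_y for interior categories (eta-free, exact)."""
        gap = np.zeros(self.n)
        both = self.has_up & self.has_lo
        gap[both] = tau[self.y[both] - 1] - tau[self.y[both]]
        return gap

    def _logp(self, tau, eta):
        logp, _ = self._obs_pieces(tau, eta, want_derivs=0)
        return logp

    def _derivative_pieces(self, tau, eta, want_curvature=True):
        logp, derivs = self._obs_pieces(
            tau, eta, want_derivs=2 if want_curvature else 1
        )
        return (logp, *derivs)

    def _obs_pieces(self, tau, eta, want_derivs):
        """Per-observation log-probability and (optionally) score ratios.

        Uses log F(-x) = log F(x) - x and p = exp(log F) throughout, so every
        quantity stays finite for arbitrarily extreme linear predictors; the
        interior-category mass is evaluated as
        log p = log F(a) + log F(b) - b + log(1 - exp(tau_{y-1} - tau_y)),
        whose last term is eta-free and therefore exactly cancellation-safe.
        """
        a, b = self._bounds(tau, eta)
        la = -np.logaddexp(0.0, -a)  # log F(a)
        lb = -np.logaddexp(0.0, -b)
        hu = self.has_up[..., None] if eta.ndim == 2 else self.has_up
        hl = self.has_lo[..., None] if eta.ndim == 2 else self.has_lo
        both = hu & hl
        gap = self._gaps(tau)
        if eta.ndim == 2:
            gap = gap[:, None]
        logp = np.where(hu, la, lb - b)  # lb - b = log(1 - F(b))
        mid = la + lb - b + _log1mexp(np.minimum(gap, -1e-300))
        logp = np.where(both, mid, logp)
        if not want_derivs:
            return logp, None
        # ga = f(a)/p, gb = f(b)/p with f the logistic density
        ga = np.where(hu, np.exp(2.0 * la - a - logp), 0.0)
        gb = np.where(hl, np.exp(2.0 * lb - b - logp), 0.0)
        g1 = ga - gb  # -(d logp / d eta)
        if want_derivs < 2:
            return logp, (ga, gb, g1, None)
        pa = np.exp(la)
        pb = np.exp(lb)
        g2 = ga * (1.0 - 2.0 * pa) - gb * (1.0 - 2.0 * pb)
        return logp, (ga, gb, g1, g2)

    def _group_sum(self, arr):
        return np.add.reduceat(arr, self.starts, axis=0)

    # -- adaptive centering ------------------------------------------------
    def center(self, tau, beta, sigma, z0=None, max_newton=50):
        """Conditional mode and curvature scale of each group's integrand."""
        xb = self.X @ beta
        z = np.zeros(self.G) if z0 is None else z0.copy()
        curv = np.ones(self.G)
        for _ in range(max_newton):
            eta = xb + sigma * z[self.g]
            _, _, _, g1, g2 = self._derivative_pieces(tau, eta)
            s1 = self._group_sum(g1)
            s2 = self._group_sum(g2 - g1 * g1)  # d2 logp / deta2 per obs
            grad = -sigma * s1 - z
            curv = 1.0 - sigma**2 * s2  # -f'' >= 1 by log-concavity
            step = grad / curv
            step = np.clip(step, -4.0, 4.0)
            z += step
            if np.max(np.abs(grad)) < 1e-11:
                break
        return z, 1.0 / np.sqrt(curv)

    def _node_grid(self, mode, scale):
        """Quadrature abscissae per group, (G, J)."""
        return mode[:, None] + math.sqrt(2.0) * scale[:, None] * self.nodes[None, :]

    # -- likelihood --------------------------------------------------------
    def loglik_fixed_nodes(self, tau, beta, sigma, t, log_scale_const, want_grad=False):
        """Marginal log-likelihood on a frozen node grid ``t`` (G, J).

        ``log_scale_const`` is log(sqrt(2) * s_g) per group.  With the grid
        frozen, the value and its analytic gradient are exactly consistent,
        which is what the inner optimizer needs.
        """
        xb = self.X @ beta
        t_obs = t[self.g]  # (n, J)
        eta = xb[:, None] + sigma * t_obs
        if not want_grad:
            logp = self._logp(tau, eta)
            lg = self._group_sum(logp)
            terms = self.logw[None, :] + lg - 0.5 * t * t - 0.5 * math.log(2 * math.pi)
            value = float(np.sum(log_scale_const + special.logsumexp(terms, axis=1)))
            return value, None
        logp, ga, gb, g1, _ = self._derivative_pieces(tau, eta, want_curvature=False)
        lg = self._group_sum(logp)
        terms = self.logw[None, :] + lg - 0.5 * t * t - 0.5 * math.log(2 * math.pi)
        lse = special.logsumexp(terms, axis=1)
        value = float(np.sum(log_scale_const + lse))
        post = np.exp(terms - lse[:, None])  # (G, J) posterior node weights
        w_obs = post[self.g]  # (n, J)
        s_eta = -(w_obs * g1).sum(axis=1)  # d loglik / d eta_i
        grad_beta = self.X.T @ s_eta
        grad_sigma = float(-(w_obs * g1 * t_obs).sum())
        a_i = (w_obs * ga).sum(axis=1)
        b_i = (w_obs * gb).sum(axis=1)
        grad_tau = np.bincount(
            self.y[self.has_up], a_i[self.has_up], minlength=self.q - 1
        ) - np.bincount(
            self.y[self.has_lo] - 1, b_i[self.has_lo], minlength=self.q - 1
        )
        return value, (grad_tau, grad_beta, grad_sigma)

    def _refine_centering(self, tau, beta, sigma, mode, scale):
        """One moment-matching pass: recentre each group's rule on the
        posterior mean/sd seen through the current grid.  Tightens the
        mode/curvature rule by about an order of magnitude for small groups
        with skewed integrands (large sigma)."""
        t = self._node_grid(mode, scale)
        eta = (self.X @ beta)[:, None] + sigma * t[self.g]
        lg = self._group_sum(self._logp(tau, eta))
        terms = self.logw[None, :] + lg - 0.5 * t * t
        post = np.exp(terms - special.logsumexp(terms, axis=1)[:, None])
        mean = (post * t).sum(axis=1)
        sd = np.sqrt(np.maximum((post * t * t).sum(axis=1) - mean**2, 1e-12))
        return mean, sd

    def loglik_adaptive(self, tau, beta, sigma, want_grad=False, z0=None):
        """Marginal log-likelihood with freshly recomputed adaptive centering."""
        if not self.random:
            return self._loglik_plain(tau, beta, want_grad)
        mode, scale = self.center(tau, beta, sigma, z0=z0)
        mode, scale = self._refine_centering(tau, beta, sigma, mode, scale)
        t = self._node_grid(mode, scale)
        const = 0.5 * math.log(2.0) + np.log(scale)
        return self.loglik_fixed_nodes(tau, beta, sigma, t, const, want_grad)

    def _loglik_plain(self, tau, beta, want_grad=False):
        eta = self.X @ beta
        if not want_grad:
            return float(self._logp(tau, eta).sum()), None
        logp, ga, gb, g1, _ = self._derivative_pieces(tau, eta, want_curvature=False)
        grad_beta = self.X.T @ (-g1)
        grad_tau = np.bincount(
            self.y[self.has_up], ga[self.has_up], minlength=self.q - 1
        ) - np.bincount(self.y[self.has_lo] - 1, gb[self.has_lo], minlength=self.q - 1)
        return float(logp.sum()), (grad_tau, grad_beta, 0.0)


# ------------------------------------------------------- parameter plumbing
def _raw_to_natural(raw, q, p, random):
    tau = np.empty(q - 1)
    tau[0] = raw[0]
    if q > 2:
        tau[1:] = raw[0] + np.cumsum(np.exp(raw[1 : q - 1]))
    beta = raw[q - 1 : q - 1 + p]
    sigma = float(np.exp(raw[-1])) if random else 0.0
    return tau, beta, sigma


def _natural_to_raw(tau, beta, sigma, random):
    gaps = np.diff(tau)
    raw = [tau[0], *np.log(np.maximum(gaps, 1e-8))] + list(beta)
    if random:
        raw.append(math.log(max(sigma, 1e-6)))
    return np.array(raw, dtype=float)


def _chain_gradient(raw, grad_tau, grad_beta, grad_sigma, q, random):
    out = np.empty(len(raw))
    out[0] = grad_tau.sum()
    for j in range(1, q - 1):
        out[j] = math.exp(raw[j]) * grad_tau[j:].sum()
    out[q - 1 : q - 1 + len(grad_beta)] = grad_beta
    if random:
        out[-1] = math.exp(raw[-1]) * grad_sigma
    return out


# ------------------------------------------------------------------ fitting
def loglik(
    spec: ModelSpec,
    params: Mapping,
    data: RatingDataset,
) -> float:
    """Marginal log-likelihood at given parameter values.

    ``params`` must contain ``thresholds`` (ascending, length q-1), ``beta``
    (aligned with the design columns of ``spec`` on ``data``) and
    ``sigma_u`` (>= 0, ignored when the spec has no random intercept).
    """
    y, X, names, groups, q = build_design(data, spec)
    tau = np.asarray(params["thresholds"], dtype=float)
    if tau.shape != (q - 1,) or (np.diff(tau) <= 0).any():
        raise ValueError("thresholds must be ascending with length q-1")
    beta = np.asarray(params.get("beta", np.zeros(len(names))), dtype=float)
    if beta.shape != (len(names),):
        raise ValueError(f"beta must have length {len(names)} ({names})")
    sigma = float(params.get("sigma_u", 0.0))
    if sigma < 0:
        raise ValueError("sigma_u must be >= 0")
    random = spec.random_intercept is not None and sigma > 0
    core = _OrdinalCore(y, X, groups, q, spec.n_quadrature, random=random)
    value, _ = core.loglik_adaptive(tau, beta, sigma)
    return value


def fit(
    spec: ModelSpec,
    data: RatingDataset,
    start: Mapping | None = None,
    compute_vcov: bool = True,
) -> ModelFit:
    """Fit the model by maximum likelihood.

    Runs an outer loop that alternates (i) recomputing the adaptive
    quadrature grid at the current parameters and (ii) an exact inner
    L-BFGS-B maximization on the frozen grid, until the parameters stop
    moving.  The covariance matrix is the inverse observed information,
    obtained by finite differences of the analytic score; pass
    ``compute_vcov=False`` to skip it when only point estimates are needed
    (e.g. in large simulation sweeps).
    """
    y, X, names, groups, q = build_design(data, spec)
    random = spec.random_intercept is not None
    n_groups = int(groups.max()) + 1
    if random and n_groups < 2:
        raise FitError("random intercept needs at least 2 groups")
    core = _OrdinalCore(y, X, groups, q, spec.n_quadrature, random=random)
    p = X.shape[1]

    if start is not None:
        raw = _natural_to_raw(
            np.asarray(start["thresholds"], float),
            np.asarray(start.get("beta", np.zeros(p)), float),
            float(start.get("sigma_u", 0.5)),
            random,
        )
    else:
        cum = np.clip(
            np.cumsum(np.bincount(y, minlength=q)[: q - 1]) / len(y), 1e-3, 1 - 1e-3
        )
        cum = np.maximum.accumulate(cum + 1e-6 * np.arange(q - 1))
        tau0 = np.log(cum / (1 - cum))
        beta0 = np.zeros(p)
        if random:
            # cheap plain ordered-logit warm start for the expensive fit
            def plain_objective(r):
                tau_r, beta_r, _ = _raw_to_natural(r, q, p, False)
                value, grads = core._loglik_plain(tau_r, beta_r, want_grad=True)
                return -value, -_chain_gradient(r, *grads, q, False)

            plain = optimize.minimize(
                plain_objective,
                _natural_to_raw(tau0, beta0, 0.5, False),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 100},
            )
            tau0, beta0, _ = _raw_to_natural(plain.x, q, p, False)
        raw = _natural_to_raw(tau0, beta0, 0.5, random)

    z_warm = np.zeros(core.G)
    success = True
    for outer in range(12):
        tau, beta, sigma = _raw_to_natural(raw, q, p, random)
        if random:
            mode, scale = core.center(tau, beta, sigma, z0=z_warm)
            mode, scale = core._refine_centering(tau, beta, sigma, mode, scale)
            z_warm = mode
            t = core._node_grid(mode, scale)
            const = 0.5 * math.log(2.0) + np.log(scale)

        def objective(r):
            tau_r, beta_r, sigma_r = _raw_to_natural(r, q, p, random)
            if random:
                value, grads = core.loglik_fixed_nodes(
                    tau_r, beta_r, sigma_r, t, const, want_grad=True
                )
            else:
                value, grads = core._loglik_plain(tau_r, beta_r, want_grad=True)
            g = _chain_gradient(r, *grads, q, random)
            return -value, -g

        res = optimize.minimize(
            objective,
            raw,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": spec.max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        moved = np.max(np.abs(res.x - raw))
        raw = res.x
        success = bool(res.success) or res.status == 0
        if moved < max(spec.tol, 1e-9):
            break
    converged = success and (not random or moved < 1e-4)

    tau, beta, sigma = _raw_to_natural(raw, q, p, random)
    value, _ = core.loglik_adaptive(tau, beta, sigma, z0=z_warm)

    # observed information by central differences of the analytic score
    k = len(raw)
    if compute_vcov:
        def score(r):
            tau_r, beta_r, sigma_r = _raw_to_natural(r, q, p, random)
            _, grads = core.loglik_adaptive(
                tau_r, beta_r, sigma_r, want_grad=True, z0=z_warm
            )
            return _chain_gradient(r, *grads, q, random)

        hess = np.zeros((k, k))
        for j in range(k):
            h = 1e-5 * max(1.0, abs(raw[j]))
            e = np.zeros(k)
            e[j] = h
            hess[:, j] = (score(raw + e) - score(raw - e)) / (2 * h)
        hess = 0.5 * (hess + hess.T)
        try:
            cov_raw = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov_raw = np.full((k, k), np.nan)
            converged = False
    else:
        cov_raw = np.full((k, k), np.nan)

    # delta method to the natural scale (tau's, beta's, sigma_u)
    jac = np.zeros((k, k))
    jac[0, 0] = 1.0
    for c in range(1, q - 1):
        jac[c, 0] = 1.0
        for j in range(1, c + 1):
            jac[c, j] = math.exp(raw[j])
    jac[q - 1 : q - 1 + p, q - 1 : q - 1 + p] = np.eye(p)
    if random:
        jac[-1, -1] = sigma
    cov_nat = jac @ cov_raw @ jac.T

    labels = [f"cut{j + 1}" for j in range(q - 1)] + names + (
        ["sigma_u"] if random else []
    )
    if not random:
        cov_nat = cov_nat[: q - 1 + p, : q - 1 + p]
    vcov = pd.DataFrame(cov_nat, index=labels, columns=labels)
    return ModelFit(
        thresholds=tau,
        beta=pd.Series(beta, index=names, dtype=float),
        sigma_u=sigma,
        loglik=value,
        vcov=vcov,
        converged=converged,
        n_obs=core.n,
        n_groups=n_groups if random else 1,
        spec=spec,
    )


def odds_ratios(fit_result: ModelFit, terms: Sequence[str] | None = None) -> pd.DataFrame:
    """Odds ratios with Wald 95% CIs and p-values for fixed-effect terms."""
    if terms is None:
        terms = list(fit_result.beta.index)
    rows = []
    for term in terms:
        if term not in fit_result.beta.index:
            raise KeyError(f"unknown term {term!r}")
        b = float(fit_result.beta[term])
        se = fit_result.se(term)
        z = b / se if se > 0 else np.inf * np.sign(b) if b else 0.0
        pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        if not np.isfinite(se) or se == 0:
            ci = (math.exp(b), math.exp(b))
            pval = np.nan if not np.isfinite(se) else (1.0 if b == 0 else 0.0)
        else:
            ci = (math.exp(b - 1.959963984540054 * se), math.exp(b + 1.959963984540054 * se))
        rows.append((term, b, se, math.exp(b), ci[0], ci[1], pval))
    return pd.DataFrame(
        rows, columns=["term", "beta", "se", "or", "ci_low", "ci_high", "pvalue"]
    ).set_index("term")


@dataclass
class LikelihoodRatioTest:
    statistic: float
    df: int
    pvalue: float
    fit_full: ModelFit
    fit_reduced: ModelFit


def interaction_test(
    spec: ModelSpec, data: RatingDataset, pair: tuple[str, str]
) -> LikelihoodRatioTest:
    """Likelihood-ratio test of one interaction block.

    Fits the spec with and without ``pair`` in its interaction list; the
    test statistic is twice the log-likelihood difference on as many degrees
    of freedom as dummy products the block adds.
    """
    for f in pair:
        if f not in spec.fixed_effects:
            raise FitError(f"interaction factor {f!r} must be a fixed effect")
    pair_t = tuple(pair)
    reduced_spec = replace(
        spec, interactions=tuple(x for x in spec.interactions if tuple(x) != pair_t)
    )
    full_spec = replace(spec, interactions=reduced_spec.interactions + (pair_t,))
    fit_reduced = fit(reduced_spec, data)
    fit_full = fit(full_spec, data)
    df = len(fit_full.beta) - len(fit_reduced.beta)
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    pval = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LikelihoodRatioTest(stat, df, pval, fit_full, fit_reduced)
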