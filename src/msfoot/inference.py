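"""Fitting the two-component footprint mixture by EM with SQUAREM acceleration.

Because the site-level latent rates and split probabilities marginalize in
closed form (negative binomial for totals, beta-binomial for splits), the
only latent variable left is the per-site binding indicator Z, and the
marginal likelihood can be maximized by exact EM:

* E-step: posterior P(Z=1 | counts) from the two component likelihoods and
  the logistic prior.
* M-step: block-wise numerical maximization of the posterior-weighted
  log-likelihood — one (alpha, lambda0_bar) block per replicate and
  component, and one (p_bar_j, tau_j) block per scale, shared across
  replicates.  Each block is solved in an unconstrained parameterization
  (logs, logits; tau_j = unimodality floor + exp(s_j)) with analytic
  gradients, and reverted if the optimizer fails to improve it, so the
  marginal likelihood never decreases.
* Prior update: ridge-stabilized weighted logistic regression with
  fractional responses.

One full cycle is a fixed-point map on the packed unconstrained parameter
vector; SQUAREM extrapolation (steplength -|r|/|v| with backtracking toward
the plain EM step) accelerates convergence without breaking monotonicity.

M-step objectives are evaluated on unique (parent, left) count pairs per
node with posterior-summed weights — identical values, far fewer
special-function evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit

from .likelihoods import (
    BoundParams,
    UnboundParams,
    loglik_bound,
    loglik_total_only,
    loglik_unbound,
)
from .multiscale import PyramidStack

__all__ = [
    "PriorModel",
    "EMConfig",
    "FitResult",
    "PosteriorResult",
    "SquaremResult",
    "e_step",
    "m_step",
    "update_prior",
    "em_iterate",
    "squarem",
    "squarem_accelerate",
    "fit_mixture",
    "fit_flexbg",
    "posterior_odds",
]

_LOG_BOUNDS = (np.log(1e-4), np.log(1e8))
_WEIGHT_EPS = 1e-10


def _design(features: Optional[np.ndarray], n: int) -> np.ndarray:
    """Intercept column plus optional site features."""
    if features is None:
        return np.ones((n, 1))
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != n:
        features = features.T
    if features.shape[0] != n:
        raise ValueError("features must have one row per site")
    return np.column_stack([np.ones(n), features])


@dataclass
class PriorModel:
    """Logistic prior on binding: zeta_n = sigmoid(beta . [1, f_n])."""

    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))

    def zeta(self, features: Optional[np.ndarray] = None, n: Optional[int] = None):
        if n is None:
            if features is None:
                raise ValueError("need features or the number of sites")
            n = np.atleast_2d(features).shape[0]
        X = _design(features, n)
        if X.shape[1] != len(self.beta):
            raise ValueError("feature dimension does not match prior weights")
        return expit(X @ self.beta)


@dataclass
class EMConfig:
    """Knobs of the fitting procedure (defaults recorded for reproducibility)."""

    tol: float = 1e-6
    max_iter: int = 200
    inner_maxiter: int = 25
    ridge: float = 1e-6
    tau_init: float = 100.0
    alpha_init: float = 1.0
    total_only: bool = False
    accelerate: bool = True
    anchor_bound: bool = True
    verbose: bool = False


@dataclass
class FitResult:
    bound: BoundParams
    unbound: UnboundParams
    prior: PriorModel
    loglik_trajectory: np.ndarray
    converged: bool
    n_iterations: int
    total_only: bool = False


@dataclass
class PosteriorResult:
    """Per-site binding evidence: log_posterior_odds = logit(posterior_prob)."""

    loglik_bound: np.ndarray
    loglik_unbound: np.ndarray
    posterior_prob: np.ndarray
    log_posterior_odds: np.ndarray


def e_step(ll_bound, ll_unbound, zeta):
    """Posterior bound probability per site, via log-sum-exp.

    Sites where both component log-likelihoods are -inf fall back to the
    prior with a warning.
    """
    ll_bound = np.asarray(ll_bound, dtype=float)
    ll_unbound = np.asarray(ll_unbound, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lzb = np.log(zeta) + ll_bound
        lzu = np.log1p(-zeta) + ll_unbound
        denom = np.logaddexp(lzb, lzu)
        q = np.exp(lzb - denom)
    bad = ~np.isfinite(denom)
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} site(s) with -inf likelihood under both components; "
            "posterior set to the prior"
        )
        q = np.where(bad, zeta, q)
    return q


# ---------------------------------------------------------------------------
# M-step blocks


def _fit_negbin_block(totals, weights, alpha0, lambda0, maxiter=50):
    """Weighted MLE of one replicate's (alpha, lambda0_bar); reverts on failure."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() < _WEIGHT_EPS:
        return alpha0, lambda0
    vals, inv = np.unique(np.asarray(totals), return_inverse=True)
    w = np.bincount(inv, weights=weights)
    vals = vals.astype(float)

    def nll(u):
        a, lam = np.exp(u)
        denom = a + lam
        ll = (
            gammaln(vals + a)
            - gammaln(a)
            + a * (np.log(a) - np.log(denom))
            + vals * (np.log(lam) - np.log(denom))
        )
        f = -float(w @ ll)
        da = digamma(vals + a) - digamma(a) + np.log(a) + 1.0 - np.log(denom) - (a + vals) / denom
        dl = vals / lam - (a + vals) / denom
        return f, -np.array([float(w @ da) * a, float(w @ dl) * lam])

    u0 = np.log([alpha0, lambda0])
    f0, _ = nll(u0)
    res = minimize(
        nll, u0, jac=True, method="L-BFGS-B", bounds=[_LOG_BOUNDS, _LOG_BOUNDS],
        options={"maxiter": maxiter},
    )
    if np.isfinite(res.fun) and res.fun <= f0:
        a, lam = np.exp(res.x)
        return float(a), float(lam)
    return alpha0, lambda0


def _tau_floor(p):
    """Smallest tau keeping every Beta(p*tau, (1-p)*tau) unimodal."""
    return float(max(np.max(1.0 / p), np.max(1.0 / (1.0 - p))))


def _fit_beta_block(groups, weights_flat, p0, tau0, maxiter=25):
    """Weighted MLE of one scale's (p_bar, tau) under the unimodality floor.

    ``groups`` holds, per node, the unique (parent, left) pairs and the
    inverse index of the flattened (site, replicate) observations; weights
    are posterior probabilities repeated across replicates.
    """
    K = len(p0)
    if np.sum(weights_flat) < _WEIGHT_EPS:
        return np.asarray(p0, dtype=float), float(tau0)
    wlist = [
        np.bincount(inv, weights=weights_flat, minlength=len(n_u))
        for (n_u, _l, inv) in groups
    ]
    p0c = np.clip(np.asarray(p0, dtype=float), 1e-3, 1.0 - 1e-3)
    m0 = _tau_floor(p0c)
    theta0 = np.concatenate([logit(p0c), [np.log(max(tau0 - m0, 1e-6))]])

    def unpack(theta):
        p = expit(theta[:K])
        per = np.maximum(1.0 / p, 1.0 / (1.0 - p))
        kstar = int(np.argmax(per))
        tau = per[kstar] + np.exp(theta[K])
        return p, tau, kstar

    def nll(theta):
        p, tau, kstar = unpack(theta)
        f = 0.0
        gp = np.zeros(K)
        T = 0.0
        dg_tau = digamma(tau)
        lg_tau = gammaln(tau)
        for k in range(K):
            n_u, l_u, _ = groups[k]
            w = wlist[k]
            a = p[k] * tau
            b = (1.0 - p[k]) * tau
            ll = (
                gammaln(l_u + a)
                + gammaln(n_u - l_u + b)
                - gammaln(n_u + tau)
                - gammaln(a)
                - gammaln(b)
                + lg_tau
            )
            f -= float(w @ ll)
            ga = float(w @ (digamma(l_u + a) - digamma(n_u + tau) - digamma(a) + dg_tau))
            gb = float(
                w @ (digamma(n_u - l_u + b) - digamma(n_u + tau) - digamma(b) + dg_tau)
            )
            gp[k] = tau * (ga - gb)
            T += p[k] * ga + (1.0 - p[k]) * gb
        pk = p[kstar]
        dmdp = -1.0 / pk**2 if 1.0 / pk >= 1.0 / (1.0 - pk) else 1.0 / (1.0 - pk) ** 2
        gp[kstar] += T * dmdp
        grad = np.concatenate([-(gp * p * (1.0 - p)), [-T * np.exp(theta[K])]])
        return f, grad

    f0, _ = nll(theta0)
    res = minimize(
        nll, theta0, jac=True, method="L-BFGS-B",
        bounds=[(-7.0, 7.0)] * K + [(np.log(1e-4), np.log(1e7))],
        options={"maxiter": maxiter},
    )
    if np.isfinite(res.fun) and res.fun <= f0:
        p, tau, _ = unpack(res.x)
        return p, float(tau)
    return np.asarray(p0, dtype=float), float(tau0)


def m_step(stack: PyramidStack, posteriors, bound: BoundParams,
           unbound: UnboundParams, config: Optional[EMConfig] = None):
    """Posterior-weighted block maximization of both components.

    Returns updated (BoundParams, UnboundParams).  Blocks with negligible
    total weight are left untouched; flexible-background split parameters
    are never modified here (they are fit once from naked-DNA data).
    """
    config = config or EMConfig()
    q = np.asarray(posteriors, dtype=float)
    S = stack.S
    maxiter = config.inner_maxiter

    alpha = bound.alpha.copy()
    lam = bound.lambda0_bar.copy()
    p_bar = [pj.copy() for pj in bound.p_bar]
    tau = bound.tau.copy()
    if q.sum() >= _WEIGHT_EPS:
        for s in range(S):
            alpha[s], lam[s] = _fit_negbin_block(
                stack.totals[:, s], q, alpha[s], lam[s], maxiter
            )
        if not config.total_only:
            w_flat = np.repeat(q, S)  # matches row-major (N, S) flattening
            groups = stack.node_groups()
            for j in range(stack.J):
                p_bar[j], tau[j] = _fit_beta_block(
                    groups[j], w_flat, p_bar[j], tau[j], maxiter
                )
    bound_new = BoundParams(p_bar=p_bar, tau=tau, alpha=alpha, lambda0_bar=lam)

    alpha_o = unbound.alpha_o.copy()
    lam_o = unbound.lambda0_bar_o.copy()
    if (1.0 - q).sum() >= _WEIGHT_EPS:
        for s in range(S):
            alpha_o[s], lam_o[s] = _fit_negbin_block(
                stack.totals[:, s], 1.0 - q, alpha_o[s], lam_o[s], maxiter
            )
    unbound_new = UnboundParams(
        alpha_o=alpha_o,
        lambda0_bar_o=lam_o,
        flexbg=unbound.flexbg,
        p_bar_o=unbound.p_bar_o,
        tau_o=unbound.tau_o,
    )
    return bound_new, unbound_new


def update_prior(posteriors, features=None, ridge: float = 1e-6,
                 tol: float = 1e-10, max_iter: int = 100) -> PriorModel:
    """Ridge-stabilized weighted logistic regression with fractional responses.

    Maximizes sum_n [q_n log zeta_n + (1-q_n) log(1-zeta_n)] minus a small
    L2 penalty that keeps the solution finite under perfect separation.
    """
    q = np.asarray(posteriors, dtype=float)
    X = _design(features, len(q))
    beta = np.zeros(X.shape[1])

    def objective(b):
        z = X @ b
        return float(q @ (-np.logaddexp(0, -z)) + (1 - q) @ (-np.logaddexp(0, z))) \
            - 0.5 * ridge * float(b @ b)

    f_cur = objective(beta)
    for _ in range(max_iter):
        zeta = expit(X @ beta)
        grad = X.T @ (q - zeta) - ridge * beta
        W = np.clip(zeta * (1 - zeta), 1e-12, None)
        H = X.T @ (X * W[:, None]) + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(30):  # halve until the penalized objective improves
            cand = beta + scale * step
            f_new = objective(cand)
            if f_new >= f_cur - 1e-14:
                break
            scale *= 0.5
        else:
            break
        if abs(f_new - f_cur) < tol * (abs(f_cur) + 1.0) and np.linalg.norm(scale * step) < 1e-8:
            beta = cand
            break
        beta, f_cur = cand, f_new
    return PriorModel(beta=beta)


# ---------------------------------------------------------------------------
# EM driver


def _site_logliks(stack, bound, unbound, total_only):
    if total_only:
        return loglik_total_only(stack, bound), loglik_total_only(stack, unbound)
    return loglik_bound(stack, bound), loglik_unbound(stack, unbound)


def _marginal_loglik(llb, llu, zeta):
    with np.errstate(divide="ignore"):
        return float(np.logaddexp(np.log(zeta) + llb, np.log1p(-zeta) + llu).sum())


def _check_finite(llb, llu):
    bad = ~(np.isfinite(llb) | np.isfinite(llu))
    if np.any(bad):
        idx = np.flatnonzero(bad)[:20]
        raise RuntimeError(
            f"non-finite likelihood under both components at sites {idx.tolist()}"
        )


def _em_cycle(stack, features, bound, unbound, prior, config):
    zeta = prior.zeta(features, stack.N)
    llb, llu = _site_logliks(stack, bound, unbound, config.total_only)
    _check_finite(llb, llu)
    q = e_step(llb, llu, zeta)
    bound, unbound = m_step(stack, q, bound, unbound, config)
    prior = update_prior(q, features, ridge=config.ridge)
    return bound, unbound, prior


def default_init(stack: PyramidStack, features=None, config: Optional[EMConfig] = None):
    """Moment-style starting values.

    lambda0_bar starts at the top/bottom-quartile mean total per replicate
    (bound/unbound), alpha at 1, p_bar at pooled empirical split fractions
    clipped to [0.01, 0.99], tau at ``tau_init``, and the prior at zeta=0.5.
    """
    config = config or EMConfig()
    S = stack.S
    lam_b = np.empty(S)
    lam_u = np.empty(S)
    for s in range(S):
        t = stack.totals[:, s].astype(float)
        hi, lo = np.quantile(t, 0.75), np.quantile(t, 0.25)
        lam_b[s] = max(t[t >= hi].mean(), 0.1)
        lam_u[s] = max(t[t <= lo].mean(), 0.05)
        if lam_b[s] <= lam_u[s]:
            lam_b[s] = lam_u[s] * 1.5 + 0.1
    p_bar = []
    for j in range(stack.J):
        num = stack.lefts[j].sum(axis=(0, 1)).astype(float)
        den = stack.parents[j].sum(axis=(0, 1)).astype(float)
        pj = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        p_bar.append(np.clip(pj, 0.01, 0.99))
    tau = np.full(stack.J, config.tau_init)
    bound = BoundParams(p_bar=p_bar, tau=tau,
                        alpha=np.full(S, config.alpha_init), lambda0_bar=lam_b)
    unbound = UnboundParams(alpha_o=np.full(S, config.alpha_init), lambda0_bar_o=lam_u)
    n_beta = _design(features, stack.N).shape[1]
    prior = PriorModel(beta=np.zeros(n_beta))
    return bound, unbound, prior


def em_iterate(stack, features, init, config: Optional[EMConfig] = None) -> FitResult:
    """Plain EM: alternate E-step, block M-step and prior update to convergence."""
    config = config or EMConfig()
    bound, unbound, prior = init
    traj = []
    converged = False
    n_done = 0
    for _ in range(config.max_iter):
        zeta = prior.zeta(features, stack.N)
        llb, llu = _site_logliks(stack, bound, unbound, config.total_only)
        _check_finite(llb, llu)
        L = _marginal_loglik(llb, llu, zeta)
        traj.append(L)
        if len(traj) >= 2 and abs(traj[-1] - traj[-2]) < config.tol * (abs(traj[-2]) + 1e-12):
            converged = True
            break
        q = e_step(llb, llu, zeta)
        bound, unbound = m_step(stack, q, bound, unbound, config)
        prior = update_prior(q, features, ridge=config.ridge)
        n_done += 1
    return FitResult(
        bound=bound, unbound=unbound, prior=prior,
        loglik_trajectory=np.asarray(traj), converged=converged,
        n_iterations=n_done, total_only=config.total_only,
    )


# ---------------------------------------------------------------------------
# SQUAREM


@dataclass
class SquaremResult:
    x: np.ndarray
    converged: bool
    n_iterations: int
    n_map_evaluations: int
    obj_trajectory: np.ndarray


def squarem(F: Callable, x0, objective: Optional[Callable] = None,
            tol: float = 1e-7, max_iter: int = 100) -> SquaremResult:
    """SQUAREM acceleration of a fixed-point map.

    Each outer iteration takes two map steps, extrapolates with steplength
    ``-|r|/|v|`` (``r = x1-x0``, ``v = x2-2*x1+x0``) and, when an objective
    is supplied, backtracks toward steplength -1 — the plain map step — so
    the objective never decreases.  A stabilizing map application follows
    each accepted extrapolation.
    """
    x = np.asarray(x0, dtype=float)
    traj = []
    n_map = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x1 = F(x)
        x2 = F(x1)
        n_map += 2
        r = x1 - x
        v = (x2 - x1) - r
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            x_new = x2
        else:
            a = -np.linalg.norm(r) / nv
            if a > -1.0:
                a = -1.0
            f2 = objective(x2) if objective is not None else None
            while True:
                xp = x - 2.0 * a * r + a * a * v
                if objective is None:
                    break
                fp = objective(xp)
                if np.isfinite(fp) and fp >= f2 - 1e-10:
                    break
                if a >= -1.0 - 1e-12:
                    xp = x2
                    break
                a = (a - 1.0) / 2.0
            x_new = F(xp)
            n_map += 1
        if objective is not None:
            traj.append(objective(x_new))
            if len(traj) >= 2 and abs(traj[-1] - traj[-2]) < tol * (abs(traj[-2]) + 1e-12):
                x = x_new
                converged = True
                break
        else:
            if np.linalg.norm(x_new - x2) < tol * (np.linalg.norm(x2) + 1e-12):
                x = x_new
                converged = True
                break
        x = x_new
    return SquaremResult(
        x=x, converged=converged, n_iterations=it,
        n_map_evaluations=n_map, obj_trajectory=np.asarray(traj),
    )


# ---------------------------------------------------------------------------
# packed unconstrained parameter vector (for SQUAREM over EM cycles)


def _pack(bound, unbound, prior, total_only):
    parts = [np.log(bound.alpha), np.log(bound.lambda0_bar)]
    if not total_only:
        for j in range(bound.J):
            pc = np.clip(bound.p_bar[j], 1e-6, 1.0 - 1e-6)
            parts.append(logit(pc))
            parts.append([np.log(max(bound.tau[j] - _tau_floor(pc), 1e-8))])
    parts.append(np.log(unbound.alpha_o))
    parts.append(np.log(unbound.lambda0_bar_o))
    parts.append(prior.beta)
    return np.concatenate([np.atleast_1d(p) for p in parts])


def _unpack(theta, template: FitResult | tuple, total_only):
    # SQUAREM extrapolation can propose arbitrary vectors, so saturate the
    # transforms instead of letting expit/exp produce exact 0/1 or inf
    if isinstance(template, tuple):
        bound_t, unbound_t, prior_t = template
    else:
        bound_t, unbound_t, prior_t = template.bound, template.unbound, template.prior
    theta = np.clip(np.asarray(theta, dtype=float), -600.0, 600.0)
    S = bound_t.S
    i = 0
    alpha = np.exp(theta[i:i + S]); i += S
    lam = np.exp(theta[i:i + S]); i += S
    p_bar = []
    tau = np.empty(bound_t.J)
    if not total_only:
        for j in range(bound_t.J):
            K = 2**j
            pj = np.clip(expit(theta[i:i + K]), 1e-9, 1.0 - 1e-9); i += K
            tau[j] = _tau_floor(pj) + np.exp(theta[i]); i += 1
            p_bar.append(pj)
    else:
        p_bar = [pj.copy() for pj in bound_t.p_bar]
        tau = bound_t.tau.copy()
    alpha_o = np.exp(theta[i:i + S]); i += S
    lam_o = np.exp(theta[i:i + S]); i += S
    beta = theta[i:]
    bound = BoundParams(p_bar=p_bar, tau=tau, alpha=alpha, lambda0_bar=lam)
    unbound = UnboundParams(
        alpha_o=alpha_o, lambda0_bar_o=lam_o, flexbg=unbound_t.flexbg,
        p_bar_o=unbound_t.p_bar_o, tau_o=unbound_t.tau_o,
    )
    return bound, unbound, PriorModel(beta=beta)


def squarem_accelerate(stack, features, init, config: Optional[EMConfig] = None) -> FitResult:
    """Run SQUAREM over the EM cycle map; monotone via backtracking."""
    config = config or EMConfig()
    theta0 = _pack(*init, config.total_only)

    def F(theta):
        b, u, pr = _unpack(theta, init, config.total_only)
        b, u, pr = _em_cycle(stack, features, b, u, pr, config)
        return _pack(b, u, pr, config.total_only)

    def obj(theta):
        b, u, pr = _unpack(theta, init, config.total_only)
        zeta = pr.zeta(features, stack.N)
        llb, llu = _site_logliks(stack, b, u, config.total_only)
        return _marginal_loglik(llb, llu, zeta)

    res = squarem(F, theta0, objective=obj, tol=config.tol, max_iter=config.max_iter)
    bound, unbound, prior = _unpack(res.x, init, config.total_only)
    return FitResult(
        bound=bound, unbound=unbound, prior=prior,
        loglik_trajectory=res.obj_trajectory, converged=res.converged,
        n_iterations=res.n_iterations, total_only=config.total_only,
    )


def _anchor(fit: FitResult) -> FitResult:
    """Label the hypersensitive (larger mean total) component as bound."""
    if fit.bound.lambda0_bar.mean() >= fit.unbound.lambda0_bar_o.mean():
        return fit
    warnings.warn("components swapped so that 'bound' has the larger mean total")
    bound = BoundParams(
        p_bar=fit.bound.p_bar, tau=fit.bound.tau,
        alpha=fit.unbound.alpha_o, lambda0_bar=fit.unbound.lambda0_bar_o,
    )
    unbound = UnboundParams(
        alpha_o=fit.bound.alpha, lambda0_bar_o=fit.bound.lambda0_bar,
        flexbg=fit.unbound.flexbg, p_bar_o=fit.unbound.p_bar_o, tau_o=fit.unbound.tau_o,
    )
    return replace(fit, bound=bound, unbound=unbound,
                   prior=PriorModel(beta=-fit.prior.beta))


def fit_mixture(stack: PyramidStack, features=None,
                config: Optional[EMConfig] = None, init=None) -> FitResult:
    """Fit all hyperparameters of the mixture; the package's main entry point."""
    config = config or EMConfig()
    if init is None:
        init = default_init(stack, features, config)
    if config.accelerate:
        fit = squarem_accelerate(stack, features, init, config)
    else:
        fit = em_iterate(stack, features, init, config)
    if config.anchor_bound:
        fit = _anchor(fit)
    return fit


def fit_flexbg(naked_stack: PyramidStack, stack: PyramidStack, features=None,
               config: Optional[EMConfig] = None, init=None) -> FitResult:
    """Two-stage fit with the flexible naked-DNA background.

    Stage 1 fits the background cleavage profile (p_bar_o, tau_o) to the
    naked-DNA counts with every site treated as background (no mixture).
    Stage 2 runs the mixture EM on the chromatin data with those parameters
    frozen.
    """
    if naked_stack is None:
        raise ValueError(
            "flexible background requires naked-DNA counts at the same sites; "
            "use the uniform background otherwise"
        )
    config = config or EMConfig()
    if naked_stack.J != stack.J:
        raise ValueError("naked-DNA window must match the chromatin window")
    p_bar_o = []
    for j in range(naked_stack.J):
        num = naked_stack.lefts[j].sum(axis=(0, 1)).astype(float)
        den = naked_stack.parents[j].sum(axis=(0, 1)).astype(float)
        pj = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        p_bar_o.append(np.clip(pj, 0.01, 0.99))
    tau_o = np.full(naked_stack.J, config.tau_init)
    ones = np.ones(naked_stack.N * naked_stack.S)
    groups = naked_stack.node_groups()
    for j in range(naked_stack.J):
        p_bar_o[j], tau_o[j] = _fit_beta_block(
            groups[j], ones, p_bar_o[j], tau_o[j], maxiter=200
        )
    if init is None:
        bound0, unbound0, prior0 = default_init(stack, features, config)
    else:
        bound0, unbound0, prior0 = init
    unbound0 = UnboundParams(
        alpha_o=unbound0.alpha_o, lambda0_bar_o=unbound0.lambda0_bar_o,
        flexbg=True, p_bar_o=p_bar_o, tau_o=tau_o,
    )
    return fit_mixture(stack, features, config, init=(bound0, unbound0, prior0))


def posterior_odds(stack: PyramidStack, fit: FitResult, features=None) -> PosteriorResult:
    """Per-site posterior binding probability and natural-log posterior odds."""
    zeta = np.clip(fit.prior.zeta(features, stack.N), 1e-12, 1 - 1e-12)
    llb, llu = _site_logliks(stack, fit.bound, fit.unbound, fit.total_only)
    log_odds = logit(zeta) + llb - llu
    prob = expit(log_odds)
    return PosteriorResult(
        loglik_bound=llb, loglik_unbound=llu,
        posterior_prob=prob, log_posterior_odds=log_odds,
    )
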