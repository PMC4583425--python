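"""Closed-form marginal log-likelihoods of the footprint mixture components.

At a bound site the per-base counts follow a Poisson whose multiscale
parameters are themselves random: the total rate is gamma distributed with
shape ``alpha`` and rate ``alpha / lambda0_bar`` (so the marginal total is
negative binomial with mean ``lambda0_bar`` and variance ``lambda0_bar +
lambda0_bar**2 / alpha``), and each dyadic split probability is beta
distributed with mean ``p_bar_jk`` and scale-specific precision ``tau_j``
(so the marginal left-child count is beta-binomial).  At an unbound site
the splits are a point mass at 0.5 — uniformly spread reads — unless the
flexible background learned from naked-DNA data replaces them with their
own beta-binomials.  Everything is computed in log space; zero-count
parents contribute exactly zero.

The precision constraint ``p_bar * tau >= 1`` and ``(1 - p_bar) * tau >= 1``
keeps every beta unimodal and is enforced by projection (with a ``1e-6``
margin) whenever a parameter set is constructed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.special import betaln, gammaln

from .multiscale import CountPyramid, PyramidStack, stack_site

__all__ = [
    "BoundParams",
    "UnboundParams",
    "negbin_logpmf",
    "betabin_logpmf",
    "binom_logpmf",
    "loglik_bound",
    "loglik_unbound",
    "loglik_total_only",
]

_UNIMODAL_MARGIN = 1e-6

Pyramids = Union[PyramidStack, Sequence[CountPyramid]]


def negbin_logpmf(x, alpha, lambda_bar):
    """Log-pmf of the gamma-Poisson (negative binomial) total count.

    Parameterized by the gamma shape ``alpha`` and mean ``lambda_bar``
    (gamma rate ``alpha / lambda_bar``); the marginal has mean
    ``lambda_bar`` and variance ``lambda_bar + lambda_bar**2 / alpha``.
    """
    x = np.asarray(x)
    alpha = np.asarray(alpha, dtype=float)
    lambda_bar = np.asarray(lambda_bar, dtype=float)
    if np.any(alpha <= 0) or np.any(lambda_bar <= 0):
        raise ValueError("alpha and lambda_bar must be positive")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    out = (
        gammaln(x + alpha)
        - gammaln(alpha)
        - gammaln(x + 1)
        + alpha * (np.log(alpha) - np.log(alpha + lambda_bar))
        + x * (np.log(lambda_bar) - np.log(alpha + lambda_bar))
    )
    return out if out.ndim else float(out)


def betabin_logpmf(k, n, a, b):
    """Log-pmf of the beta-binomial: Binomial(k | n, q) with q ~ Beta(a, b).

    Computed via log-beta functions; ``n == 0`` returns exactly 0.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta parameters must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    out = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )
    return out if out.ndim else float(out)


def binom_logpmf(k, n, p):
    """Plain binomial log-pmf (log-space; used for the uniform background)."""
    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    out = out + np.where(k > 0, k * logp, 0.0) + np.where(n - k > 0, (n - k) * log1mp, 0.0)
    return out if out.ndim else float(out)


def _project_unimodal(p_bar, tau):
    """Project tau up so every Beta(p*tau, (1-p)*tau) stays unimodal."""
    tau = np.array(tau, dtype=float, copy=True)
    out_p = []
    for j, pj in enumerate(p_bar):
        pj = np.asarray(pj, dtype=float)
        if np.any(pj <= 0) or np.any(pj >= 1):
            raise ValueError("split means must lie strictly inside (0, 1)")
        out_p.append(pj)
        floor = max(np.max(1.0 / pj), np.max(1.0 / (1.0 - pj)))
        if tau[j] < floor + _UNIMODAL_MARGIN:
            tau[j] = floor + _UNIMODAL_MARGIN
    return out_p, tau


@dataclass
class BoundParams:
    """Hyperparameters of the bound-site hierarchy.

    ``p_bar`` (ragged, one array per scale) and ``tau`` (length J) are
    shared across replicates; ``alpha`` and ``lambda0_bar`` (length S) are
    replicate specific to absorb library-depth differences.
    """

    p_bar: list
    tau: np.ndarray
    alpha: np.ndarray
    lambda0_bar: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.lambda0_bar = np.atleast_1d(np.asarray(self.lambda0_bar, dtype=float))
        if np.any(self.alpha <= 0) or np.any(self.lambda0_bar <= 0):
            raise ValueError("alpha and lambda0_bar must be positive")
        if len(self.alpha) != len(self.lambda0_bar):
            raise ValueError("alpha and lambda0_bar must have one entry per replicate")
        self.p_bar, self.tau = _project_unimodal(self.p_bar, self.tau)
        for j, pj in enumerate(self.p_bar):
            if len(pj) != 2**j:
                raise ValueError("p_bar must hold 2**(j-1) values at scale j")

    @property
    def J(self) -> int:
        return len(self.p_bar)

    @property
    def S(self) -> int:
        return len(self.alpha)

    def to_dict(self) -> dict:
        return {
            "p_bar": [pj.tolist() for pj in self.p_bar],
            "tau": self.tau.tolist(),
            "alpha": self.alpha.tolist(),
            "lambda0_bar": self.lambda0_bar.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoundParams":
        return cls(
            p_bar=[np.asarray(pj, dtype=float) for pj in d["p_bar"]],
            tau=np.asarray(d["tau"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            lambda0_bar=np.asarray(d["lambda0_bar"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "BoundParams":
        return cls.from_dict(json.loads(s))


@dataclass
class UnboundParams:
    """Hyperparameters of the background component.

    With ``flexbg`` off, all split probabilities are the constant 0.5
    (reads uniform over the window).  With ``flexbg`` on, ``p_bar_o`` and
    ``tau_o`` describe the naked-DNA cleavage profile and its heterogeneity
    and obey the same unimodality constraint.
    """

    alpha_o: np.ndarray
    lambda0_bar_o: np.ndarray
    flexbg: bool = False
    p_bar_o: list = None
    tau_o: np.ndarray = None

    def __post_init__(self):
        self.alpha_o = np.atleast_1d(np.asarray(self.alpha_o, dtype=float))
        self.lambda0_bar_o = np.atleast_1d(np.asarray(self.lambda0_bar_o, dtype=float))
        if np.any(self.alpha_o <= 0) or np.any(self.lambda0_bar_o <= 0):
            raise ValueError("alpha_o and lambda0_bar_o must be positive")
        if len(self.alpha_o) != len(self.lambda0_bar_o):
            raise ValueError("alpha_o and lambda0_bar_o must have one entry per replicate")
        if self.flexbg:
            if self.p_bar_o is None or self.tau_o is None:
                raise ValueError("flexbg requires p_bar_o and tau_o")
            self.p_bar_o, self.tau_o = _project_unimodal(self.p_bar_o, self.tau_o)

    @property
    def S(self) -> int:
        return len(self.alpha_o)

    def to_dict(self) -> dict:
        return {
            "alpha_o": self.alpha_o.tolist(),
            "lambda0_bar_o": self.lambda0_bar_o.tolist(),
            "flexbg": bool(self.flexbg),
            "p_bar_o": None if self.p_bar_o is None else [pj.tolist() for pj in self.p_bar_o],
            "tau_o": None if self.tau_o is None else np.asarray(self.tau_o).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnboundParams":
        return cls(
            alpha_o=np.asarray(d["alpha_o"], dtype=float),
            lambda0_bar_o=np.asarray(d["lambda0_bar_o"], dtype=float),
            flexbg=bool(d.get("flexbg", False)),
            p_bar_o=None
            if d.get("p_bar_o") is None
            else [np.asarray(pj, dtype=float) for pj in d["p_bar_o"]],
            tau_o=None if d.get("tau_o") is None else np.asarray(d["tau_o"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "UnboundParams":
        return cls.from_dict(json.loads(s))


def _as_stack(pyramids: Pyramids) -> PyramidStack:
    if isinstance(pyramids, PyramidStack):
        return pyramids
    return stack_site(list(pyramids))


def _betabin_scale_terms(stack: PyramidStack, p_bar, tau) -> np.ndarray:
    """Per-site sum of beta-binomial node terms, excluding log C(n, k)."""
    out = np.zeros(stack.N)
    for j in range(stack.J):
        a = p_bar[j] * tau[j]  # (K,)
        b = (1.0 - p_bar[j]) * tau[j]
        n = stack.parents[j]
        k = stack.lefts[j]
        terms = (
            gammaln(k + a)
            + gammaln(n - k + b)
            - gammaln(n + tau[j])
            - gammaln(a)
            - gammaln(b)
            + gammaln(tau[j])
        )
        out += terms.sum(axis=(1, 2))
    return out


def _negbin_site_terms(stack: PyramidStack, alpha, lambda_bar) -> np.ndarray:
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    lambda_bar = np.atleast_1d(np.asarray(lambda_bar, dtype=float))
    if len(alpha) != stack.S:
        raise ValueError(
            f"params describe {len(alpha)} replicates but data has {stack.S}"
        )
    return negbin_logpmf(stack.totals, alpha[None, :], lambda_bar[None, :]).sum(axis=1)


def _check_depth(stack: PyramidStack, J: int):
    if J != stack.J:
        raise ValueError(f"params describe {J} scales but data pyramid has {stack.J}")


def loglik_bound(pyramids: Pyramids, params: BoundParams):
    """Marginal log-likelihood of each site under the bound component.

    Sums, over replicates, the negative-binomial total term plus one
    beta-binomial term per dyadic split.  Returns an (N,) array for a
    :class:`PyramidStack`, or a float for one site's list of per-replicate
    pyramids.
    """
    stack = _as_stack(pyramids)
    _check_depth(stack, params.J)
    ll = _negbin_site_terms(stack, params.alpha, params.lambda0_bar)
    ll = ll + _betabin_scale_terms(stack, params.p_bar, params.tau) + stack.logbc_persite()
    return ll if isinstance(pyramids, PyramidStack) else float(ll[0])


def loglik_unbound(pyramids: Pyramids, params: UnboundParams):
    """Marginal log-likelihood of each site under the background component.

    Uniform mode: splits are Binomial(left | parent, 0.5).  Flexible mode:
    beta-binomial with the naked-DNA profile ``(p_bar_o, tau_o)``.
    """
    stack = _as_stack(pyramids)
    ll = _negbin_site_terms(stack, params.alpha_o, params.lambda0_bar_o)
    if params.flexbg:
        _check_depth(stack, len(params.p_bar_o))
        ll = ll + _betabin_scale_terms(stack, params.p_bar_o, params.tau_o)
        ll = ll + stack.logbc_persite()
    else:
        # sum over nodes of n*log(1/2); node totals at each scale sum to the
        # window total, so the exponent telescopes to J * total per replicate
        ll = ll + stack.logbc_persite() + np.log(0.5) * stack.J * stack.totals.sum(axis=1)
    return ll if isinstance(pyramids, PyramidStack) else float(ll[0])


def loglik_total_only(pyramids: Pyramids, params):
    """Scale-0 (total count) part only: the 'no cleavage profile' model.

    Accepts either component's parameter set and uses its gamma-Poisson
    totals; all split terms are dropped.
    """
    stack = _as_stack(pyramids)
    if isinstance(params, UnboundParams):
        alpha, lam = params.alpha_o, params.lambda0_bar_o
    else:
        alpha, lam = params.alpha, params.lambda0_bar
    ll = _negbin_site_terms(stack, alpha, lam)
    return ll if isinstance(pyramids, PyramidStack) else float(ll[0])
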