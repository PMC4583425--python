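"""Scikit-learn style front end to the footprint mixture model.

``FootprintMixture`` treats the (sites x replicates x bases) count tensor
as X and learns the two-component mixture by EM; ``predict_proba`` /
``decision_function`` then score any tensor extracted at the same window.
The estimator follows sklearn conventions (``get_params``/``set_params``,
trailing-underscore fitted attributes, ``check_is_fitted``) so it composes
with sklearn model selection where that is useful.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .inference import (
    EMConfig,
    FitResult,
    PosteriorResult,
    PriorModel,
    fit_flexbg,
    fit_mixture,
    posterior_odds,
)
from .likelihoods import BoundParams, UnboundParams
from .multiscale import PyramidStack, build_pyramid_stack

__all__ = ["FootprintMixture", "fit_footprint_mixture", "VARIANTS"]

VARIANTS = ("multiscale", "multiscale_flexbg", "total_only")


class FootprintMixture(BaseEstimator):
    """Two-component multiscale mixture for motif-site binding inference.

    Parameters
    ----------
    variant : {"multiscale", "multiscale_flexbg", "total_only"}
        Full model with uniform background, full model with the flexible
        naked-DNA background (requires ``background`` counts at fit time),
        or the total-count-only comparison model with no cleavage profile.
    tol : float
        Relative marginal log-likelihood change declaring convergence.
    max_iter : int
        Maximum EM (or SQUAREM outer) iterations.
    inner_maxiter : int
        L-BFGS iterations per M-step block.
    ridge : float
        L2 stabilizer of the logistic prior update.
    tau_init, alpha_init : float
        Starting precision per scale and gamma shape per replicate.
    accelerate : bool
        Use SQUAREM extrapolation over the EM cycle map.
    anchor_bound : bool
        After fitting, label the component with the larger mean total rate
        as bound (bound sites are hypersensitive).

    Attributes
    ----------
    bound_ : BoundParams
    unbound_ : UnboundParams
    prior_ : PriorModel
    loglik_trajectory_ : ndarray
    converged_ : bool
    n_iter_ : int
    window_ : int
    n_replicates_ : int
    """

    def __init__(self, variant: str = "multiscale", *, tol: float = 1e-6,
                 max_iter: int = 200, inner_maxiter: int = 25,
                 ridge: float = 1e-6, tau_init: float = 100.0,
                 alpha_init: float = 1.0, accelerate: bool = True,
                 anchor_bound: bool = True, verbose: bool = False):
        self.variant = variant
        self.tol = tol
        self.max_iter = max_iter
        self.inner_maxiter = inner_maxiter
        self.ridge = ridge
        self.tau_init = tau_init
        self.alpha_init = alpha_init
        self.accelerate = accelerate
        self.anchor_bound = anchor_bound
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _config(self) -> EMConfig:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        return EMConfig(
            tol=self.tol, max_iter=self.max_iter, inner_maxiter=self.inner_maxiter,
            ridge=self.ridge, tau_init=self.tau_init, alpha_init=self.alpha_init,
            total_only=self.variant == "total_only", accelerate=self.accelerate,
            anchor_bound=self.anchor_bound, verbose=self.verbose,
        )

    @staticmethod
    def _stack(X) -> PyramidStack:
        if isinstance(X, PyramidStack):
            return X
        return build_pyramid_stack(np.asarray(X))

    def fit(self, X, y=None, *, features=None, background=None):
        """Fit hyperparameters on a count tensor.

        ``X`` is (N, S, L) or (N, L); ``features`` optional (N, F) site
        covariates for the logistic prior (PWM score etc.); ``background``
        is the naked-DNA tensor required by the flexbg variant.
        """
        stack = self._stack(X)
        config = self._config()
        if self.variant == "multiscale_flexbg":
            if background is None:
                raise ValueError(
                    "variant 'multiscale_flexbg' needs naked-DNA background "
                    "counts; pass background=... or use variant 'multiscale'"
                )
            fit = fit_flexbg(self._stack(background), stack, features, config)
        else:
            fit = fit_mixture(stack, features, config)
        self.bound_ = fit.bound
        self.unbound_ = fit.unbound
        self.prior_ = fit.prior
        self.loglik_trajectory_ = fit.loglik_trajectory
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iterations
        self.window_ = stack.L
        self.n_replicates_ = stack.S
        self.classes_ = np.array([0, 1])
        return self

    def _fit_result(self) -> FitResult:
        check_is_fitted(self, "bound_")
        return FitResult(
            bound=self.bound_, unbound=self.unbound_, prior=self.prior_,
            loglik_trajectory=self.loglik_trajectory_, converged=self.converged_,
            n_iterations=self.n_iter_, total_only=self.variant == "total_only",
        )

    def posterior(self, X, features=None) -> PosteriorResult:
        """Full per-site posterior evidence (probabilities, log odds, lls)."""
        check_is_fitted(self, "bound_")
        stack = self._stack(X)
        if stack.L != self.window_:
            raise ValueError(
                f"model was fit at window {self.window_} but data has {stack.L}"
            )
        return posterior_odds(stack, self._fit_result(), features)

    def decision_function(self, X, features=None):
        """Natural-log posterior odds of binding per site."""
        return self.posterior(X, features).log_posterior_odds

    def predict_proba(self, X, features=None):
        p = self.posterior(X, features).posterior_prob
        return np.column_stack([1.0 - p, p])

    def predict(self, X, features=None):
        return (self.decision_function(X, features) > 0).astype(int)

    def score(self, X, y=None, features=None):
        """Mean per-site marginal log-likelihood under the fitted mixture."""
        res = self.posterior(X, features)
        zeta = np.clip(self.prior_.zeta(features, len(res.loglik_bound)), 1e-12, 1 - 1e-12)
        with np.errstate(divide="ignore"):
            l = np.logaddexp(
                np.log(zeta) + res.loglik_bound,
                np.log1p(-zeta) + res.loglik_unbound,
            )
        return float(l.mean())

    # ------------------------------------------------------------------
    # persistence

    def to_dict(self) -> dict:
        check_is_fitted(self, "bound_")
        return {
            "variant": self.variant,
            "window": int(self.window_),
            "n_replicates": int(self.n_replicates_),
            "bound": self.bound_.to_dict(),
            "unbound": self.unbound_.to_dict(),
            "prior": {"beta": self.prior_.beta.tolist()},
            "fit": {
                "converged": bool(self.converged_),
                "n_iterations": int(self.n_iter_),
                "loglik_trajectory": np.asarray(self.loglik_trajectory_).tolist(),
            },
        }

    def save(self, path: str):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FootprintMixture":
        est = cls(variant=d["variant"])
        est.bound_ = BoundParams.from_dict(d["bound"])
        est.unbound_ = UnboundParams.from_dict(d["unbound"])
        est.prior_ = PriorModel(beta=np.asarray(d["prior"]["beta"]))
        est.loglik_trajectory_ = np.asarray(d["fit"]["loglik_trajectory"])
        est.converged_ = bool(d["fit"]["converged"])
        est.n_iter_ = int(d["fit"]["n_iterations"])
        est.window_ = int(d["window"])
        est.n_replicates_ = int(d["n_replicates"])
        est.classes_ = np.array([0, 1])
        return est

    @classmethod
    def load(cls, path: str) -> "FootprintMixture":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_footprint_mixture(counts, features=None, background=None,
                          **kwargs) -> FootprintMixture:
    """Thin functional wrapper: fit a :class:`FootprintMixture` and return it."""
    return FootprintMixture(**kwargs).fit(
        counts, features=features, background=background
    )
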