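"""Scikit-learn style estimators over the BCI fitting routines.

``X`` is always a tidy trial table (``pandas.DataFrame`` with at least
``task``, ``condition`` and ``response`` columns; the trial-CSV schema).  The
estimators are thin stateful wrappers over :mod:`flashbci.fitting` so they
compose with sklearn model-selection tooling while the functional API stays
available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import core, fitting
from .types import (
    DEFAULT_MU_P,
    DEFAULT_SIGMA_A,
    STRATEGIES,
    VARIANTS,
    FitConfig,
    IntegrationSpec,
)

__all__ = ["BCIObserverFit", "ModelSelector", "AuditoryNoiseCalibrator"]


def _check_trials(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    missing = {"condition", "response"} - set(X.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    if X.empty:
        raise ValueError("empty trial table")
    return X


class BCIObserverFit(BaseEstimator):
    """Maximum-likelihood fit of one model variant under one decision rule.

    Parameters
    ----------
    variant : {"bci", "forced_fusion", "full_segregation", "mle"}
    strategy : {"averaging", "selection", "matching"}
    sigma_a, mu_p : auditory noise and prior mean fixed during the fit.
    n_restarts, seed, tolerance, likelihood_floor, included_tasks :
        see :class:`flashbci.types.FitConfig`.
    n_nodes, span_sigmas : marginalisation grid of the response model.

    Attributes (after ``fit``)
    --------------------------
    params_ : fitted :class:`ModelParams`
    log_likelihood_, bic_, r2_, n_trials_, k_free_ : fit summaries
    result_ : the full :class:`FitResult`
    """

    def __init__(
        self,
        variant: str = "bci",
        strategy: str = "averaging",
        sigma_a: float = DEFAULT_SIGMA_A,
        mu_p: float = DEFAULT_MU_P,
        n_restarts: int = 10,
        seed: int = 0,
        tolerance: float = 1e-6,
        likelihood_floor: float = 1e-6,
        included_tasks: tuple = ("detection", "double_flash"),
        n_nodes: int = 101,
        span_sigmas: float = 5.0,
    ):
        self.variant = variant
        self.strategy = strategy
        self.sigma_a = sigma_a
        self.mu_p = mu_p
        self.n_restarts = n_restarts
        self.seed = seed
        self.tolerance = tolerance
        self.likelihood_floor = likelihood_floor
        self.included_tasks = included_tasks
        self.n_nodes = n_nodes
        self.span_sigmas = span_sigmas

    def _config(self) -> FitConfig:
        return FitConfig(
            n_restarts=self.n_restarts,
            seed=self.seed,
            tolerance=self.tolerance,
            likelihood_floor=self.likelihood_floor,
            included_tasks=tuple(self.included_tasks),
            sigma_a=self.sigma_a,
            mu_p=self.mu_p,
            integration=IntegrationSpec(
                n_nodes_per_axis=self.n_nodes, span_sigmas=self.span_sigmas
            ),
        )

    def fit(self, X, y=None):
        X = _check_trials(X)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        result = fitting.fit_model(X, self.variant, self.strategy, self._config())
        self.result_ = result
        self.params_ = result.params
        self.log_likelihood_ = result.log_likelihood
        self.bic_ = result.bic
        self.r2_ = result.r2
        self.n_trials_ = result.n_trials
        self.k_free_ = result.k_free
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-trial response-category probabilities (n_trials, 4)."""
        self._check_fitted()
        X = _check_trials(X)
        spec = self._config().integration
        labels = sorted(X["condition"].unique())
        dists = core.response_distributions(labels, self.params_, self.strategy, spec)
        lookup = dict(zip(labels, dists))
        return np.vstack([lookup[c] for c in X["condition"]])

    def predict(self, X) -> np.ndarray:
        """Most probable reported count per trial."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per trial (higher is better)."""
        self._check_fitted()
        X = _check_trials(X)
        nll = fitting.negative_log_likelihood(
            X,
            self.variant,
            self.strategy,
            self.params_,
            self._config().integration,
            self.likelihood_floor,
        )
        return -nll / len(X)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")


class ModelSelector(BaseEstimator):
    """Fit all four model variants (BCI under all three decision rules).

    Attributes (after ``fit``)
    --------------------------
    report_ : :class:`flashbci.fitting.ModelComparisonReport`
    best_variant_, best_strategy_ : BIC winner
    screen_pass_ : whether the BCI fit clears the R2 quality screen
    """

    def __init__(
        self,
        sigma_a: float = DEFAULT_SIGMA_A,
        mu_p: float = DEFAULT_MU_P,
        n_restarts: int = 10,
        seed: int = 0,
        r2_threshold: float = 0.8,
        included_tasks: tuple = ("detection", "double_flash"),
        n_nodes: int = 101,
        span_sigmas: float = 5.0,
    ):
        self.sigma_a = sigma_a
        self.mu_p = mu_p
        self.n_restarts = n_restarts
        self.seed = seed
        self.r2_threshold = r2_threshold
        self.included_tasks = included_tasks
        self.n_nodes = n_nodes
        self.span_sigmas = span_sigmas

    def fit(self, X, y=None):
        X = _check_trials(X)
        config = FitConfig(
            n_restarts=self.n_restarts,
            seed=self.seed,
            included_tasks=tuple(self.included_tasks),
            sigma_a=self.sigma_a,
            mu_p=self.mu_p,
            integration=IntegrationSpec(
                n_nodes_per_axis=self.n_nodes, span_sigmas=self.span_sigmas
            ),
        )
        self.report_ = fitting.compare_models(X, config, self.r2_threshold)
        self.best_variant_ = self.report_.best_variant
        self.best_strategy_ = self.report_.best_strategy
        self.screen_pass_ = self.report_.r2_screen_pass
        return self


class AuditoryNoiseCalibrator(BaseEstimator):
    """1-D ML estimate of auditory noise from beep-count reports.

    Fits the reduced observer (independent causes, unisensory estimation,
    visual and prior parameters pinned) to beep-detection trials; exposes the
    estimate as ``sigma_a_``.
    """

    def __init__(self, seed: int = 0, n_nodes: int = 101, span_sigmas: float = 5.0):
        self.seed = seed
        self.n_nodes = n_nodes
        self.span_sigmas = span_sigmas

    def fit(self, X, y=None):
        X = _check_trials(X)
        config = FitConfig(
            seed=self.seed,
            integration=IntegrationSpec(
                n_nodes_per_axis=self.n_nodes, span_sigmas=self.span_sigmas
            ),
        )
        self.sigma_a_ = fitting.calibrate_sigma_a(X, config)
        return self
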