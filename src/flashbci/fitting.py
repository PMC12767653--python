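"""Maximum-likelihood fitting of the BCI observer and its reduced variants.

Four models are compared: the full BCI model (free causal prior, prior SD and
visual noise), forced fusion (p_common = 1), full segregation (p_common = 0)
and MLE-style cue averaging (fusion with a flat numerosity prior).  Auditory
noise is fixed at the value obtained from the beep-detection calibration
sub-fit (sigma_a = 0.2 by default) and the prior mean at mu_p = 1.5.  Models
are scored by BIC = k*ln(n) - 2*logL and screened by a variance-explained R2
computed on per-cell response-category proportions.

Detection-task trials carry yes/no reports coded as counts 1/0 and enter the
likelihood through p(report >= 1) vs p(report = 0); flash-numerosity trials
use the full 0-3 response distribution.
"""

from __future__ import annotations

import math
import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from . import core
from .types import (
    DEFAULT_BOUNDS,
    FLAT_SIGMA_P,
    R_MAX,
    STRATEGIES,
    VARIANTS,
    Condition,
    FitConfig,
    FitResult,
    IntegrationSpec,
    ModelParams,
    ModelVariant,
)

__all__ = [
    "negative_log_likelihood",
    "fit_model",
    "compute_bic",
    "compute_r2",
    "compare_models",
    "calibrate_sigma_a",
    "ModelComparisonReport",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Raised when a quantity (R2, correlation) is undefined on the data."""


# ---------------------------------------------------------------------------
# response-count tables


def _as_variant(variant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}") from None


def _trial_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = pd.DataFrame(list(trials))
    if df.empty:
        raise ValueError("empty trial set")
    return df


def _count_table(df: pd.DataFrame):
    """Collapse trials to per-(task, condition) response counts.

    Returns ``[(condition_label, kind, counts)]`` where ``kind`` is ``"detect"``
    for yes/no detection trials (counts over {no, yes}) and ``"count"`` for
    numerosity reports (counts over 0..R_MAX).  The likelihood then costs the
    same regardless of the number of trials.
    """
    entries = []
    for (task, cond), sub in df.groupby(["task", "condition"], sort=True):
        r = sub["response"].to_numpy(int)
        if task == "detection":
            counts = np.array([(r == 0).sum(), (r >= 1).sum()], float)
            entries.append((cond, "detect", counts))
        else:
            counts = np.bincount(r, minlength=R_MAX + 1).astype(float)
            entries.append((cond, "count", counts))
    return entries


def _nll_from_table(table, params, strategy, spec, floor):
    conds = [e[0] for e in table]
    dists = core.response_distributions(conds, params, strategy, spec)
    nll = 0.0
    floor_hits = 0
    for (cond, kind, counts), dist in zip(table, dists):
        if kind == "detect":
            probs = np.array([dist[0], 1.0 - dist[0]])
        else:
            probs = dist
        clipped = np.maximum(probs, floor)
        floor_hits += int(np.sum((probs < floor) & (counts > 0)))
        nll -= float(counts @ np.log(clipped))
    return nll, floor_hits


def negative_log_likelihood(
    trials,
    variant,
    strategy: str,
    params: ModelParams,
    spec: IntegrationSpec | None = None,
    floor: float = 1e-6,
) -> float:
    """-sum_t ln max(p(r_t | condition_t), floor) for the given observer."""
    variant = _as_variant(variant)
    for name, value in variant.fixed_params.items():
        if not math.isclose(getattr(params, name), value, rel_tol=0, abs_tol=1e-12):
            raise ValueError(
                f"params.{name}={getattr(params, name)} violates the "
                f"{variant.name} constraint {name}={value}"
            )
    df = _trial_frame(trials)
    table = _count_table(df)
    nll, _ = _nll_from_table(table, params, strategy, spec or IntegrationSpec(), floor)
    return nll


def compute_bic(log_likelihood: float, k_free: int, n_trials: int) -> float:
    """Bayesian Information Criterion, k*ln(n) - 2*logL (lower is better)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if k_free < 0:
        raise ValueError("k_free must be >= 0")
    return k_free * math.log(n_trials) - 2.0 * log_likelihood


# ---------------------------------------------------------------------------
# R2 fit-quality screen


def _cell_proportions(df: pd.DataFrame):
    """Observed response-category proportions per condition x location x eye cell."""
    keys = [k for k in ("eye", "location_id") if k in df.columns] + ["task", "condition"]
    obs, meta = [], []
    for key, sub in df.groupby(keys, sort=True):
        r = sub["response"].to_numpy(int)
        if sub["task"].iloc[0] == "detection":
            props = np.array([(r == 0).mean(), (r >= 1).mean()])
        else:
            props = np.bincount(r, minlength=R_MAX + 1) / len(r)
        obs.append(props)
        meta.append((sub["task"].iloc[0], sub["condition"].iloc[0], len(props)))
    return obs, meta


def compute_r2(
    trials,
    fit: "FitResult | ModelParams",
    spec: IntegrationSpec | None = None,
    strategy: str | None = None,
) -> float:
    """Variance explained: 1 - SS_res / SS_tot over cell-category proportions.

    Cells are condition x location x eye; observed values are the per-cell
    response-category proportions, predictions the model's category
    probabilities, and SS_tot is taken around the grand mean of the observed
    proportions.
    """
    if isinstance(fit, FitResult):
        params, strategy, spec = fit.params, fit.strategy, spec
    else:
        params = fit
        if strategy is None:
            raise ValueError("strategy required when passing raw params")
    spec = spec or IntegrationSpec()
    df = _trial_frame(trials)
    obs, meta = _cell_proportions(df)
    conds = sorted({(t, c) for t, c, _ in meta})
    dists = core.response_distributions([c for _, c in conds], params, strategy, spec)
    pred_by_cond = {}
    for (task, cond), dist in zip(conds, dists):
        if task == "detection":
            pred_by_cond[(task, cond)] = np.array([dist[0], 1.0 - dist[0]])
        else:
            pred_by_cond[(task, cond)] = dist
    observed = np.concatenate(obs)
    predicted = np.concatenate([pred_by_cond[(t, c)] for t, c, _ in meta])
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("all cells identical: R2 undefined")
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# optimisation

_LOG_SCALE = {"sigma_v", "sigma_p", "sigma_a"}
# ranges the multi-start draws from (inside the box constraints; sigmas log-uniform)
_START_RANGES = {
    "p_common": (0.05, 0.95),
    "sigma_v": (0.08, 2.0),
    "sigma_p": (0.3, 30.0),
    "sigma_a": (0.05, 2.0),
}

# deterministic coarse-scan axes seeding the local searches; the likelihood
# can be multimodal (p_common trades off against sigma_p), so random restarts
# alone are not reliable
_SCAN_AXES = {
    "p_common": np.linspace(0.05, 0.95, 7),
    "sigma_v": np.geomspace(0.1, 1.5, 5),
    "sigma_p": np.geomspace(0.3, 30.0, 5),
    "sigma_a": np.geomspace(0.05, 2.0, 5),
}


def _to_internal(name, value):
    return math.log(value) if name in _LOG_SCALE else value


def _from_internal(name, value):
    return math.exp(value) if name in _LOG_SCALE else value


def _filter_tasks(df: pd.DataFrame, included_tasks) -> pd.DataFrame:
    if "task" not in df.columns:
        df = df.assign(task="double_flash")
    sub = df[df["task"].isin(included_tasks)]
    if sub.empty:
        raise ValueError(f"no trials from tasks {tuple(included_tasks)}")
    return sub


def fit_model(trials, variant, strategy: str, config: FitConfig | None = None) -> FitResult:
    """Fit one model variant/strategy by bounded multi-start ML.

    Free parameters (per the variant) are optimised by Nelder-Mead in a
    transformed space (log for the sigmas) from ``config.n_restarts`` seeded
    starting points; the best restart wins.  Deterministic given
    ``config.seed``.
    """
    config = config or FitConfig()
    variant = _as_variant(variant)
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    df = _filter_tasks(_trial_frame(trials), config.included_tasks)
    table = _count_table(df)
    n_trials = len(df)
    spec = config.integration
    floor = config.likelihood_floor

    fixed = {"sigma_a": config.sigma_a, "mu_p": config.mu_p}
    fixed.update(variant.fixed_params)
    free = variant.free_params

    def params_from(z):
        values = dict(fixed)
        for name, zi in zip(free, z):
            values[name] = _from_internal(name, zi)
        values.setdefault("p_common", 0.5)
        return ModelParams(**values)

    def objective(z):
        nll, _ = _nll_from_table(table, params_from(z), strategy, spec, floor)
        return nll

    bounds = []
    for name in free:
        lo, hi = config.bounds.get(name, DEFAULT_BOUNDS[name])
        bounds.append((_to_internal(name, lo), _to_internal(name, hi)))

    rng = np.random.default_rng(config.seed)

    # coarse deterministic scan; its best corners join the seeded restarts
    axes = [
        [_to_internal(name, v) for v in _SCAN_AXES[name]
         if config.bounds.get(name, DEFAULT_BOUNDS[name])[0] <= v
         <= config.bounds.get(name, DEFAULT_BOUNDS[name])[1]]
        for name in free
    ]
    corners = [np.array(z) for z in itertools.product(*axes)]
    scan = sorted(corners, key=objective)[:3]

    starts = list(scan)
    for _ in range(config.n_restarts):
        z0 = []
        for name, (lo, hi) in zip(free, bounds):
            a, b = _START_RANGES[name]
            a, b = _to_internal(name, a), _to_internal(name, b)
            z0.append(rng.uniform(max(a, lo), min(b, hi)))
        starts.append(np.asarray(z0))

    best = None
    restart_fun = []
    for z0 in starts:
        res = optimize.minimize(
            objective,
            z0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-4, "fatol": config.tolerance, "maxiter": 400 * max(len(free), 1)},
        )
        restart_fun.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {config.n_restarts} restarts failed for {variant.name}/{strategy}"
        )
    # polish: restart the simplex from the winner (NM can stall on ridges)
    polish = optimize.minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-5, "fatol": config.tolerance, "maxiter": 400 * max(len(free), 1)},
    )
    if polish.fun <= best.fun:
        best = polish

    params = params_from(best.x)
    nll, floor_hits = _nll_from_table(table, params, strategy, spec, floor)
    logl = -nll
    try:
        r2 = compute_r2(df, params, spec, strategy)
    except DegenerateDataError:
        r2 = float("nan")
    return FitResult(
        variant=variant,
        strategy=strategy,
        params=params,
        log_likelihood=logl,
        n_trials=n_trials,
        k_free=variant.k_free,
        bic=compute_bic(logl, variant.k_free, n_trials),
        r2=r2,
        diagnostics={
            "floor_hits": floor_hits,
            "restart_nll": restart_fun,
            "n_restarts": config.n_restarts,
            "converged": bool(best.success),
        },
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparisonReport:
    """All fits for one fitting unit plus the BIC winner and the R2 screen."""

    fits: Mapping  # (variant_name, strategy) -> FitResult
    variant_best: Mapping  # variant_name -> FitResult (BCI: its best strategy)
    best_variant: str
    best_strategy: str
    r2_threshold: float

    @property
    def best(self) -> FitResult:
        return self.variant_best[self.best_variant]

    @property
    def r2_screen_pass(self) -> bool:
        r2 = self.variant_best["bci"].r2
        return bool(np.isfinite(r2) and r2 >= self.r2_threshold)

    def as_dict(self) -> dict:
        return {
            "fits": {f"{v}/{s}": fr.as_dict() for (v, s), fr in self.fits.items()},
            "best_variant": self.best_variant,
            "best_strategy": self.best_strategy,
            "r2_threshold": self.r2_threshold,
            "screen_pass": self.r2_screen_pass,
        }


def compare_models(
    trials, config: FitConfig | None = None, r2_threshold: float = 0.8
) -> ModelComparisonReport:
    """Fit all four variants (the BCI model under all three strategies).

    For p_common pinned at 1 or 0 the three decision strategies coincide, so
    the reduced variants are fitted once (labelled with the averaging rule).
    The winner is the lowest-BIC variant, the BCI entry being its best
    strategy.
    """
    config = config or FitConfig()
    fits = {}
    for strategy in STRATEGIES:
        fits[("bci", strategy)] = fit_model(trials, "bci", strategy, config)
    for name in ("forced_fusion", "full_segregation", "mle"):
        fits[(name, "averaging")] = fit_model(trials, name, "averaging", config)

    bci_best = min(
        (fits[("bci", s)] for s in STRATEGIES), key=lambda f: f.bic
    )
    variant_best = {
        "bci": bci_best,
        "forced_fusion": fits[("forced_fusion", "averaging")],
        "full_segregation": fits[("full_segregation", "averaging")],
        "mle": fits[("mle", "averaging")],
    }
    best_variant = min(variant_best, key=lambda v: variant_best[v].bic)
    return ModelComparisonReport(
        fits=fits,
        variant_best=variant_best,
        best_variant=best_variant,
        best_strategy=variant_best[best_variant].strategy,
        r2_threshold=r2_threshold,
    )


# ---------------------------------------------------------------------------
# auditory-noise calibration


def calibrate_sigma_a(beep_trials, config: FitConfig | None = None) -> float:
    """Estimate sigma_a from beep-count reports (beep-detection task).

    A reduced observer is used: independent causes (p_common = 0) with
    unisensory estimation, visual and prior parameters pinned
    (sigma_v = 0.4, mu_p = 0, sigma_p = flat), leaving sigma_a as the only
    free parameter of a 1-D ML fit.  A log-spaced scan brackets the optimum
    (ties resolved toward the smallest sigma_a) before local refinement.
    """
    config = config or FitConfig()
    df = _trial_frame(beep_trials)
    conds = [Condition.from_label(c) for c in df["condition"]]
    s_a = np.array([c.n_beeps for c in conds])
    if len(np.unique(s_a)) < 2:
        raise ValueError("beep trials show no auditory variation")
    responses = df["response"].to_numpy(int)
    counts = {
        b: np.bincount(responses[s_a == b], minlength=R_MAX + 1).astype(float)
        for b in np.unique(s_a)
    }
    spec = config.integration
    lo, hi = config.bounds.get("sigma_a", DEFAULT_BOUNDS["sigma_a"])

    def nll(sigma_a):
        params = ModelParams(
            p_common=0.0, sigma_v=0.4, sigma_a=sigma_a, sigma_p=FLAT_SIGMA_P, mu_p=0.0
        )
        total = 0.0
        for b, cnt in counts.items():
            dist = core.auditory_response_distribution(int(b), params, spec)
            total -= float(cnt @ np.log(np.maximum(dist, config.likelihood_floor)))
        return total

    grid = np.geomspace(lo, hi, 41)
    vals = np.array([nll(s) for s in grid])
    i = int(np.argmin(vals))  # first minimum -> smallest sigma on a plateau
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-5}
    )
    if res.fun < vals[i] - 1e-9:
        return float(res.x)
    return float(grid[i])
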