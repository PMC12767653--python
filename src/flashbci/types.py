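"""Domain types for the audiovisual numerosity observer and its fitting pipeline.

The experiment presents brief flashes and beeps at peripheral visual-field
locations; a stimulus is described by a condition code ``FXBY`` (X flashes,
Y beeps) and the observer reports an integer numerosity 0-3.  The generative
model is a Bayesian causal-inference (BCI) observer parameterised by a causal
prior ``p_common``, sensory noise standard deviations ``sigma_v`` / ``sigma_a``
(in flash-count units) and a Gaussian numerosity prior ``(mu_p, sigma_p)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Condition",
    "ModelParams",
    "IntegrationSpec",
    "ModelVariant",
    "FitConfig",
    "FitResult",
    "ObserverSpec",
    "STRATEGIES",
    "VARIANTS",
    "CONDITIONS",
    "R_MAX",
    "DEFAULT_SIGMA_A",
    "DEFAULT_MU_P",
    "FLAT_SIGMA_P",
]

#: Largest reportable numerosity (responses are integers in ``[0, R_MAX]``).
R_MAX = 3

#: Auditory noise fixed in the main fits (mean of the calibration sub-fits).
DEFAULT_SIGMA_A = 0.2

#: Numerosity prior mean fixed in the main fits.
DEFAULT_MU_P = 1.5

#: Prior standard deviation treated as "flat" (MLE variant, calibration).
FLAT_SIGMA_P = 4000.0

#: The three decision rules mapping the causal posterior to a report.
STRATEGIES = ("averaging", "selection", "matching")

_LABEL_RE = re.compile(r"^F(\d)B(\d)$")


@dataclass(frozen=True)
class Condition:
    """An ``FXBY`` audiovisual stimulus: ``n_flashes`` flashes, ``n_beeps`` beeps."""

    n_flashes: int
    n_beeps: int

    def __post_init__(self) -> None:
        if self.n_flashes not in (0, 1):
            raise ValueError(f"n_flashes must be 0 or 1, got {self.n_flashes}")
        if self.n_beeps not in (0, 1, 2):
            raise ValueError(f"n_beeps must be 0, 1 or 2, got {self.n_beeps}")

    @property
    def label(self) -> str:
        return f"F{self.n_flashes}B{self.n_beeps}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"not an FXBY condition label: {label!r}")
        return cls(int(m.group(1)), int(m.group(2)))


#: The four conditions used in the flash tasks.
CONDITIONS = {
    lab: Condition.from_label(lab) for lab in ("F0B0", "F1B0", "F1B1", "F1B2")
}


@dataclass(frozen=True)
class ModelParams:
    """BCI observer parameters.

    p_common : prior probability that flash and beep share a cause, in [0, 1].
    sigma_v, sigma_a : sensory noise SDs (flash/beep count units), > 0.
    sigma_p : SD of the Gaussian numerosity prior, > 0.
    mu_p : mean of the numerosity prior.
    """

    p_common: float
    sigma_v: float
    sigma_a: float = DEFAULT_SIGMA_A
    sigma_p: float = 1.5
    mu_p: float = DEFAULT_MU_P

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_common <= 1.0):
            raise ValueError(f"p_common must be in [0, 1], got {self.p_common}")
        for name in ("sigma_v", "sigma_a", "sigma_p"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not math.isfinite(self.mu_p):
            raise ValueError(f"mu_p must be finite, got {self.mu_p}")

    def replace(self, **kw) -> "ModelParams":
        d = {
            "p_common": self.p_common,
            "sigma_v": self.sigma_v,
            "sigma_a": self.sigma_a,
            "sigma_p": self.sigma_p,
            "mu_p": self.mu_p,
        }
        d.update(kw)
        return ModelParams(**d)

    def as_dict(self) -> dict:
        return {
            "p_common": self.p_common,
            "sigma_v": self.sigma_v,
            "sigma_a": self.sigma_a,
            "sigma_p": self.sigma_p,
            "mu_p": self.mu_p,
        }


@dataclass(frozen=True)
class IntegrationSpec:
    """How the discrete response distribution is marginalised over sensory noise.

    ``grid`` uses a deterministic tensor-product of Gauss-weighted nodes
    (``n_nodes_per_axis`` per sensory axis, spanning ``±span_sigmas`` standard
    deviations); ``monte_carlo`` draws ``mc_samples`` seeded samples and exists
    mainly as an independent cross-check of the grid.
    """

    n_nodes_per_axis: int = 101
    span_sigmas: float = 5.0
    method: str = "grid"
    mc_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes_per_axis < 11 or self.n_nodes_per_axis % 2 == 0:
            raise ValueError("n_nodes_per_axis must be an odd integer >= 11")
        if self.span_sigmas < 4:
            raise ValueError("span_sigmas must be >= 4")
        if self.method not in ("grid", "monte_carlo"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")


@dataclass(frozen=True)
class ModelVariant:
    """A model in the comparison set: which BCI parameters are free vs pinned."""

    name: str
    free_params: tuple
    fixed_params: Mapping[str, float] = field(default_factory=dict)

    @property
    def k_free(self) -> int:
        return len(self.free_params)


#: The four compared models.  The BCI model frees the causal prior, prior SD
#: and visual noise; forced fusion / full segregation pin p_common to 1 / 0;
#: the MLE model is forced fusion with a flat numerosity prior.
VARIANTS = {
    "bci": ModelVariant("bci", ("p_common", "sigma_p", "sigma_v"), {}),
    "forced_fusion": ModelVariant(
        "forced_fusion", ("sigma_p", "sigma_v"), {"p_common": 1.0}
    ),
    "full_segregation": ModelVariant(
        "full_segregation", ("sigma_p", "sigma_v"), {"p_common": 0.0}
    ),
    "mle": ModelVariant(
        "mle",
        ("sigma_v",),
        {"p_common": 1.0, "sigma_p": FLAT_SIGMA_P, "mu_p": DEFAULT_MU_P},
    ),
}

#: Default box constraints for the free parameters.
DEFAULT_BOUNDS = {
    "p_common": (0.0, 1.0),
    "sigma_v": (0.01, 10.0),
    "sigma_p": (0.01, 5000.0),
    "sigma_a": (0.01, 10.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Settings for maximum-likelihood fitting."""

    n_restarts: int = 10
    seed: int = 0
    bounds: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    tolerance: float = 1e-6
    likelihood_floor: float = 1e-6
    fit_unit: str = "participant"
    included_tasks: tuple = ("detection", "double_flash")
    sigma_a: float = DEFAULT_SIGMA_A
    mu_p: float = DEFAULT_MU_P
    integration: IntegrationSpec = field(default_factory=IntegrationSpec)

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.fit_unit not in ("participant", "participant_location"):
            raise ValueError(f"unknown fit_unit {self.fit_unit!r}")
        if not (self.likelihood_floor > 0):
            raise ValueError("likelihood_floor must be > 0")


@dataclass(frozen=True)
class FitResult:
    """One maximum-likelihood fit of a model variant/strategy to a trial set."""

    variant: ModelVariant
    strategy: str
    params: ModelParams
    log_likelihood: float
    n_trials: int
    k_free: int
    bic: float
    r2: float
    diagnostics: Mapping = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "variant": self.variant.name,
            "strategy": self.strategy,
            "params": self.params.as_dict(),
            "logL": self.log_likelihood,
            "n": self.n_trials,
            "k": self.k_free,
            "BIC": self.bic,
            "R2": None if self.r2 is None or not np.isfinite(self.r2) else self.r2,
            "diagnostics": dict(self.diagnostics),
        }


@dataclass(frozen=True)
class ObserverSpec:
    """Generative truth for one synthetic participant.

    ``detect_prob`` maps ``(location_id, eye)`` to the probability that a
    physically presented flash reaches the observer at all (undetected flashes
    are replaced by a zero-flash stimulus before inference); a scalar applies
    everywhere.  ``lapse_rate`` is the probability of a uniform 0-3 guess.
    """

    participant_id: str
    group: str
    true_params: ModelParams
    strategy: str = "averaging"
    detect_prob: object = 1.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("low_vision", "sighted"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")

    def detect_probability(self, location_id: int, eye: str) -> float:
        if isinstance(self.detect_prob, Mapping):
            return float(self.detect_prob[(location_id, eye)])
        return float(self.detect_prob)
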