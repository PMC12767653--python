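"""Synthetic study design and simulated observer cohorts.

Reproduces the experiment's structure: 24 stimulus locations (8 polar angles
x 5/10/15 degrees eccentricity), monocular flash-detection (F1B0 x5 + F0B0 x1
per location per eye) and double-flash (F1B2 x10 + F1B1 x1) tasks, and a
binocular beep-detection task (6 FXBY conditions x3 per location).  Responses
come from the generative BCI observer in :mod:`flashbci.core`.

Low-vision observers add the structure the analysis has to cope with:
per-location detectability (an undetected flash reaches the observer as a
zero-flash stimulus), optional response lapses, and heterogeneous model
parameters across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .types import R_MAX, STRATEGIES, Condition, ModelParams, ObserverSpec

__all__ = [
    "ECCENTRICITIES_DEG",
    "N_ANGLES",
    "EYES",
    "TRIAL_COLUMNS",
    "GroupConfig",
    "CohortConfig",
    "build_stimulus_grid",
    "build_task_design",
    "simulate_participant",
    "simulate_cohort",
]

ECCENTRICITIES_DEG = (5, 10, 15)
N_ANGLES = 8
EYES = ("left", "right")

#: Exact schema of the trial CSV.
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "eye",
    "location_id",
    "eccentricity_deg",
    "angle_index",
    "task",
    "condition",
    "response",
]

#: Condition repetitions per stimulus location, per task.
TASK_CONDITIONS = {
    "detection": {"F1B0": 5, "F0B0": 1},
    "double_flash": {"F1B2": 10, "F1B1": 1},
    "beep_detection": {
        f"F{f}B{b}": 3 for f in (0, 1) for b in (0, 1, 2)
    },
}


def build_stimulus_grid() -> pd.DataFrame:
    """The 24 stimulus locations, ordered by (eccentricity, angle).

    Angles are 45-degree steps around fixation; each of the three
    eccentricity rings holds eight locations.
    """
    rows = []
    loc = 0
    for ecc in ECCENTRICITIES_DEG:
        for ang in range(N_ANGLES):
            rows.append(
                {
                    "location_id": loc,
                    "eccentricity_deg": ecc,
                    "angle_index": ang,
                    "angle_deg": ang * 360.0 / N_ANGLES,
                }
            )
            loc += 1
    return pd.DataFrame(rows)


def build_task_design(task: str, seed: int, eyes=None) -> pd.DataFrame:
    """Randomised trial schedule for one task with exact repetition counts.

    Detection and double-flash run monocularly (shuffled separately per eye);
    beep detection is binocular.  Reproducible given ``seed``.
    """
    if task not in TASK_CONDITIONS:
        raise ValueError(f"unknown task {task!r}")
    grid = build_stimulus_grid()
    if task == "beep_detection":
        eyes = ("binocular",)
    elif eyes is None:
        eyes = EYES
    rng = np.random.default_rng(seed)
    frames = []
    for eye in eyes:
        rows = []
        for _, loc in grid.iterrows():
            for cond, reps in TASK_CONDITIONS[task].items():
                for _ in range(reps):
                    rows.append(
                        {
                            "eye": eye,
                            "location_id": int(loc.location_id),
                            "eccentricity_deg": int(loc.eccentricity_deg),
                            "angle_index": int(loc.angle_index),
                            "task": task,
                            "condition": cond,
                        }
                    )
        block = pd.DataFrame(rows)
        frames.append(block.iloc[rng.permutation(len(block))].reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def _detection_code(counts: np.ndarray) -> np.ndarray:
    """Detection yes/no coded as counts 1/0 from a numerosity report."""
    return (counts >= 1).astype(int)


def simulate_participant(spec: ObserverSpec, designs, seed: int) -> pd.DataFrame:
    """Forward-simulate every trial of the given task designs for one observer.

    For flash tasks, an undetected flash (probability ``1 - detect_prob`` at
    that location/eye) replaces the visual stimulus with s_V = 0 before the
    observer's inference; lapses replace the report with a uniform 0-3 guess.
    Beep-detection responses use the auditory channel alone.  Detection-task
    reports are coded 1 (flash seen, count >= 1) or 0.
    """
    if isinstance(designs, pd.DataFrame):
        designs = [designs]
    rng = np.random.default_rng(seed)
    frames = []
    for design in designs:
        df = design.reset_index(drop=True).copy()
        n = len(df)
        task = df["task"].iloc[0]
        responses = np.zeros(n, int)
        if task == "beep_detection":
            for cond_label, idx in df.groupby("condition").groups.items():
                cond = Condition.from_label(cond_label)
                idx = np.asarray(idx)
                x_a = rng.normal(cond.n_beeps, spec.true_params.sigma_a, size=len(idx))
                flat = spec.true_params.replace(sigma_p=4000.0, mu_p=0.0)
                est = core.estimate_auditory_alone(x_a, flat)
                responses[idx] = core.discretize_estimate(est)
        else:
            detect_p = np.array(
                [
                    spec.detect_probability(l, e)
                    for l, e in zip(df["location_id"], df["eye"])
                ]
            )
            n_flashes = np.array(
                [Condition.from_label(c).n_flashes for c in df["condition"]]
            )
            seen = rng.random(n) < detect_p
            eff_flashes = np.where(seen, n_flashes, 0)
            for cond_label, idx in df.groupby("condition").groups.items():
                cond = Condition.from_label(cond_label)
                idx = np.asarray(idx)
                for s_v in np.unique(eff_flashes[idx]):
                    mask = idx[eff_flashes[idx] == s_v]
                    eff = Condition(int(s_v), cond.n_beeps)
                    responses[mask] = core.simulate_responses(
                        eff, spec.true_params, spec.strategy, len(mask), rng
                    )
            if task == "detection":
                responses = _detection_code(responses)
        if spec.lapse_rate > 0:
            lapse = rng.random(n) < spec.lapse_rate
            guesses = rng.integers(0, R_MAX + 1, size=n)
            if task == "detection":
                guesses = _detection_code(guesses)
            responses = np.where(lapse, guesses, responses)
        df["response"] = responses
        df["participant_id"] = spec.participant_id
        df["group"] = spec.group
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupConfig:
    """Distributions the per-participant generative truths are drawn from.

    Parameter means/SDs default to the magnitudes typical of audiovisual
    numerosity studies (causal prior ~0.8 sighted / ~0.6 low vision, visual
    noise ~0.3 flash units, prior SD ~1-2); the between-participant SDs are
    the reported standard errors scaled by sqrt(N).  Low-vision field loss is
    emulated by a per-participant fraction of "invisible" locations with low
    flash detectability.
    """

    group: str = "sighted"
    n: int = 21
    p_common_mean: float = 0.81
    p_common_sd: float = 0.27
    sigma_p_mean: float = 1.64
    sigma_p_sd: float = 0.96
    sigma_v_mean: float = 0.35
    sigma_v_sd: float = 0.14
    sigma_a: float = 0.2
    mu_p: float = 1.5
    invisible_fraction_range: tuple = (0.0, 0.0)
    invisible_detect_range: tuple = (0.05, 0.4)
    visible_detect_range: tuple = (1.0, 1.0)
    lapse_range: tuple = (0.0, 0.0)
    # empirical prevalence of the three decision rules (averaging most common)
    strategy_probs: tuple = (0.59, 0.24, 0.18)


def low_vision_defaults() -> GroupConfig:
    return GroupConfig(
        group="low_vision",
        n=21,
        p_common_mean=0.63,
        p_common_sd=0.40,
        sigma_p_mean=1.04,
        sigma_p_sd=0.83,
        sigma_v_mean=0.32,
        sigma_v_sd=0.18,
        invisible_fraction_range=(0.1, 0.6),
        invisible_detect_range=(0.05, 0.4),
        visible_detect_range=(0.85, 1.0),
        lapse_range=(0.0, 0.05),
    )


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple = field(
        default_factory=lambda: (GroupConfig(), low_vision_defaults())
    )
    tasks: tuple = ("detection", "double_flash")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _draw_observer(rng, gcfg: GroupConfig, participant_id: str) -> ObserverSpec:
    params = ModelParams(
        p_common=_truncated_normal(rng, gcfg.p_common_mean, gcfg.p_common_sd, 0.0, 1.0),
        sigma_v=_truncated_normal(rng, gcfg.sigma_v_mean, gcfg.sigma_v_sd, 0.05, 3.0),
        sigma_a=gcfg.sigma_a,
        sigma_p=_truncated_normal(rng, gcfg.sigma_p_mean, gcfg.sigma_p_sd, 0.1, 20.0),
        mu_p=gcfg.mu_p,
    )
    probs = np.asarray(gcfg.strategy_probs, float)
    strategy = STRATEGIES[rng.choice(len(STRATEGIES), p=probs / probs.sum())]
    f_lo, f_hi = gcfg.invisible_fraction_range
    frac_invisible = rng.uniform(f_lo, f_hi)
    if gcfg.invisible_fraction_range == (0.0, 0.0) and gcfg.visible_detect_range == (
        1.0,
        1.0,
    ):
        detect_prob = 1.0  # fully sighted: every location detectable
    else:
        grid = build_stimulus_grid()
        detect_prob = {}
        for eye in EYES:
            n_loc = len(grid)
            invisible = rng.random(n_loc) < frac_invisible
            lows = rng.uniform(*gcfg.invisible_detect_range, size=n_loc)
            highs = rng.uniform(*gcfg.visible_detect_range, size=n_loc)
            for loc, inv, lo, hi in zip(grid["location_id"], invisible, lows, highs):
                detect_prob[(int(loc), eye)] = float(lo if inv else hi)
    return ObserverSpec(
        participant_id=participant_id,
        group=gcfg.group,
        true_params=params,
        strategy=strategy,
        detect_prob=detect_prob,
        lapse_rate=float(rng.uniform(*gcfg.lapse_range)),
    )


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Simulate every participant of the configured cohort.

    Returns ``(trials, truth)``: one tidy trial table covering all
    participants (schema :data:`TRIAL_COLUMNS`) and the list of generating
    :class:`ObserverSpec` truths, for recovery scoring.  Deterministic given
    ``seed``; each participant uses a child seed so that adding participants
    never perturbs existing ones.
    """
    config = config or CohortConfig()
    truth = []
    frames = []
    for g_idx, gcfg in enumerate(config.groups):
        prefix = "LV" if gcfg.group == "low_vision" else "SC"
        for i in range(gcfg.n):
            pid = f"{prefix}{i + 1:03d}"
            child = np.random.default_rng([seed, g_idx, i])
            spec = _draw_observer(child, gcfg, pid)
            designs = [
                build_task_design(task, seed=int(child.integers(2**31)))
                for task in config.tasks
            ]
            trials = simulate_participant(spec, designs, seed=int(child.integers(2**31)))
            truth.append(spec)
            frames.append(trials)
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS), truth
    return pd.concat(frames, ignore_index=True), truth
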