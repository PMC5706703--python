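"""Synthetic cohort generator.

Simulates subjects performing the candy-catching task with the statistical
structure the downstream analysis assumes: targets from the blockwise prior,
splashes from the likelihood, and a linear-weighting response model

    response = w(condition) * centroid + (1 - w(condition)) * prior_mean + noise

with per-subject motor noise and occasional lapses.  A lapse either leaves
the net at its random initial position ("net_init", the default — the failure
mode hypothesized for inattentive trials) or produces no response at all
("timeout", recorded as a missing value).

Reliance weights ``w`` may follow the ideal-observer value per condition
(optionally shrunk toward the prior by ``weight_scale``), or be a constant
(a heuristic, non-Bayesian subject).  Subject-level heterogeneity is injected
through independent per-condition weight jitter and jittered noise/lapse
parameters, and every subject receives an age drawn to mimic the study cohort
(mean 8.22 y, SD 1.80 y, clipped to 5-12 y).

Randomness is split with ``numpy.random.SeedSequence`` keyed by
(group index, subject index), so extending a cohort never reshuffles the
subjects already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .task import DEFAULT_DESIGN, Condition, TaskDesign, optimal_slope

__all__ = [
    "Observer",
    "SubjectDataset",
    "GroupSpec",
    "CohortSpec",
    "default_cohort_spec",
    "null_cohort_spec",
    "build_schedule",
    "sample_trial",
    "simulate_response",
    "simulate_subject",
    "simulate_cohort",
]

LapseMode = Literal["net_init", "timeout"]

#: Canonical order of the per-trial table columns (splash columns inserted
#: between `target` and `net_init` by the writers).
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "block",
    "trial_index",
    "prior_sd",
    "likelihood_sd",
    "target",
    "net_init",
    "response",
    "caught",
]


@dataclass
class Observer:
    """A simulated subject.

    ``weights`` maps (prior_sd, likelihood_sd) to the reliance weight used in
    that condition; it is ``None`` for subjects reconstructed from a trial CSV
    (their ground truth is unknown).
    """

    subject_id: str
    group: str
    age: float
    weights: Optional[dict[tuple[float, float], float]]
    motor_noise_sd: float = 0.0
    lapse_rate: float = 0.0
    lapse_mode: LapseMode = "net_init"
    seed: object = None

    def __post_init__(self) -> None:
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")
        if self.weights is not None:
            for key, w in self.weights.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"weight for {key} outside [0, 1]: {w}")

    def weight_for(self, condition: Condition | tuple[float, float]) -> float:
        if self.weights is None:
            raise ValueError(f"observer {self.subject_id} has no ground-truth weights")
        key = condition.key if isinstance(condition, Condition) else tuple(condition)
        for (p, l), w in self.weights.items():
            if np.isclose(p, key[0]) and np.isclose(l, key[1]):
                return w
        raise KeyError(f"no weight for condition {key}")


@dataclass
class SubjectDataset:
    """One subject's metadata plus their ordered per-trial table."""

    observer: Observer
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)


class GroupSpec(BaseModel):
    """Distributional spec for one group of simulated subjects."""

    model_config = ConfigDict(extra="forbid")

    name: str
    n_subjects: int = Field(default=9, ge=1)
    weight_scale: float = Field(default=1.0, ge=0.0, le=2.0)
    constant_weight: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    weight_jitter_sd: float = Field(default=0.08, ge=0.0)
    motor_noise_sd: float = Field(default=0.03, ge=0.0)
    motor_noise_jitter_sd: float = Field(default=0.005, ge=0.0)
    lapse_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    lapse_jitter_sd: float = Field(default=0.02, ge=0.0)
    lapse_mode: LapseMode = "net_init"
    age_mean: float = 8.22
    age_sd: float = Field(default=1.80, ge=0.0)


class CohortSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    groups: list[GroupSpec]


def default_cohort_spec() -> CohortSpec:
    """Two age-matched groups of 9: near-optimal TD subjects and CP subjects
    whose reliance on the likelihood is shrunk toward the prior."""
    return CohortSpec(
        groups=[
            GroupSpec(name="CP", weight_scale=0.75),
            GroupSpec(name="TD", weight_scale=1.0),
        ]
    )


def null_cohort_spec() -> CohortSpec:
    """Two groups drawn from one and the same observer distribution
    (no group effect); used for calibration studies."""
    return CohortSpec(
        groups=[
            GroupSpec(name="CP", weight_scale=1.0),
            GroupSpec(name="TD", weight_scale=1.0),
        ]
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_schedule(
    design: TaskDesign = DEFAULT_DESIGN,
    start_prior: str = "random",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Blocked trial schedule: prior constant within a block and alternating
    across blocks; the likelihood conditions balanced and shuffled within
    each block.

    ``start_prior`` is "narrow", "wide", or "random" (a coin flip, as in the
    experiment's randomly chosen starting condition).  Returns a DataFrame
    with columns block, trial_index, prior_sd, likelihood_sd.
    """
    rng = _as_rng(seed)
    lik_sds = sorted(design.likelihood_sds)
    if design.trials_per_block % len(lik_sds) != 0:
        raise ValueError(
            f"trials_per_block={design.trials_per_block} is not divisible by the "
            f"{len(lik_sds)} likelihood conditions"
        )
    prior_sds = sorted(design.prior_sds)
    if start_prior == "random":
        start_prior = "narrow" if rng.integers(2) == 0 else "wide"
    if start_prior == "narrow":
        order = [prior_sds[0], prior_sds[-1]]
    elif start_prior == "wide":
        order = [prior_sds[-1], prior_sds[0]]
    else:
        raise ValueError(f"start_prior must be narrow|wide|random, got {start_prior!r}")

    reps = design.trials_per_block // len(lik_sds)
    rows = []
    for block in range(design.n_blocks):
        prior_sd = order[block % 2]
        liks = np.repeat(lik_sds, reps)
        rng.shuffle(liks)
        for t, lik in enumerate(liks):
            rows.append((block, t, prior_sd, float(lik)))
    return pd.DataFrame(rows, columns=["block", "trial_index", "prior_sd", "likelihood_sd"])


def sample_trial(
    condition: Condition | tuple[float, float],
    design: TaskDesign = DEFAULT_DESIGN,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Draw one trial's stimuli: (target, splash, net_init).

    target ~ N(mu, prior_sd^2); splash = n i.i.d. N(target, likelihood_sd^2);
    net_init ~ Uniform[0, 1].  No truncation at the screen edges.
    """
    rng = _as_rng(rng)
    prior_sd, lik_sd = (
        condition.key if isinstance(condition, Condition) else tuple(condition)
    )
    target = rng.normal(design.prior_mean, prior_sd)
    splash = rng.normal(target, lik_sd, size=design.n_samples)
    net_init = rng.uniform(0.0, 1.0)
    return float(target), splash, float(net_init)


def simulate_response(
    observer: Observer,
    splash: np.ndarray,
    net_init: float,
    condition: Condition | tuple[float, float],
    design: TaskDesign = DEFAULT_DESIGN,
    rng: np.random.Generator | int | None = None,
) -> float:
    """One response from the linear-weighting model, or NaN on a timeout lapse."""
    rng = _as_rng(rng)
    w = observer.weight_for(condition)
    if observer.lapse_rate > 0 and rng.uniform() < observer.lapse_rate:
        return float("nan") if observer.lapse_mode == "timeout" else float(net_init)
    c = float(np.mean(splash))
    resp = w * c + (1.0 - w) * design.prior_mean
    if observer.motor_noise_sd > 0:
        resp += rng.normal(0.0, observer.motor_noise_sd)
    return float(resp)


def simulate_subject(
    observer: Observer,
    design: TaskDesign = DEFAULT_DESIGN,
    start_prior: str = "random",
    seed: int | np.random.Generator | None = None,
) -> SubjectDataset:
    """Simulate a full session (schedule + stimuli + responses) for one subject.

    Vectorized over trials.  ``caught`` is |response - target| <= net_halfwidth
    and is missing exactly when the response is missing (timeout).
    """
    rng = _as_rng(observer.seed if seed is None else seed)
    sched = build_schedule(design, start_prior=start_prior, seed=rng)
    n = len(sched)
    targets = rng.normal(design.prior_mean, sched["prior_sd"].to_numpy())
    splash = rng.normal(
        targets[:, None],
        sched["likelihood_sd"].to_numpy()[:, None],
        size=(n, design.n_samples),
    )
    net_init = rng.uniform(0.0, 1.0, size=n)
    centroids = splash.mean(axis=1)

    # resolve each unique condition once, then broadcast over trials
    pairs = list(zip(sched["prior_sd"].to_numpy(), sched["likelihood_sd"].to_numpy()))
    wmap = {key: observer.weight_for(key) for key in set(pairs)}
    weights = np.array([wmap[key] for key in pairs])
    resp = weights * centroids + (1.0 - weights) * design.prior_mean
    resp += rng.normal(0.0, observer.motor_noise_sd, size=n)
    lapse = rng.uniform(size=n) < observer.lapse_rate
    if observer.lapse_mode == "timeout":
        resp[lapse] = np.nan
    else:
        resp[lapse] = net_init[lapse]

    caught = pd.array(np.abs(resp - targets) <= design.net_halfwidth, dtype="boolean")
    caught[np.isnan(resp)] = pd.NA

    df = pd.DataFrame(
        {
            "subject_id": observer.subject_id,
            "group": observer.group,
            "age": observer.age,
            "block": sched["block"],
            "trial_index": sched["trial_index"],
            "prior_sd": sched["prior_sd"],
            "likelihood_sd": sched["likelihood_sd"],
            "target": targets,
        }
    )
    for j in range(design.n_samples):
        df[f"splash_{j + 1}"] = splash[:, j]
    df["net_init"] = net_init
    df["response"] = resp
    df["caught"] = caught
    return SubjectDataset(observer=observer, trials=df)


def _make_observer(
    gspec: GroupSpec,
    subject_id: str,
    design: TaskDesign,
    ss: np.random.SeedSequence,
) -> Observer:
    rng = np.random.default_rng(ss)
    age = float(np.clip(rng.normal(gspec.age_mean, gspec.age_sd), 5.0, 12.0))
    weights: dict[tuple[float, float], float] = {}
    for cond in design.conditions():
        if gspec.constant_weight is not None:
            base = gspec.constant_weight
        else:
            base = gspec.weight_scale * optimal_slope(
                cond.prior_sd, cond.likelihood_sd, design.n_samples
            )
        w = float(np.clip(base + rng.normal(0.0, gspec.weight_jitter_sd), 0.0, 1.0))
        weights[cond.key] = w
    noise = float(max(rng.normal(gspec.motor_noise_sd, gspec.motor_noise_jitter_sd), 0.0))
    lapse = float(np.clip(rng.normal(gspec.lapse_rate, gspec.lapse_jitter_sd), 0.0, 0.3))
    return Observer(
        subject_id=subject_id,
        group=gspec.name,
        age=age,
        weights=weights,
        motor_noise_sd=noise,
        lapse_rate=lapse,
        lapse_mode=gspec.lapse_mode,
    )


def simulate_cohort(
    spec: CohortSpec | None = None,
    design: TaskDesign = DEFAULT_DESIGN,
    seed: int = 0,
) -> list[SubjectDataset]:
    """Simulate every subject of a cohort, reproducibly.

    Each subject's observer parameters and session use generators seeded by
    SeedSequence(seed, spawn_key=(group_index, subject_index, stream)), so the
    cohort is stable under appending groups or subjects.
    """
    spec = spec or default_cohort_spec()
    datasets: list[SubjectDataset] = []
    for gi, gspec in enumerate(spec.groups):
        for si in range(gspec.n_subjects):
            sid = f"{gspec.name}{si + 1:02d}"
            obs_ss = np.random.SeedSequence(seed, spawn_key=(gi, si, 0))
            trial_ss = np.random.SeedSequence(seed, spawn_key=(gi, si, 1))
            observer = _make_observer(gspec, sid, design, obs_ss)
            observer.seed = (seed, gi, si)
            datasets.append(
                simulate_subject(
                    observer,
                    design,
                    start_prior="random",
                    seed=np.random.default_rng(trial_ss),
                )
            )
    return datasets


def cohort_manifest(datasets: list[SubjectDataset], design: TaskDesign) -> dict:
    """Ground-truth observer parameters, JSON-serializable; the companion of a
    written trial CSV, used by parameter-recovery checks."""
    subjects = []
    for ds in datasets:
        o = ds.observer
        subjects.append(
            {
                "subject_id": o.subject_id,
                "group": o.group,
                "age": o.age,
                "motor_noise_sd": o.motor_noise_sd,
                "lapse_rate": o.lapse_rate,
                "lapse_mode": o.lapse_mode,
                "seed": list(o.seed) if isinstance(o.seed, tuple) else o.seed,
                "weights": None
                if o.weights is None
                else {
                    design.condition_for(p, l).name: w
                    for (p, l), w in o.weights.items()
                },
            }
        )
    return {"n_subjects": len(subjects), "subjects": subjects}
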