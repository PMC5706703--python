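"""Generative model of the candy-catching task and its Bayesian ideal observer.

The task: on each trial a hidden target ("candy") is drawn from a Gaussian
prior over horizontal screen position, N(mu, sigma_s^2).  The subject sees a
"splash" of ``n`` dots drawn i.i.d. from a Gaussian likelihood centered on the
target, N(s, sigma_l^2), and places a narrow vertical "net" where they believe
the target fell.  Positions are expressed in screen-width units: the screen
spans [0, 1] and the prior mean sits at 0.5.

An ideal observer combines the splash centroid (the sufficient statistic for
the likelihood location, with sampling distribution N(s, sigma_l^2 / n)) with
the prior by precision weighting, yielding a Gaussian posterior whose mean is
a convex combination of prior mean and centroid.  The weight on the centroid,

    w* = sigma_s^2 / (sigma_s^2 + sigma_l^2 / n),

is the optimal reliance on the likelihood and the benchmark against which
subjects' fitted estimation slopes are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TaskDesign",
    "Condition",
    "PosteriorParams",
    "DEFAULT_DESIGN",
    "optimal_slope",
    "posterior_params",
    "centroid",
    "chance_level",
]


def _require_positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class Condition:
    """One cell of the prior x likelihood design."""

    prior_sd: float
    likelihood_sd: float
    prior_label: str
    likelihood_label: str

    @property
    def name(self) -> str:
        return f"{self.prior_label}_prior-{self.likelihood_label}_likelihood"

    @property
    def key(self) -> tuple[float, float]:
        return (self.prior_sd, self.likelihood_sd)


@dataclass(frozen=True)
class TaskDesign:
    """Fixed parameters of the experiment.

    All positions and SDs are in screen-width units.  The default instance is
    the study design: prior mean at screen center, prior SD .03 (narrow) or
    .1 (wide), likelihood SD .025 / .1 / .25 (narrow / medium / wide), splashes
    of 4 dots, 4 blocks of 120 trials, a 6 s response window and a 1 s
    stimulus.  The net half-width of .01 is chosen so that a uniformly placed
    net catches the target on ~2% of trials (the task's chance level).
    """

    prior_mean: float = 0.5
    prior_sds: tuple[float, ...] = (0.03, 0.1)
    likelihood_sds: tuple[float, ...] = (0.025, 0.1, 0.25)
    n_samples: int = 4
    n_blocks: int = 4
    trials_per_block: int = 120
    net_halfwidth: float = 0.01
    response_window: float = 6.0
    stimulus_duration: float = 1.0

    def __post_init__(self) -> None:
        for name in ("prior_sds", "likelihood_sds"):
            sds = getattr(self, name)
            if len(sds) == 0:
                raise ValueError(f"{name} must be non-empty")
            for sd in sds:
                _require_positive(name, sd)
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if not 0.0 <= self.prior_mean <= 1.0:
            raise ValueError(f"prior_mean must lie in [0, 1], got {self.prior_mean}")
        if not 0.0 < self.net_halfwidth < 0.5:
            raise ValueError(
                f"net_halfwidth must lie in (0, 0.5), got {self.net_halfwidth}"
            )
        if self.response_window <= 0 or self.stimulus_duration <= 0:
            raise ValueError("response_window and stimulus_duration must be > 0")

    def conditions(self) -> list[Condition]:
        """The crossed prior x likelihood conditions, narrowest first."""
        prior_labels = _spread_labels(len(self.prior_sds))
        lik_labels = _spread_labels(len(self.likelihood_sds))
        out = []
        for p_sd, p_lab in zip(sorted(self.prior_sds), prior_labels):
            for l_sd, l_lab in zip(sorted(self.likelihood_sds), lik_labels):
                out.append(Condition(p_sd, l_sd, p_lab, l_lab))
        return out

    def condition_for(self, prior_sd: float, likelihood_sd: float) -> Condition:
        for cond in self.conditions():
            if np.isclose(cond.prior_sd, prior_sd) and np.isclose(
                cond.likelihood_sd, likelihood_sd
            ):
                return cond
        raise KeyError(
            f"({prior_sd}, {likelihood_sd}) is not a condition of this design"
        )


def _spread_labels(k: int) -> list[str]:
    if k == 1:
        return ["only"]
    if k == 2:
        return ["narrow", "wide"]
    if k == 3:
        return ["narrow", "medium", "wide"]
    return [f"level{i + 1}" for i in range(k)]


DEFAULT_DESIGN = TaskDesign()


@dataclass(frozen=True)
class PosteriorParams:
    """Mean and variance of the ideal observer's Gaussian posterior."""

    mean: float
    variance: float


def optimal_slope(prior_sd: float, likelihood_sd: float, n_samples: int) -> float:
    """Optimal reliance on the likelihood, sigma_s^2 / (sigma_s^2 + sigma_l^2/n).

    This is the weight an ideal observer places on the splash centroid, and
    the benchmark value of the estimation slope.  Strictly between 0 and 1
    for finite positive SDs: 1 in the limit of a perfectly reliable splash
    (sigma_l -> 0), 0 in the limit of a perfectly concentrated prior.
    """
    _require_positive("prior_sd", prior_sd)
    _require_positive("likelihood_sd", likelihood_sd)
    if not np.all(np.asarray(n_samples) >= 1):
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    prior_var = np.square(prior_sd)
    centroid_var = np.square(likelihood_sd) / n_samples
    return prior_var / (prior_var + centroid_var)


def posterior_params(
    prior_mean: float,
    prior_sd: float,
    centroid: float,
    likelihood_sd: float,
    n_samples: int,
) -> PosteriorParams:
    """Gaussian posterior over target location given the splash centroid.

    Precision-weighted combination of the prior N(mu, sigma_s^2) and the
    centroid sampling distribution N(s, sigma_l^2/n): the posterior mean is
    w*c + (1-w)*mu with w = ``optimal_slope``, and the posterior precision is
    the sum of the two precisions.
    """
    w = optimal_slope(prior_sd, likelihood_sd, n_samples)
    mean = w * centroid + (1.0 - w) * prior_mean
    variance = 1.0 / (1.0 / prior_sd**2 + n_samples / likelihood_sd**2)
    return PosteriorParams(mean=float(mean), variance=float(variance))


def centroid(splash: Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean of the splash dots — the likelihood's location estimate."""
    arr = np.asarray(splash, dtype=float)
    if arr.size == 0:
        raise ValueError("splash must contain at least one sample")
    return float(arr.mean())


def chance_level(
    design: TaskDesign = DEFAULT_DESIGN,
    n_mc: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
    net_halfwidth: float | None = None,
) -> float:
    """Monte-Carlo catch probability of a net placed uniformly at random.

    Targets are drawn from the widest prior of the design (the condition in
    which random placement is most forgiving is irrelevant here: for a net
    much narrower than the screen the answer is ~2*net_halfwidth regardless).
    With the default half-width of .01 this is the task's ~2% chance level.

    ``net_halfwidth`` overrides the design's value when given (it may be 0,
    which yields probability 0).
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    hw = design.net_halfwidth if net_halfwidth is None else float(net_halfwidth)
    if hw < 0:
        raise ValueError(f"net_halfwidth must be >= 0, got {hw}")
    rng = np.random.default_rng(seed)
    prior_sd = max(design.prior_sds)
    targets = rng.normal(design.prior_mean, prior_sd, size=n_mc)
    nets = rng.uniform(0.0, 1.0, size=n_mc)
    return float(np.mean(np.abs(nets - targets) <= hw))
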