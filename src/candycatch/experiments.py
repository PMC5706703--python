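"""Simulation studies that validate the analysis chain on synthetic cohorts.

These are the package's standard numerical experiments: parameter recovery
(do fitted estimation slopes recover the generating weights?), bootstrap CI
coverage, type-I calibration of the Scheirer-Ray-Hare group effect under a
null cohort, and its power under a known group difference.  Tests and the
reproduction script both call these, so the numbers they report come from
one code path.

Problem sizes default to: one study-sized cohort (18 subjects x 480 trials)
for recovery, 500 single-condition subjects for coverage, and 200 simulated
cohorts for calibration.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, GroupSpec, simulate_cohort
from .estimation import bootstrap_slope_ci, fit_cohort_slopes
from .stats import slopes_factorial_test
from .task import DEFAULT_DESIGN, TaskDesign

__all__ = [
    "recovery_experiment",
    "ci_coverage_experiment",
    "null_calibration_experiment",
    "power_experiment",
]


def recovery_cohort_spec(lapse_mode: str = "timeout") -> CohortSpec:
    """The recovery study's cohort: study-condition noise (0.03) and lapse
    rate (0.05), near-optimal TD group and prior-shifted CP group.

    Recovery is assessed with "timeout" lapses by default: those trials are
    missing and excluded by the slope fit, so the fitted slope estimates the
    generating weight.  With "net_init" lapses the lapse trials stay in the
    regression and the slope's estimand is itself shifted away from the
    weight — that variant measures contamination, not estimator error.
    """
    return CohortSpec(
        groups=[
            GroupSpec(name="CP", weight_scale=0.75, lapse_mode=lapse_mode),
            GroupSpec(name="TD", weight_scale=1.0, lapse_mode=lapse_mode),
        ]
    )


def recovery_experiment(
    seed: int,
    design: TaskDesign = DEFAULT_DESIGN,
    lapse_mode: str = "timeout",
) -> dict:
    """Median absolute error of fitted slopes against the generating weights
    over one 18-subject cohort (6 conditions x 18 subjects = 108 fits)."""
    spec = recovery_cohort_spec(lapse_mode)
    datasets = simulate_cohort(spec, design, seed=seed)
    slopes = fit_cohort_slopes(datasets, design, n_boot=0, seed=seed)
    truth = {}
    for ds in datasets:
        for key, w in ds.observer.weights.items():
            truth[(ds.observer.subject_id, round(key[0], 9), round(key[1], 9))] = w
    errors = np.array(
        [
            abs(r.slope - truth[(r.subject_id, round(r.prior_sd, 9), round(r.likelihood_sd, 9))])
            for r in slopes.itertuples()
        ]
    )
    return {
        "median_abs_error": float(np.median(errors)),
        "max_abs_error": float(np.max(errors)),
        "n_fits": int(errors.size),
    }


def ci_coverage_experiment(
    seed: int,
    n_subjects: int = 500,
    n_trials: int = 80,
    n_boot: int = 1000,
    motor_noise_sd: float = 0.03,
    design: TaskDesign = DEFAULT_DESIGN,
) -> dict:
    """Coverage of the 95% percentile bootstrap CI for the estimation slope.

    Each simulated subject performs ``n_trials`` trials of one condition
    (conditions cycled over the design grid) with a known weight drawn
    uniformly from [0.1, 0.9], motor noise and no lapses; coverage is the
    fraction of subjects whose CI contains the generating weight.
    """
    rng = np.random.default_rng(seed)
    conds = [(c.prior_sd, c.likelihood_sd) for c in design.conditions()]
    mu = design.prior_mean
    covered = 0
    for i in range(n_subjects):
        prior_sd, lik_sd = conds[i % len(conds)]
        w = rng.uniform(0.1, 0.9)
        targets = rng.normal(mu, prior_sd, n_trials)
        splash = rng.normal(targets[:, None], lik_sd, (n_trials, design.n_samples))
        c = splash.mean(axis=1)
        y = w * c + (1 - w) * mu + rng.normal(0, motor_noise_sd, n_trials)
        lo, hi = bootstrap_slope_ci(c, y, mu, n_boot=n_boot, seed=rng)
        covered += lo <= w <= hi
    return {"coverage": covered / n_subjects, "n_subjects": n_subjects}


def null_cohort_constant_spec(weight: float = 0.5) -> CohortSpec:
    """Null cohort for calibration: both groups drawn from one and the same
    observer distribution with a condition-independent mean weight, so the
    only structure in the slopes is noise (no group, prior, or likelihood
    effect)."""
    return CohortSpec(
        groups=[
            GroupSpec(name="CP", constant_weight=weight),
            GroupSpec(name="TD", constant_weight=weight),
        ]
    )


def null_calibration_experiment(
    seed: int,
    n_cohorts: int = 200,
    alpha: float = 0.05,
    design: TaskDesign = DEFAULT_DESIGN,
) -> dict:
    """Type-I error of the SRH group main effect over simulated null cohorts."""
    spec = null_cohort_constant_spec()
    rejections = 0
    for i in range(n_cohorts):
        datasets = simulate_cohort(spec, design, seed=seed + i)
        slopes = fit_cohort_slopes(datasets, design, n_boot=0, seed=seed + i)
        p = slopes_factorial_test(slopes, effects=["group"])[0].p_value
        rejections += p < alpha
    return {
        "rejection_rate": rejections / n_cohorts,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
    }


def power_experiment(
    seed: int,
    n_sims: int = 40,
    weight_a: float = 0.4,
    weight_b: float = 0.6,
    motor_noise_sd: float = 0.05,
    alpha: float = 0.05,
    design: TaskDesign = DEFAULT_DESIGN,
) -> dict:
    """Power of the SRH group effect when group mean weights differ."""
    spec = CohortSpec(
        groups=[
            GroupSpec(name="CP", constant_weight=weight_a, motor_noise_sd=motor_noise_sd),
            GroupSpec(name="TD", constant_weight=weight_b, motor_noise_sd=motor_noise_sd),
        ]
    )
    rejections = 0
    for i in range(n_sims):
        datasets = simulate_cohort(spec, design, seed=seed + i)
        slopes = fit_cohort_slopes(datasets, design, n_boot=0, seed=seed + i)
        p = slopes_factorial_test(slopes, effects=["group"])[0].p_value
        rejections += p < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}
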