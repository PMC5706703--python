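"""End-to-end pipeline: simulate -> fit -> test -> report.

A ``RunConfig`` (JSON, schema-validated; unknown keys rejected) bundles the
task design, the cohort spec and the analysis options.  Every stage is a
plain function over files/dataframes so the CLI subcommands and ``run``
compose identically, and all randomness flows from the single master seed
recorded in the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import io as ccio
from .cohort import CohortSpec, SubjectDataset, default_cohort_spec, simulate_cohort
from .estimation import cohort_performance, fit_cohort_slopes
from .stats import (
    TestResult,
    group_performance_test,
    performance_vs_chance,
    slopes_factorial_test,
)
from .task import TaskDesign, chance_level

__all__ = [
    "DesignConfig",
    "AnalysisConfig",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_fit",
    "stage_test",
    "stage_report",
]

log = logging.getLogger("candycatch")


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    prior_mean: float = 0.5
    prior_sds: list[float] = Field(default=[0.03, 0.1])
    likelihood_sds: list[float] = Field(default=[0.025, 0.1, 0.25])
    n_samples: int = 4
    n_blocks: int = 4
    trials_per_block: int = 120
    net_halfwidth: float = 0.01
    response_window: float = 6.0
    stimulus_duration: float = 1.0

    def to_design(self) -> TaskDesign:
        return TaskDesign(
            prior_mean=self.prior_mean,
            prior_sds=tuple(self.prior_sds),
            likelihood_sds=tuple(self.likelihood_sds),
            n_samples=self.n_samples,
            n_blocks=self.n_blocks,
            trials_per_block=self.trials_per_block,
            net_halfwidth=self.net_halfwidth,
            response_window=self.response_window,
            stimulus_duration=self.stimulus_duration,
        )


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_boot: int = 1000
    fit_intercept: bool = False
    chance: float = 0.02
    alternative: str = "two-sided"
    wilcoxon_mode: str = "auto"
    paired_group_test: bool = True
    chance_mc: int = 200_000


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    design: DesignConfig = Field(default_factory=DesignConfig)
    cohort: CohortSpec = Field(default_factory=default_cohort_spec)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0
    out_dir: str = "candycatch_out"
    trials_csv: Optional[str] = None  # analyze an existing CSV instead of simulating


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON run config; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    try:
        return RunConfig.model_validate_json(Path(path).read_text())
    except ValidationError as err:
        raise ValueError(f"invalid run config {path}:\n{err}") from err


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: FAILED after %.2fs (%s)", stage, dt, exc)
            return False

    return _T()


def stage_simulate(config: RunConfig, out_dir: Path) -> list[SubjectDataset]:
    design = config.design.to_design()
    with _timed("simulate"):
        datasets = simulate_cohort(config.cohort, design, seed=config.seed)
        ccio.write_trials(datasets, out_dir / "trials.csv")
        ccio.write_manifest(datasets, design, out_dir / "manifest.json")
    return datasets


def stage_fit(
    datasets: list[SubjectDataset], config: RunConfig, out_dir: Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    design = config.design.to_design()
    with _timed("fit"):
        slopes = fit_cohort_slopes(
            datasets,
            design,
            n_boot=config.analysis.n_boot,
            seed=config.seed,
            fit_intercept=config.analysis.fit_intercept,
        )
        perf = cohort_performance(datasets, design)
        slopes.to_csv(out_dir / "slopes.csv", index=False, float_format=ccio.FLOAT_FORMAT)
        perf.to_csv(out_dir / "performance.csv", index=False, float_format=ccio.FLOAT_FORMAT)
    return slopes, perf


def stage_test(
    slopes: pd.DataFrame, perf: pd.DataFrame, config: RunConfig, out_dir: Path
) -> dict:
    a = config.analysis
    design = config.design.to_design()
    with _timed("test"):
        results: list[TestResult] = []
        results += performance_vs_chance(
            perf, chance=a.chance, alternative=a.alternative, mode=a.wilcoxon_mode
        )
        results.append(
            group_performance_test(
                perf,
                paired=a.paired_group_test,
                alternative=a.alternative,
                mode=a.wilcoxon_mode,
            )
        )
        results += slopes_factorial_test(slopes)
        chance_mc = chance_level(design, n_mc=a.chance_mc, seed=config.seed)
        bundle = {
            "seed": config.seed,
            "chance_level_mc": chance_mc,
            "chance_level_assumed": a.chance,
            "tests": [r.to_dict() for r in results],
        }
        (out_dir / "tests.json").write_text(json.dumps(bundle, indent=2))
    return bundle


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    def fmt(v):
        return floatfmt.format(v) if isinstance(v, (float, np.floating)) else str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in r) + " |" for r in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


def stage_report(out_dir: Path) -> Path:
    """Render a Markdown report from the CSV/JSON artifacts in ``out_dir``."""
    with _timed("report"):
        slopes = pd.read_csv(out_dir / "slopes.csv")
        perf = pd.read_csv(out_dir / "performance.csv")
        bundle = json.loads((out_dir / "tests.json").read_text())

        perf_tab = (
            perf.groupby("group")["p_correct"]
            .agg(["median", "mean", "count"])
            .reset_index()
        )
        slope_tab = (
            slopes.groupby(["prior_label", "likelihood_label", "group"])
            .agg(mean_slope=("slope", "mean"), optimal=("optimal", "first"))
            .reset_index()
            .sort_values(["prior_label", "likelihood_label", "group"])
        )
        tests = pd.DataFrame(bundle["tests"])

        lines = [
            "# Candy-catching analysis report",
            "",
            f"Master seed: {bundle['seed']}",
            "",
            f"Monte-Carlo chance level: {bundle['chance_level_mc']:.4f} "
            f"(assumed {bundle['chance_level_assumed']:.3f})",
            "",
            "## Task performance p(correct) by group",
            "",
            _md_table(perf_tab),
            "",
            "## Estimation slope by condition and group (vs optimal)",
            "",
            _md_table(slope_tab),
            "",
            "## Statistical tests",
            "",
            _md_table(tests.fillna(""), floatfmt="{:.4g}"),
            "",
        ]
        path = out_dir / "report.md"
        path.write_text("\n".join(lines))
    return path


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages; returns a bundle with the in-memory artifacts and paths.

    If ``config.trials_csv`` is set, simulation is skipped and the CSV is
    analyzed instead (identical downstream path).
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.trials_csv is not None:
        with _timed("load"):
            datasets = ccio.read_trials(
                config.trials_csv, design=config.design.to_design()
            )
    else:
        datasets = stage_simulate(config, out)
    slopes, perf = stage_fit(datasets, config, out)
    tests = stage_test(slopes, perf, config, out)
    report = stage_report(out)
    return {
        "out_dir": out,
        "datasets": datasets,
        "slopes": slopes,
        "performance": perf,
        "tests": tests,
        "report_path": report,
    }
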