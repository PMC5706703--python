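"""Readers and writers for the package's plain-text interchange formats.

The canonical per-trial table is a CSV with header

    subject_id, group, age, block, trial_index, prior_sd, likelihood_sd,
    target, splash_1..splash_n, net_init, response, caught

in screen-width units; an empty ``response`` cell is a timeout (missing), and
``caught`` is then empty too.  Floats are written with 12 significant digits
so a write -> read round trip is lossless for practical purposes.  Files with
different column names (e.g. a deposited dataset) are adapted through a
``column_map`` of {file column -> canonical column}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .task import TaskDesign, DEFAULT_DESIGN
from .cohort import Observer, SubjectDataset, cohort_manifest

__all__ = [
    "write_trials",
    "read_trials",
    "write_manifest",
    "read_manifest",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"

_MANDATORY = [
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
]
_INT_COLS = ["block", "trial_index"]
_FLOAT_COLS = ["age", "prior_sd", "likelihood_sd", "target", "net_init"]


def write_trials(datasets: Iterable[SubjectDataset], path: str | Path) -> Path:
    """Write a cohort's trials as one canonical CSV (deterministic bytes)."""
    path = Path(path)
    df = pd.concat([ds.trials for ds in datasets], ignore_index=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _parse_float(
    raw: pd.Series, col: str, allow_blank: bool
) -> tuple[np.ndarray, list[int]]:
    vals = np.full(len(raw), np.nan)
    bad: list[int] = []
    for i, s in enumerate(raw):
        s = s.strip()
        if s == "":
            if not allow_blank:
                bad.append(i)
            continue
        try:
            vals[i] = float(s)
        except ValueError:
            bad.append(i)
    return vals, bad


def read_trials(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    design: TaskDesign = DEFAULT_DESIGN,
) -> list[SubjectDataset]:
    """Read a trial CSV into per-subject datasets.

    ``column_map`` renames file columns to canonical names before
    validation.  Rows with unparseable numerics raise with their file line
    numbers; blank cells are permitted only in ``response``/``caught``.
    Observers reconstructed here carry no ground-truth weights.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        unknown = set(column_map) - set(raw.columns)
        if unknown:
            raise ValueError(f"column_map refers to absent columns: {sorted(unknown)}")
        raw = raw.rename(columns=dict(column_map))

    splash_cols = sorted(
        (c for c in raw.columns if c.startswith("splash_")),
        key=lambda c: int(c.split("_")[1]),
    )
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if not splash_cols:
        missing.append("splash_1..splash_n")
    if missing:
        raise ValueError(f"trial CSV {path} lacks mandatory columns: {missing}")

    df = pd.DataFrame({"subject_id": raw["subject_id"], "group": raw["group"]})
    errors: list[str] = []
    for col in _INT_COLS:
        vals, bad = _parse_float(raw[col], col, allow_blank=False)
        if bad:
            errors.append(f"{col}: lines {[i + 2 for i in bad[:5]]}")
        df[col] = vals.astype("int64", copy=False) if not bad else vals
    for col in _FLOAT_COLS + splash_cols:
        vals, bad = _parse_float(raw[col], col, allow_blank=False)
        if bad:
            errors.append(f"{col}: lines {[i + 2 for i in bad[:5]]}")
        df[col] = vals
    vals, bad = _parse_float(raw["response"], "response", allow_blank=True)
    if bad:
        errors.append(f"response: lines {[i + 2 for i in bad[:5]]}")
    df["response"] = vals
    if errors:
        raise ValueError(f"unparseable numeric cells in {path}: " + "; ".join(errors))

    if "caught" in raw.columns:
        caught = pd.array(
            [None if s.strip() == "" else s.strip().lower() in ("true", "1")
             for s in raw["caught"]],
            dtype="boolean",
        )
    else:
        hit = np.abs(df["response"] - df["target"]) <= design.net_halfwidth
        caught = pd.array(hit, dtype="boolean")
        caught[np.isnan(df["response"])] = pd.NA
    df["caught"] = caught

    # caught must be missing exactly when the response is
    df.loc[np.isnan(df["response"]), "caught"] = pd.NA

    dup = df.duplicated(subset=["subject_id", "block", "trial_index"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValueError(
            f"duplicate (subject_id, block, trial_index) rows in {path}, "
            f"e.g. lines {lines}"
        )

    # reorder to canonical layout
    ordered = (
        ["subject_id", "group", "age", "block", "trial_index",
         "prior_sd", "likelihood_sd", "target"]
        + splash_cols
        + ["net_init", "response", "caught"]
    )
    df = df[ordered]

    datasets = []
    for sid in df["subject_id"].unique():
        sub = df[df["subject_id"] == sid].reset_index(drop=True)
        observer = Observer(
            subject_id=str(sid),
            group=str(sub["group"].iloc[0]),
            age=float(sub["age"].iloc[0]),
            weights=None,
        )
        datasets.append(SubjectDataset(observer=observer, trials=sub))
    return datasets


def write_manifest(
    datasets: list[SubjectDataset], design: TaskDesign, path: str | Path
) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cohort_manifest(datasets, design), indent=2))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
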