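"""Trial-table I/O, run configuration and reproducibility plumbing.

The on-disk trial format is a plain CSV with one row per participant ×
round and the header::

    participant_id,round_index,condition,truth,E1,X1,X2,X3,X4,E2

``X4`` is present only for CONTROL rounds (four peers, no stimulus, no
first estimate); ``E1`` is empty exactly there.  Readers validate the
schema row by row and report offending row indices, so malformed tables
fail early rather than deep inside a fit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .task_design import (
    ALL_ROUND_TYPES,
    DEFAULT_MEAN_OFFSET_FRACTION,
    DEFAULT_SLIDER,
    Trial,
)

__all__ = [
    "SCHEMA_COLUMNS",
    "RunConfig",
    "read_trials",
    "write_trials",
    "trials_from_frame",
    "trials_to_frame",
    "data_hash",
    "config_hash",
    "load_defaults",
]


def load_defaults() -> dict:
    """The packaged canonical design constants (defaults.yaml)."""
    from importlib import resources

    text = resources.files("beastmix").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)

SCHEMA_COLUMNS = (
    "participant_id", "round_index", "condition", "truth",
    "E1", "X1", "X2", "X3", "X4", "E2",
)

_INT_COLS = ("round_index", "truth", "E1", "X1", "X2", "X3", "X4", "E2")


@dataclass(frozen=True)
class RunConfig:
    """Serializable bundle of the constants governing a run.

    Absent fields fall back to the packaged defaults; a run's config (and
    its hash) is archived alongside every artifact it produces.
    """

    slider: tuple[int, int] = DEFAULT_SLIDER
    mean_offset_fraction: float = DEFAULT_MEAN_OFFSET_FRACTION
    n_participants: int = 95
    n_condition_rounds: int = 5
    n_filler: int = 10
    n_control: int = 5
    pool_size: int = 100
    estimator_bias: float = -0.1
    estimator_sd: float = 0.25
    prior_mean_sd: float = 2.5
    prior_group_sd_scale: float = 1.0
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    rhat_threshold: float = 1.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "slider" in raw:
            raw["slider"] = tuple(raw["slider"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["slider"] = list(d["slider"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a config for artifact provenance."""
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def data_hash(trials: pd.DataFrame) -> str:
    """Stable short hash of a trial table (order-insensitive)."""
    df = trials.loc[:, list(SCHEMA_COLUMNS)].sort_values(
        ["participant_id", "round_index"], kind="mergesort"
    )
    payload = df.to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate(df: pd.DataFrame, slider: tuple[int, int]) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df.loc[:, list(SCHEMA_COLUMNS)].copy()
    for col in _INT_COLS:
        try:
            df[col] = df[col].astype("Int64")
        except (ValueError, TypeError) as err:
            raise ValueError(f"column {col!r} must be integer: {err}") from None

    lo, hi = slider
    errors = []
    for idx, row in df.iterrows():
        cond = row["condition"]
        if cond not in ALL_ROUND_TYPES:
            errors.append(f"row {idx}: unknown condition {cond!r}")
            continue
        is_ctrl = cond == "CONTROL"
        if pd.isna(row["E2"]):
            errors.append(f"row {idx}: E2 missing")
        if is_ctrl:
            if not pd.isna(row["E1"]):
                errors.append(f"row {idx}: CONTROL round must not have E1")
            if any(pd.isna(row[c]) for c in ("X1", "X2", "X3", "X4")):
                errors.append(f"row {idx}: CONTROL round needs X1..X4")
        else:
            if pd.isna(row["E1"]):
                errors.append(f"row {idx}: E1 missing")
            if any(pd.isna(row[c]) for c in ("X1", "X2", "X3")):
                errors.append(f"row {idx}: needs X1..X3")
            if not pd.isna(row["X4"]):
                errors.append(f"row {idx}: X4 only allowed for CONTROL")
        for c in ("E1", "X1", "X2", "X3", "X4", "E2"):
            v = row[c]
            if not pd.isna(v) and not (lo <= v <= hi):
                errors.append(f"row {idx}: {c}={v} outside slider {slider}")
    if errors:
        raise ValueError("invalid trial table:\n" + "\n".join(errors[:20]))
    return df


def read_trials(path: str | Path, slider: tuple[int, int] = DEFAULT_SLIDER) -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    return _validate(df, slider)


def write_trials(trials: pd.DataFrame, path: str | Path,
                 slider: tuple[int, int] = DEFAULT_SLIDER) -> None:
    """Validate and write a trial table CSV (round-trips with read_trials)."""
    df = _validate(trials, slider)
    df.to_csv(path, index=False)


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        X = list(t.X) + [None] * (4 - len(t.X))
        rows.append(dict(
            participant_id=t.participant_id, round_index=t.round_index,
            condition=t.condition, truth=t.truth, E1=t.E1,
            X1=X[0], X2=X[1], X3=X[2], X4=X[3], E2=t.E2,
        ))
    df = pd.DataFrame(rows)
    for col in _INT_COLS:
        df[col] = df[col].astype("Int64")
    return df


def trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    """Convert a validated trial table into Trial objects."""
    out = []
    for _, row in df.iterrows():
        is_ctrl = row["condition"] == "CONTROL"
        xs = ("X1", "X2", "X3", "X4") if is_ctrl else ("X1", "X2", "X3")
        out.append(Trial(
            participant_id=str(row["participant_id"]),
            round_index=int(row["round_index"]),
            condition=str(row["condition"]),
            truth=int(row["truth"]),
            E1=None if is_ctrl else int(row["E1"]),
            X=tuple(int(row[c]) for c in xs),
            E2=None if pd.isna(row["E2"]) else int(row["E2"]),
        ))
    return out
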