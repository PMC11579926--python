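"""File contracts: trial-table and trace CSV schemas, configs, manifests.

Conventions: times in seconds, session-relative (0 at session start);
sessions 1-based (0 = pre-exposure); contrasts stored as fractions in
(0, 1].  CSV is the interchange format; every reader validates its schema
strictly and lists offending columns in errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .photometry import PhotometryTrace

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_trace",
    "write_trace",
    "RunConfig",
    "load_run_config",
    "write_manifest",
    "load_real_data_stub",
    "SchemaError",
]


class SchemaError(ValueError):
    pass


TRIAL_COLUMNS = {
    "session_index": "int",
    "trial_index": "int",
    "side": "str",
    "contrast": "float",
    "quiescent_duration": "float",
    "stim_onset_time": "float",
    "first_movement_time": "float",
    "feedback_time": "float",
    "choice": "str",
    "correct": "bool",
    "reward_volume": "float",
}

TRACE_COLUMNS = ("time_s", "fluorescence")


def _check_columns(df: pd.DataFrame, required, what: str):
    missing = sorted(set(required) - set(df.columns))
    extra = sorted(set(df.columns) - set(required))
    if missing or extra:
        raise SchemaError(
            f"{what}: bad columns; missing={missing or 'none'}, "
            f"unexpected={extra or 'none'}")


def write_trials(trials: pd.DataFrame, path) -> None:
    _check_columns(trials, TRIAL_COLUMNS, "trial table")
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Contrasts must be fractions in (0, 1]; values > 1 (a percent dialect)
    are rejected with a pointer at the convention.
    """
    df = pd.read_csv(path)
    _check_columns(df, TRIAL_COLUMNS, f"trial table {path}")
    df["session_index"] = df["session_index"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    bad = df["contrast"].dropna()
    if ((bad <= 0) | (bad > 1)).any():
        raise SchemaError(
            f"trial table {path}: contrast values must be fractions in "
            "(0, 1] (got values outside that range; percent dialects like "
            "'100' are not accepted)")
    sides = set(df["side"].dropna()) | set(df["choice"].dropna())
    if not sides <= {"left", "right"}:
        raise SchemaError(f"trial table {path}: side/choice must be "
                          f"left/right, got {sorted(sides)}")
    if df["correct"].notna().any():
        df["correct"] = df["correct"].map(
            {True: True, False: False, "True": True, "False": False})
    return df[list(TRIAL_COLUMNS)]


def write_trace(trace: PhotometryTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace(path, stage: str = "raw", region: str = "",
               hemisphere: str = "", session_id: str = "") -> PhotometryTrace:
    df = pd.read_csv(path)
    _check_columns(df, TRACE_COLUMNS, f"trace {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise SchemaError(f"trace {path}: malformed timestamps")
    return PhotometryTrace(time=t,
                           values=df["fluorescence"].to_numpy(dtype=float),
                           stage=stage, region=region, hemisphere=hemisphere,
                           session_id=session_id)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (all stage parameters explicit)."""

    out_dir: str = "runs/out"
    seed: int = 0
    # cohort
    n_mice: int = 2
    n_sessions: int = 4
    trials_per_session: int = 100
    # stage toggles
    stages: tuple = ("simulate", "fit_behavior", "preprocess", "fit_encoding",
                     "correlate")
    # behavior sampler
    chains: int = 2
    warmup: int = 200
    draws: int = 200
    # encoding
    n_basis: int = 7
    contrast_metric: str = "diff-of-norms"
    region: str = "DMS"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def write_manifest(path, config: RunConfig, stage_info: dict) -> None:
    import dalearn

    manifest = {
        "dalearn_version": dalearn.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": stage_info,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def load_real_data_stub(manifest: dict):
    """Adapter for user-supplied pre-downloaded public task datasets.

    ``manifest`` maps names to local file paths ({'trials': ..., 'trace':
    ...}) conforming to the documented CSV schemas.  This package performs
    no network access; absent files raise an error naming the expected paths
    and schema rather than falling back silently.
    """
    out = {}
    expected = {k: Path(v) for k, v in manifest.items()}
    missing = [f"{k}: {p}" for k, p in expected.items() if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "real-data files not found: " + "; ".join(missing)
            + ". Provide pre-downloaded CSVs matching the documented "
            "schemas (trial table columns: " + ", ".join(TRIAL_COLUMNS)
            + "; trace columns: " + ", ".join(TRACE_COLUMNS) + ").")
    if "trials" in expected:
        out["trials"] = read_trials(expected["trials"])
    if "trace" in expected:
        out["trace"] = read_trace(expected["trace"])
    return out
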