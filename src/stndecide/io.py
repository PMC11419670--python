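"""Reading, writing, and validation of the package's file formats.

Trial tables and spike tables travel as plain CSV; fitted models,
cluster reports, and study reports as JSON.  Validation is strict and
reports the offending row and rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "SPIKE_COLUMNS",
    "write_trials",
    "read_trials",
    "write_spikes",
    "read_spikes",
    "write_json",
    "read_json",
    "validate_trials",
    "validate_spikes",
    "validate_file",
    "ValidationError",
]

TRIAL_COLUMNS = ["session_id", "trial_id", "signed_coh", "estim", "choice", "rt_s", "correct"]
SPIKE_COLUMNS = ["neuron_id", "trial_id", "alignment", "window_start_ms", "window_ms", "count"]


class ValidationError(ValueError):
    """A file violated the format contract; ``errors`` lists specifics."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def write_trials(trials: pd.DataFrame, path, ground_truth: bool = False) -> None:
    cols = list(TRIAL_COLUMNS)
    if ground_truth and "decision_time_s" in trials.columns:
        cols.append("decision_time_s")
    trials[cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    errors = validate_trials(df)
    if errors:
        raise ValidationError(errors)
    df["estim"] = df["estim"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    return df


def write_spikes(spikes: pd.DataFrame, path) -> None:
    spikes[SPIKE_COLUMNS].to_csv(path, index=False)


def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    errors = validate_spikes(df)
    if errors:
        raise ValidationError(errors)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def validate_trials(df: pd.DataFrame, max_errors: int = 20) -> list:
    """Rule-by-rule validation of a trial table; returns error strings."""
    errors = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {', '.join(missing)}"]
    for i, row in enumerate(df.itertuples(index=False)):
        if len(errors) >= max_errors:
            errors.append("... further errors suppressed")
            break
        if not (-1.0 <= row.signed_coh <= 1.0):
            errors.append(f"row {i}: signed_coh {row.signed_coh} outside [-1, 1]")
        if row.choice not in ("contra", "ipsi"):
            errors.append(f"row {i}: choice {row.choice!r} not in {{contra, ipsi}}")
        if not (row.rt_s > 0):
            errors.append(f"row {i}: rt_s {row.rt_s} violates rt > 0")
    n_mags = df["signed_coh"].abs().round(12).nunique()
    if n_mags != 5:
        errors.append(f"expected 5 distinct coherence magnitudes, found {n_mags}")
    for sid, g in df.groupby("session_id"):
        n_e = int(g["estim"].sum())
        n_c = len(g) - n_e
        if abs(n_e - n_c) > 1:
            errors.append(
                f"session {sid}: estim/control counts {n_e}/{n_c} differ by more than 1"
            )
    return errors


def validate_spikes(df: pd.DataFrame, max_errors: int = 20) -> list:
    """Rule-by-rule validation of a spike-count table."""
    errors = []
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {', '.join(missing)}"]
    counts = df["count"]
    bad_int = ~np.equal(np.mod(counts, 1), 0) | (counts < 0)
    for i in np.flatnonzero(bad_int.to_numpy())[:max_errors]:
        errors.append(
            f"row {i}: count {counts.iloc[i]} is not a non-negative integer"
        )
    bad_al = ~df["alignment"].isin(["motion", "saccade"])
    for i in np.flatnonzero(bad_al.to_numpy())[:max_errors]:
        errors.append(
            f"row {i}: alignment {df['alignment'].iloc[i]!r} not in {{motion, saccade}}"
        )
    if (df["window_ms"] <= 0).any():
        errors.append("window_ms must be positive")
    return errors


def validate_file(path, kind: str | None = None) -> dict:
    """Validate a CSV file as a trial or spike table.

    ``kind`` is ``trials``, ``spikes``, or None to infer from the header.
    Returns {"ok": bool, "kind": str, "errors": [...]}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if kind is None:
        if set(TRIAL_COLUMNS) <= set(df.columns):
            kind = "trials"
        elif set(SPIKE_COLUMNS) <= set(df.columns):
            kind = "spikes"
        else:
            return {
                "ok": False,
                "kind": "unknown",
                "errors": [f"header matches neither trial nor spike schema: {list(df.columns)}"],
            }
    errors = validate_trials(df) if kind == "trials" else validate_spikes(df)
    return {"ok": not errors, "kind": kind, "errors": errors}
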