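"""Delimited-text readers and writers for the study tables.

All tables are UTF-8 comma-separated files with a header row.  The gaze
schema is the package's ingestion contract for externally collected data:

    participant_id, trial_id, phase, t_ms, x_px, y_px, live_feed

Readers validate the schema (missing columns raise an error naming the
column), reject malformed rows with their file line numbers, and verify
that timestamps strictly increase within each trial.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .dataset import GazeDataset, GAZE_COLUMNS, TRIAL_KEY

__all__ = [
    "read_gaze_table",
    "read_table",
    "write_dataset",
    "read_dataset",
    "SchemaError",
]

logger = logging.getLogger(__name__)

_GAZE_NUMERIC = ["participant_id", "trial_id", "t_ms", "x_px", "y_px"]

TRIAL_COLUMNS = [
    "participant_id", "trial_id", "condition", "is_calibration",
    "screen_w", "screen_h", "fix_x", "fix_y", "fix_start_ms", "fix_duration_ms",
    "stim_start_ms", "stim_end_ms", "true_midline_x", "true_midline_y",
    "response_time_ms", "chosen_label", "novel_label", "target_label",
    "target_onset_ms", "test_start_ms", "test_end_ms",
]
AOI_COLUMNS = ["participant_id", "trial_id", "label", "x_min", "x_max", "y_min", "y_max"]


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_gaze_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a gaze sample table.

    Rows with non-numeric coordinates or timestamps are dropped with a
    warning that lists their 1-based file line numbers.  Non-monotone
    timestamps within a trial raise :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, GAZE_COLUMNS, path)
    coerced = df.copy()
    for c in _GAZE_NUMERIC:
        coerced[c] = pd.to_numeric(coerced[c], errors="coerce")
    bad = coerced[_GAZE_NUMERIC].isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path, len(lines), lines[:20])
        coerced = coerced[~bad]
    coerced = coerced.reset_index(drop=True)
    coerced["participant_id"] = coerced["participant_id"].astype(int)
    coerced["trial_id"] = coerced["trial_id"].astype(int)
    coerced["live_feed"] = coerced["live_feed"].astype(bool)
    same = (
        coerced["participant_id"].eq(coerced["participant_id"].shift())
        & coerced["trial_id"].eq(coerced["trial_id"].shift())
    )
    nonmono = same & ~(coerced["t_ms"] > coerced["t_ms"].shift())
    if nonmono.any():
        raise SchemaError(
            f"{path}: non-monotone timestamps within a trial "
            f"(first at line {int(coerced.index[nonmono][0]) + 2})"
        )
    return coerced[GAZE_COLUMNS]


def read_table(path: Union[str, Path], required=None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if required:
        _require_columns(df, required, path)
    return df


def write_dataset(ds: GazeDataset, out_dir: Union[str, Path]) -> dict:
    """Write the dataset as delimited text: gaze, layout (trial metadata
    joined with AOI rectangles, one row per trial x AOI), truth, and
    participant auxiliary tables.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["gaze"] = out / "gaze.csv"
    ds.gaze.to_csv(paths["gaze"], index=False)
    trial_cols = [c for c in TRIAL_COLUMNS if c in ds.trials.columns]
    layout = ds.trials[trial_cols].merge(ds.aois, on=TRIAL_KEY, how="left")
    paths["layout"] = out / "layout.csv"
    layout.to_csv(paths["layout"], index=False)
    paths["truth"] = out / "truth.csv"
    ds.truth.to_csv(paths["truth"], index=False)
    paths["participants"] = out / "participants.csv"
    ds.participants.to_csv(paths["participants"], index=False)
    (out / "paradigm.txt").write_text(ds.paradigm + "\n")
    return paths


def read_dataset(in_dir: Union[str, Path], paradigm: Optional[str] = None) -> GazeDataset:
    """Re-load a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    if paradigm is None:
        marker = d / "paradigm.txt"
        if not marker.exists():
            raise SchemaError(f"{d}: paradigm not given and {marker} not found")
        paradigm = marker.read_text().strip()
    gaze = read_gaze_table(d / "gaze.csv")
    layout = read_table(d / "layout.csv", required=TRIAL_KEY + ["label"])
    aoi_cols = [c for c in AOI_COLUMNS if c in layout.columns]
    aois = layout[aoi_cols].dropna(subset=["label"]).reset_index(drop=True)
    trials = (
        layout.drop(columns=[c for c in AOI_COLUMNS if c not in TRIAL_KEY])
        .drop_duplicates(subset=TRIAL_KEY)
        .reset_index(drop=True)
    )
    truth_p = d / "truth.csv"
    truth = pd.read_csv(truth_p) if truth_p.exists() else pd.DataFrame()
    part_p = d / "participants.csv"
    participants = pd.read_csv(part_p) if part_p.exists() else pd.DataFrame()
    screen_w = float(trials["screen_w"].iloc[0]) if "screen_w" in trials else 1280.0
    screen_h = float(trials["screen_h"].iloc[0]) if "screen_h" in trials else 720.0
    ds = GazeDataset(
        paradigm=paradigm,
        gaze=gaze,
        trials=trials,
        aois=aois,
        truth=truth,
        participants=participants,
        screen_w=screen_w,
        screen_h=screen_h,
    )
    ds.validate()
    return ds
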