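"""In-memory container for a gaze study: sample, trial, AOI, and truth tables.

All tables are plain :class:`pandas.DataFrame` objects so that they can be
round-tripped through delimited text files without loss.  The container only
enforces the cross-table invariants (every gaze row has a trial row,
timestamps strictly increase within a trial, the truth table covers every
trial); column-level validation lives in :mod:`gazepipe.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pandas as pd

__all__ = ["GazeDataset", "ANALYSIS_PHASES", "GAZE_COLUMNS", "TRIAL_KEY"]

TRIAL_KEY = ["participant_id", "trial_id"]

GAZE_COLUMNS = ["participant_id", "trial_id", "phase", "t_ms", "x_px", "y_px", "live_feed"]

#: phases whose samples enter AOI-based analyses (everything except the
#: central fixation, the post-calibration fixation, and blank gaps)
ANALYSIS_PHASES = {
    "cascade": ("decision",),
    "novelty": ("familiarization", "test"),
    "vwp": ("images",),
}


@dataclass
class GazeDataset:
    """A full synthetic or imported study.

    Attributes
    ----------
    paradigm:
        One of ``"cascade"``, ``"novelty"``, ``"vwp"``.
    gaze:
        One row per estimated gaze sample (see :data:`GAZE_COLUMNS`).
    trials:
        One row per trial with screen geometry, fixation window, phase
        boundaries, true midlines and paradigm metadata.  Calibration
        fixations are stored as trials with ``is_calibration=True`` and are
        skipped by bias estimation, exclusion, and the paradigm analyses.
    aois:
        Long table, one row per (trial, AOI) rectangle.
    truth:
        Per-trial injected measurement bias and the participant's true
        preference parameter; empty for imported data.
    participants:
        Auxiliary per-participant fields used by the sensitivity filters
        (attention-check failures, instruction-screen time, self-reported
        reliability).
    """

    paradigm: str
    gaze: pd.DataFrame
    trials: pd.DataFrame
    aois: pd.DataFrame
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    participants: pd.DataFrame = field(default_factory=pd.DataFrame)
    screen_w: float = 1280
    screen_h: float = 720

    @property
    def analysis_phases(self) -> tuple[str, ...]:
        return ANALYSIS_PHASES[self.paradigm]

    @property
    def task_trials(self) -> pd.DataFrame:
        """Trial rows excluding calibration fixations."""
        if "is_calibration" in self.trials.columns:
            return self.trials[~self.trials["is_calibration"].astype(bool)]
        return self.trials

    def validate(self) -> None:
        """Raise ``ValueError`` on a violated cross-table invariant."""
        trial_idx = pd.MultiIndex.from_frame(self.trials[TRIAL_KEY])
        gaze_idx = pd.MultiIndex.from_frame(self.gaze[TRIAL_KEY].drop_duplicates())
        missing = gaze_idx.difference(trial_idx)
        if len(missing):
            raise ValueError(f"gaze rows without a trial row: {list(missing)[:5]}")
        # timestamps strictly increasing within each trial
        g = self.gaze
        same_trial = (
            g["participant_id"].eq(g["participant_id"].shift())
            & g["trial_id"].eq(g["trial_id"].shift())
        )
        bad = same_trial & ~(g["t_ms"] > g["t_ms"].shift())
        if bad.any():
            raise ValueError(
                f"non-increasing timestamps within a trial at rows {list(g.index[bad][:5])}"
            )
        if len(self.truth):
            truth_idx = pd.MultiIndex.from_frame(self.truth[TRIAL_KEY])
            task_idx = pd.MultiIndex.from_frame(self.task_trials[TRIAL_KEY])
            uncovered = task_idx.difference(truth_idx)
            if len(uncovered):
                raise ValueError(f"truth table does not cover trials: {list(uncovered)[:5]}")

    def copy(self) -> "GazeDataset":
        return GazeDataset(
            paradigm=self.paradigm,
            gaze=self.gaze.copy(),
            trials=self.trials.copy(),
            aois=self.aois.copy(),
            truth=self.truth.copy(),
            participants=self.participants.copy(),
            screen_w=self.screen_w,
            screen_h=self.screen_h,
        )
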