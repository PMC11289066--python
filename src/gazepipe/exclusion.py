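"""Preregistered-style exclusion cascades with auditable reports.

Exclusions run in three levels, strictly in order: participants, then
trials, then individual samples.  Within a level, rules are evaluated in a
fixed order and an excluded entity is annotated with the *first* rule that
fired.  "More than 50%" style thresholds are strict inequalities, so
boundary cases are retained.

The optional sensitivity filters mirror the hierarchical
stricter-exclusion analysis: attention-check failures, rushing through the
instruction screen, self-reported unreliable data, and live-webcam-feed
samples are added cumulatively on top of the base criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import TRIAL_KEY
from .preprocess import PreprocessedDataset

__all__ = [
    "ExclusionCriteria",
    "ExclusionReport",
    "SENSITIVITY_LEVELS",
    "flag_participants",
    "flag_trials",
    "filter_samples",
    "sensitivity_filter",
    "apply_exclusions",
]

SENSITIVITY_LEVELS = ("base", "attention", "instruction", "self_report", "live_feed")


@dataclass
class ExclusionCriteria:
    """Thresholds for the participant-, trial-, and sample-level rules.

    Trial-level midline limits are fractions of the screen extent.  In
    ``two_aoi`` mode a trial is excluded when the corrected midline
    deviates from the true midline by more than ``trial_midline_frac_x``
    of the screen width.  In ``four_aoi`` mode both axes are corrected and
    a trial is excluded when the vertical deviation exceeds
    ``trial_midline_frac_y_4aoi`` of the screen height *and* the
    horizontal deviation exceeds ``trial_midline_frac_x_4aoi`` of the
    screen width.
    """

    participant_max_off_aoi: float = 0.5
    participant_max_missing: float = 0.5
    trial_midline_frac_x: float = 0.25
    trial_midline_frac_y_4aoi: float = 0.25
    trial_midline_frac_x_4aoi: float = 0.375
    trial_sd_frac: float = 0.25
    rt_min_s: float = 0.5
    rt_max_s: float = 30.0
    attention_max_failures: int = 1
    instruction_min_s: float = 7.5
    self_report_unreliable: int = 1

    def __post_init__(self) -> None:
        for f in (
            self.participant_max_off_aoi,
            self.participant_max_missing,
            self.trial_midline_frac_x,
            self.trial_midline_frac_y_4aoi,
            self.trial_midline_frac_x_4aoi,
            self.trial_sd_frac,
        ):
            if not (0 < f <= 1):
                raise ValueError("fractions must be in (0, 1]")
        if not (self.rt_min_s < self.rt_max_s):
            raise ValueError("rt_min_s must be below rt_max_s")


@dataclass
class ExclusionReport:
    """Per-entity flags plus stage-by-stage retention counts."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    sample_counts: dict
    retention: pd.DataFrame

    def check_sums(self) -> None:
        for _, row in self.retention.iterrows():
            if row["n_retained"] + row["n_excluded"] != row["n_total"]:
                raise AssertionError(f"retention counts inconsistent at stage {row['stage']}")


def _analysis_gaze(pre: PreprocessedDataset) -> pd.DataFrame:
    phases = pre.dataset.analysis_phases
    return pre.gaze[pre.gaze["phase"].isin(phases)]


def flag_participants(
    pre: PreprocessedDataset, criteria: Optional[ExclusionCriteria] = None
) -> pd.DataFrame:
    """Participant-level rules, evaluated in order:

    1. ``no_gaze_variation`` — zero SD of both gaze coordinates across all
       task samples (a frozen estimator);
    2. ``no_response_variation`` — identical recorded response on every
       trial (only when the paradigm records responses);
    3. ``off_aoi`` — more than half of the stimulus-phase samples fall
       outside every AOI;
    4. ``missing`` — more than half of the expected trials have no data.
    """
    if criteria is None:
        criteria = ExclusionCriteria()
    if not len(pre.gaze):
        raise ValueError("empty dataset")
    task_trials = pre.dataset.task_trials
    pids = np.sort(task_trials["participant_id"].unique())

    task_gaze = pre.gaze.merge(task_trials[TRIAL_KEY], on=TRIAL_KEY, how="inner")
    gaze_sd = task_gaze.groupby("participant_id")[["x_px", "y_px"]].std(ddof=0)

    responses = task_trials.dropna(subset=["chosen_label"]) if "chosen_label" in task_trials else pd.DataFrame()
    resp_nunique = (
        responses.groupby("participant_id")["chosen_label"].agg(["nunique", "size"])
        if len(responses)
        else pd.DataFrame()
    )

    stim = _analysis_gaze(pre).merge(task_trials[TRIAL_KEY], on=TRIAL_KEY, how="inner")
    off_frac = stim.groupby("participant_id")["aoi"].apply(lambda s: float(s.isna().mean()))

    have = task_gaze[TRIAL_KEY].drop_duplicates().groupby("participant_id").size()
    expected = task_trials.groupby("participant_id").size()

    rows = []
    for pid in pids:
        rule = None
        sd = gaze_sd.loc[pid] if pid in gaze_sd.index else None
        if sd is not None and sd["x_px"] == 0.0 and sd["y_px"] == 0.0:
            rule = "no_gaze_variation"
        if rule is None and len(resp_nunique) and pid in resp_nunique.index:
            nun, cnt = resp_nunique.loc[pid, "nunique"], resp_nunique.loc[pid, "size"]
            if cnt > 1 and nun == 1:
                rule = "no_response_variation"
        frac_off = float(off_frac.get(pid, np.nan))
        if rule is None and np.isfinite(frac_off) and frac_off > criteria.participant_max_off_aoi:
            rule = "off_aoi"
        frac_missing = 1.0 - float(have.get(pid, 0)) / float(expected.get(pid, 1))
        if rule is None and frac_missing > criteria.participant_max_missing:
            rule = "missing"
        rows.append(
            {
                "participant_id": pid,
                "excluded": rule is not None,
                "rule": rule,
                "off_aoi_frac": frac_off,
                "missing_frac": frac_missing,
            }
        )
    return pd.DataFrame(rows)


def flag_trials(
    pre: PreprocessedDataset,
    criteria: Optional[ExclusionCriteria] = None,
    study_mode: str = "two_aoi",
) -> pd.DataFrame:
    """Trial-level rules, evaluated in order: missing bias estimate,
    corrected-midline deviation, midline dispersion, response-time bounds.

    The response-time rule only applies to trials that record a response
    time (the two-alternative choice paradigm).
    """
    if criteria is None:
        criteria = ExclusionCriteria()
    if study_mode not in ("two_aoi", "four_aoi"):
        raise ValueError("study_mode must be 'two_aoi' or 'four_aoi'")
    t = pre.trials
    t = t[~t["is_calibration"].astype(bool)].copy() if "is_calibration" in t else t.copy()

    dev_x = (t["corrected_midline_x"] - t["true_midline_x"]).abs()
    if "corrected_midline_y" in t:
        dev_y = (t["corrected_midline_y"] - t["true_midline_y"]).abs()
    else:
        dev_y = pd.Series(0.0, index=t.index)

    if study_mode == "two_aoi":
        midline_bad = dev_x > criteria.trial_midline_frac_x * t["screen_w"]
    else:
        midline_bad = (dev_y > criteria.trial_midline_frac_y_4aoi * t["screen_h"]) & (
            dev_x > criteria.trial_midline_frac_x_4aoi * t["screen_w"]
        )
    sd_bad = t["sd_x"].fillna(0.0) > criteria.trial_sd_frac * t["screen_w"]
    rt_s = t["response_time_ms"] / 1000.0
    rt_bad = rt_s.notna() & ((rt_s < criteria.rt_min_s) | (rt_s > criteria.rt_max_s))
    bias_missing = t["bias_missing"].astype(bool)

    rule = np.select(
        [bias_missing, midline_bad.fillna(False), sd_bad, rt_bad],
        ["no_bias_estimate", "midline_deviation", "midline_sd", "response_time"],
        default=None,
    )
    out = t[TRIAL_KEY].copy()
    out["excluded"] = rule != None  # noqa: E711
    out["rule"] = rule
    out["midline_dev_x"] = dev_x.to_numpy()
    out["midline_dev_y"] = dev_y.to_numpy()
    return out.reset_index(drop=True)


def filter_samples(
    gaze: pd.DataFrame, drop_live_feed: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Drop samples outside every AOI and, optionally, live-feed samples.

    Expects AOI-assigned gaze (an ``aoi`` column).  Returns the retained
    samples and a count dict with the fractions dropped per reason.  The
    live-feed rule is evaluated first so each dropped sample has a unique
    reason.
    """
    n_total = len(gaze)
    live = gaze["live_feed"].astype(bool) if drop_live_feed else pd.Series(False, index=gaze.index)
    off = gaze["aoi"].isna() & ~live
    keep = ~(off | live)
    counts = {
        "n_total": n_total,
        "n_live_feed": int(live.sum()),
        "n_off_aoi": int(off.sum()),
        "n_retained": int(keep.sum()),
        "frac_live_feed": float(live.sum() / n_total) if n_total else 0.0,
        "frac_off_aoi": float(off.sum() / n_total) if n_total else 0.0,
    }
    return gaze[keep], counts


def sensitivity_filter(
    pre: PreprocessedDataset,
    level: str = "base",
    criteria: Optional[ExclusionCriteria] = None,
) -> tuple[pd.DataFrame, bool, pd.DataFrame]:
    """Cumulative stricter participant filters up to ``level``.

    Levels, in hierarchical order: ``base`` (no extra rule),
    ``attention`` (more than ``attention_max_failures`` failed attention
    checks), ``instruction`` (instruction screen dismissed in under
    ``instruction_min_s`` seconds), ``self_report`` (participant rated
    their own data unreliable), ``live_feed`` (additionally drop
    live-feed-flagged samples).

    Returns ``(retained participant ids as a frame, drop_live_feed flag,
    per-level retention table)``.  Raises ``KeyError`` naming the missing
    auxiliary column if the requested level needs one that is absent.
    """
    if criteria is None:
        criteria = ExclusionCriteria()
    if level not in SENSITIVITY_LEVELS:
        raise ValueError(f"level must be one of {SENSITIVITY_LEVELS}")
    aux = pre.dataset.participants
    pids = np.sort(pre.dataset.task_trials["participant_id"].unique())
    retained = pd.Series(True, index=pids)
    needed = {
        "attention": "attention_failures",
        "instruction": "instruction_time_s",
        "self_report": "self_report",
    }
    rows = [{"level": "base", "n_participants": int(retained.sum())}]
    drop_live = False
    idx = SENSITIVITY_LEVELS.index(level)
    for lev in SENSITIVITY_LEVELS[1 : idx + 1]:
        if lev == "live_feed":
            drop_live = True
        else:
            colname = needed[lev]
            if colname not in aux.columns:
                raise KeyError(f"sensitivity level '{lev}' requires participant field '{colname}'")
            a = aux.set_index("participant_id")[colname].reindex(pids)
            if a.isna().any():
                raise KeyError(
                    f"sensitivity level '{lev}' requires participant field '{colname}' "
                    f"for all participants"
                )
            if lev == "attention":
                retained &= ~(a > criteria.attention_max_failures)
            elif lev == "instruction":
                retained &= ~(a < criteria.instruction_min_s)
            elif lev == "self_report":
                retained &= ~(a <= criteria.self_report_unreliable)
        rows.append({"level": lev, "n_participants": int(retained.sum())})
    kept = pd.DataFrame({"participant_id": retained.index[retained.to_numpy()]})
    return kept, drop_live, pd.DataFrame(rows)


def apply_exclusions(
    pre: PreprocessedDataset,
    criteria: Optional[ExclusionCriteria] = None,
    study_mode: str = "two_aoi",
    sensitivity_level: str = "base",
    drop_live_feed: Optional[bool] = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the full cascade and return analysis-ready gaze plus the report.

    The returned gaze contains only stimulus-phase samples of retained
    participants and trials, *including* off-AOI samples (the paradigm
    outcomes use in-AOI denominators and report the off-AOI fraction); the
    live-feed filter is applied here when requested.
    """
    if criteria is None:
        criteria = ExclusionCriteria()

    sens_kept, sens_live, sens_table = sensitivity_filter(pre, sensitivity_level, criteria)
    if drop_live_feed is None:
        drop_live_feed = sens_live

    pflags = flag_participants(pre, criteria)
    pflags = pflags.merge(sens_kept.assign(_sens=True), on="participant_id", how="left")
    sens_dropped = pflags["_sens"].isna() & ~pflags["excluded"]
    pflags.loc[sens_dropped, "excluded"] = True
    pflags.loc[sens_dropped, "rule"] = "sensitivity_" + sensitivity_level
    pflags = pflags.drop(columns=["_sens"])

    kept_pids = pflags.loc[~pflags["excluded"], "participant_id"]

    tflags = flag_trials(pre, criteria, study_mode)
    tflags = tflags[tflags["participant_id"].isin(kept_pids)]
    kept_trials = tflags.loc[~tflags["excluded"], TRIAL_KEY]

    stim = _analysis_gaze(pre)
    stim = stim.merge(kept_trials, on=TRIAL_KEY, how="inner")
    if drop_live_feed:
        live = stim["live_feed"].astype(bool)
        n_live = int(live.sum())
        stim = stim[~live]
    else:
        n_live = 0
    n_stim_total = len(stim) + n_live
    n_off = int(stim["aoi"].isna().sum())
    sample_counts = {
        "n_total": n_stim_total,
        "n_live_feed": n_live,
        "n_off_aoi": n_off,
        "n_retained": len(stim) - n_off,
        "frac_live_feed": n_live / n_stim_total if n_stim_total else 0.0,
        "frac_off_aoi": n_off / n_stim_total if n_stim_total else 0.0,
    }

    retention = pd.DataFrame(
        [
            {
                "stage": "participants",
                "n_total": len(pflags),
                "n_retained": int((~pflags["excluded"]).sum()),
                "n_excluded": int(pflags["excluded"].sum()),
            },
            {
                "stage": "trials",
                "n_total": len(tflags),
                "n_retained": int((~tflags["excluded"]).sum()),
                "n_excluded": int(tflags["excluded"].sum()),
            },
            {
                "stage": "samples",
                "n_total": n_stim_total,
                "n_retained": sample_counts["n_retained"],
                "n_excluded": n_live + n_off,
            },
        ]
    )
    report = ExclusionReport(
        participants=pflags,
        trials=tflags.reset_index(drop=True),
        sample_counts=sample_counts,
        retention=retention,
    )
    report.check_sums()
    return stim.reset_index(drop=True), report
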