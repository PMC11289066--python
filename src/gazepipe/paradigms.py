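"""Paradigm-specific viewing-proportion outcomes and time courses.

All outcomes are proportions of *in-AOI* samples: samples falling outside
every (corrected) AOI never enter the denominator, mirroring the
preregistered sample-level exclusion.  Trials with no in-AOI sample in the
analysis window yield a missing result; participants aggregate as the
unweighted mean of their retained trial proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import TRIAL_KEY
from . import stats as gstats

__all__ = [
    "TrialResult",
    "TimeCourse",
    "ConditionComparison",
    "cascade_proportion",
    "novelty_proportion",
    "vwp_proportion",
    "cascade_trial_results",
    "novelty_trial_results",
    "vwp_trial_results",
    "aggregate_participants",
    "decision_locked_timecourse",
    "stimulus_locked_timecourse",
    "compare_conditions",
    "plot_timecourse",
]


@dataclass
class TrialResult:
    """Viewing proportion for one trial within one analysis window."""

    participant_id: object
    trial_id: object
    proportion: float
    n_on_target: int
    n_in_aoi: int
    n_total: int
    window: tuple[float, float]


@dataclass
class TimeCourse:
    """Group-mean viewing proportion in contiguous time bins around a lock
    event (the response, or the target-word onset)."""

    bin_edges: np.ndarray  # len = n_bins + 1, ms relative to the lock event
    mean: np.ndarray
    sem: np.ndarray
    n_participants: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_ms": self.bin_edges[:-1],
                "bin_end_ms": self.bin_edges[1:],
                "mean_proportion": self.mean,
                "sem": self.sem,
                "n_participants": self.n_participants,
            }
        )


def _window_result(
    samples: pd.DataFrame,
    target_label: str,
    window: tuple[float, float],
    participant_id=None,
    trial_id=None,
) -> Optional[TrialResult]:
    lo, hi = window
    w = samples[(samples["t_ms"] >= lo) & (samples["t_ms"] < hi)]
    n_total = len(w)
    in_aoi = w[w["aoi"].notna()]
    n_in = len(in_aoi)
    if n_in == 0:
        return None
    n_on = int((in_aoi["aoi"] == target_label).sum())
    return TrialResult(
        participant_id=participant_id,
        trial_id=trial_id,
        proportion=n_on / n_in,
        n_on_target=n_on,
        n_in_aoi=n_in,
        n_total=n_total,
        window=(lo, hi),
    )


def cascade_proportion(
    samples: pd.DataFrame,
    chosen_label: str,
    response_abs_ms: float,
    window_ms: float = 100.0,
    participant_id=None,
    trial_id=None,
) -> Optional[TrialResult]:
    """Chosen-item proportion in the ``window_ms`` before the response.

    The window is ``[response - window_ms, response)``: right-open, so the
    sample coincident with the response is excluded.  Returns ``None``
    when no in-AOI sample falls inside the window.
    """
    return _window_result(
        samples, chosen_label, (response_abs_ms - window_ms, response_abs_ms),
        participant_id, trial_id,
    )


def novelty_proportion(
    samples: pd.DataFrame,
    novel_label: str,
    test_window: tuple[float, float],
    participant_id=None,
    trial_id=None,
) -> Optional[TrialResult]:
    """Novel-item proportion over the test phase."""
    return _window_result(samples, novel_label, test_window, participant_id, trial_id)


def vwp_proportion(
    samples: pd.DataFrame,
    target_label: str,
    labels: Sequence[str],
    window: tuple[float, float],
    participant_id=None,
    trial_id=None,
) -> Optional[tuple[TrialResult, dict]]:
    """Per-role proportions (target and each distractor) in the analysis
    window; the roles partition the in-AOI samples so they sum to 1."""
    res = _window_result(samples, target_label, window, participant_id, trial_id)
    if res is None:
        return None
    lo, hi = window
    w = samples[(samples["t_ms"] >= lo) & (samples["t_ms"] < hi)]
    in_aoi = w[w["aoi"].notna()]
    roles = {}
    for lab in labels:
        roles[lab] = float((in_aoi["aoi"] == lab).sum()) / len(in_aoi)
    return res, roles


# ---------------------------------------------------------------------------
# batch drivers (vectorised over trials)
# ---------------------------------------------------------------------------

def _batch_proportions(
    gaze: pd.DataFrame, trials: pd.DataFrame, target_col: str,
    lo: pd.Series, hi: pd.Series,
) -> pd.DataFrame:
    meta = trials[TRIAL_KEY + [target_col]].copy()
    meta["_lo"] = lo.to_numpy()
    meta["_hi"] = hi.to_numpy()
    g = gaze.merge(meta, on=TRIAL_KEY, how="inner")
    g = g[(g["t_ms"] >= g["_lo"]) & (g["t_ms"] < g["_hi"])]
    g["_in"] = g["aoi"].notna()
    g["_on"] = g["_in"] & (g["aoi"] == g[target_col])
    agg = g.groupby(TRIAL_KEY, sort=True).agg(
        n_total=("_in", "size"), n_in_aoi=("_in", "sum"), n_on_target=("_on", "sum")
    )
    agg = agg.reset_index()
    agg = meta[TRIAL_KEY + ["_lo", "_hi"]].merge(agg, on=TRIAL_KEY, how="left")
    agg[["n_total", "n_in_aoi", "n_on_target"]] = (
        agg[["n_total", "n_in_aoi", "n_on_target"]].fillna(0).astype(int)
    )
    agg["proportion"] = np.where(
        agg["n_in_aoi"] > 0, agg["n_on_target"] / agg["n_in_aoi"].replace(0, 1), np.nan
    )
    agg["missing"] = agg["n_in_aoi"] == 0
    return agg.rename(columns={"_lo": "window_start_ms", "_hi": "window_end_ms"})


def cascade_trial_results(
    gaze: pd.DataFrame, trials: pd.DataFrame, window_ms: float = 100.0
) -> pd.DataFrame:
    """Per-trial chosen-item proportions for every trial with a response."""
    t = trials.dropna(subset=["response_time_ms", "chosen_label"]).copy()
    resp_abs = t["stim_start_ms"] + t["response_time_ms"]
    return _batch_proportions(gaze, t, "chosen_label", resp_abs - window_ms, resp_abs)


def novelty_trial_results(gaze: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial novel-item proportions over the test phase."""
    t = trials.dropna(subset=["novel_label", "test_start_ms", "test_end_ms"]).copy()
    return _batch_proportions(gaze, t, "novel_label", t["test_start_ms"], t["test_end_ms"])


def vwp_trial_results(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    latency_ms: float = 200.0,
    window_ms: float = 400.0,
) -> pd.DataFrame:
    """Per-trial target proportions in the window starting ``latency_ms``
    after the target-word onset."""
    t = trials.dropna(subset=["target_label", "target_onset_ms"]).copy()
    lo = t["target_onset_ms"] + latency_ms
    out = _batch_proportions(gaze, t, "target_label", lo, lo + window_ms)
    out["distractor_proportion"] = np.where(
        out["n_in_aoi"] > 0, (1.0 - out["proportion"]) / 3.0, np.nan
    )
    if "condition" in trials.columns:
        out = out.merge(trials[TRIAL_KEY + ["condition"]], on=TRIAL_KEY, how="left")
    return out


def aggregate_participants(
    trial_results: pd.DataFrame, min_trials: int = 1
) -> pd.DataFrame:
    """Unweighted mean of trial proportions per participant.

    Trials with a missing proportion are skipped; participants with fewer
    than ``min_trials`` retained trials are dropped.  Trials are weighted
    equally regardless of how many samples each contributed.
    """
    tr = trial_results.dropna(subset=["proportion"])
    keys = ["participant_id"] + (["condition"] if "condition" in tr.columns else [])
    agg = tr.groupby(keys, sort=True).agg(
        mean_proportion=("proportion", "mean"),
        n_trials_retained=("proportion", "size"),
    ).reset_index()
    return agg[agg["n_trials_retained"] >= min_trials].reset_index(drop=True)


def _timecourse(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    target_col: str,
    lock: pd.Series,
    span: tuple[float, float],
    bin_ms: float,
) -> TimeCourse:
    """Shared binning: trial proportions per bin, averaged over trials
    within participants, then over participants."""
    lo, hi = span
    edges = np.arange(lo, hi + 0.5 * bin_ms, bin_ms)
    meta = trials[TRIAL_KEY + [target_col]].copy()
    meta["_lock"] = lock.to_numpy()
    g = gaze.merge(meta, on=TRIAL_KEY, how="inner")
    g = g[g["aoi"].notna()].copy()
    rel = g["t_ms"] - g["_lock"]
    g["_bin"] = np.floor((rel - lo) / bin_ms).astype(int)
    g = g[(g["_bin"] >= 0) & (g["_bin"] < len(edges) - 1)]
    g["_on"] = (g["aoi"] == g[target_col]).astype(float)
    per_trial = g.groupby(["participant_id", "trial_id", "_bin"], sort=True)["_on"].mean()
    per_part = per_trial.groupby(["participant_id", "_bin"]).mean()
    grp = per_part.groupby("_bin")
    mean = grp.mean()
    sem = grp.std(ddof=1) / np.sqrt(grp.size())
    nbins = len(edges) - 1
    idx = np.arange(nbins)
    return TimeCourse(
        bin_edges=edges,
        mean=mean.reindex(idx).to_numpy(),
        sem=sem.reindex(idx).to_numpy(),
        n_participants=grp.size().reindex(idx).fillna(0).to_numpy(dtype=int),
    )


def decision_locked_timecourse(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 100.0,
    span_ms: float = 2000.0,
) -> TimeCourse:
    """Chosen-item proportion in ``bin_ms`` bins over the ``span_ms``
    leading up to the response (time runs from -span_ms to 0)."""
    t = trials.dropna(subset=["response_time_ms", "chosen_label"]).copy()
    lock = t["stim_start_ms"] + t["response_time_ms"]
    return _timecourse(gaze, t, "chosen_label", lock, (-span_ms, 0.0), bin_ms)


def stimulus_locked_timecourse(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 100.0,
    pre_ms: float = 1000.0,
    post_ms: float = 2000.0,
) -> TimeCourse:
    """Target proportion in bins around the target-word onset."""
    t = trials.dropna(subset=["target_label", "target_onset_ms"]).copy()
    return _timecourse(
        gaze, t, "target_label", t["target_onset_ms"], (-pre_ms, post_ms), bin_ms
    )


@dataclass
class ConditionComparison:
    """Paired lab-vs-online contrast with an effect decomposition.

    ``numerator_ratio`` is (online mean - chance) / (lab mean - chance):
    how much of the above-chance signal the noisier condition retains.
    ``sd_ratio`` compares the between-participant dispersions
    (online / lab).  The test is one-sided for lab > online.
    """

    result: gstats.StatResult
    mean_online: float
    mean_lab: float
    sd_online: float
    sd_lab: float
    numerator_ratio: float
    sd_ratio: float
    n_pairs: int


def compare_conditions(
    online: pd.DataFrame,
    lab: pd.DataFrame,
    chance: float = 0.25,
    compute_bf: bool = True,
    rscale: float = 0.707,
) -> ConditionComparison:
    """Paired comparison of per-participant summaries across conditions.

    Both frames need ``participant_id`` and ``mean_proportion`` columns
    covering the same participants; unmatched ids raise ``ValueError``
    listing them.
    """
    on = online.set_index("participant_id")["mean_proportion"]
    lb = lab.set_index("participant_id")["mean_proportion"]
    only_on = sorted(set(on.index) - set(lb.index))
    only_lb = sorted(set(lb.index) - set(on.index))
    if only_on or only_lb:
        raise ValueError(
            f"unmatched participants: online-only {only_on}, lab-only {only_lb}"
        )
    on = on.sort_index()
    lb = lb.reindex(on.index)
    try:
        res = gstats.paired_t(
            lb.to_numpy(), on.to_numpy(), alternative="greater",
            compute_bf=compute_bf, rscale=rscale,
        )
    except ValueError:
        # a constant nonzero shift: the paired statistic diverges
        diff = lb.to_numpy() - on.to_numpy()
        sign = 1.0 if diff.mean() > 0 else -1.0
        res = gstats.StatResult(
            t=sign * float("inf"), df=on.size - 1, p=0.0 if sign > 0 else 1.0,
            d=sign * float("inf"), d_ci_lower=float("nan"), n=int(on.size),
            alternative="greater", mean=float(diff.mean()), sd=0.0, mu0=0.0,
            bf10=None,
        )
    mean_on, mean_lb = float(on.mean()), float(lb.mean())
    sd_on = float(on.std(ddof=1))
    sd_lb = float(lb.std(ddof=1))
    num_ratio = (
        (mean_on - chance) / (mean_lb - chance) if mean_lb != chance else float("nan")
    )
    sd_ratio = sd_on / sd_lb if sd_lb > 0 else float("nan")
    return ConditionComparison(
        result=res,
        mean_online=mean_on,
        mean_lab=mean_lb,
        sd_online=sd_on,
        sd_lab=sd_lb,
        numerator_ratio=num_ratio,
        sd_ratio=sd_ratio,
        n_pairs=int(on.size),
    )


def plot_timecourse(tc: TimeCourse, ax=None, chance: Optional[float] = None, label=None):
    """Minimal time-course plot: group mean with a +-1 SEM band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (tc.bin_edges[:-1] + tc.bin_edges[1:])
    ax.plot(centers, tc.mean, label=label)
    ax.fill_between(centers, tc.mean - tc.sem, tc.mean + tc.sem, alpha=0.3)
    if chance is not None:
        ax.axhline(chance, ls="--", c="gray", lw=1)
    ax.set_xlabel("time from lock event (ms)")
    ax.set_ylabel("viewing proportion")
    ax.set_ylim(0, 1)
    return ax
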