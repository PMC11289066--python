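"""Per-trial measurement-bias estimation and post-hoc geometry correction.

Webcam gaze estimates carry a large, slowly drifting spatial offset.  Rather
than discarding participants with poor validation accuracy, the offset is
estimated for every trial from the gaze recorded while the participant
fixates a central cross, and the *geometry* (midline and AOI bounds) of that
trial is shifted by the estimate.  Gaze samples themselves are never
modified.

The estimate uses the tailing portion of the fixation window (by time, last
80% by default) so that the initial saccade toward the cross does not enter
the average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import GazeDataset, TRIAL_KEY
from .geometry import AOI, TrialLayout

__all__ = [
    "BiasEstimate",
    "CorrectedGeometry",
    "PreprocessedDataset",
    "estimate_trial_bias",
    "correct_geometry",
    "correction_summary",
    "calibration_score",
    "calibration_scores",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasEstimate:
    """Per-trial measurement offset estimated from the fixation period.

    ``dy`` is zero in x-only mode.  ``sd_x`` is the within-trial standard
    deviation of the x positions of the fixation samples used; it
    operationalises the dispersion of the corrected midline for the
    trial-level exclusion rule.  An estimate with ``n_samples_used == 0`` is
    *missing*: its components are NaN and downstream correction falls back
    to the identity.
    """

    dx: float
    dy: float
    n_samples_used: int
    sd_x: float
    sd_y: float = float("nan")

    @property
    def missing(self) -> bool:
        return self.n_samples_used < 1

    @staticmethod
    def missing_estimate() -> "BiasEstimate":
        nan = float("nan")
        return BiasEstimate(dx=nan, dy=nan, n_samples_used=0, sd_x=nan, sd_y=nan)


@dataclass
class CorrectedGeometry:
    """Trial geometry after adding the estimated bias to every bound.

    Invariant: ``corrected bound - original bound == applied bias`` exactly,
    per axis.  ``identity`` marks the fallback used when the bias estimate
    was missing.
    """

    aois: list[AOI]
    corrected_midline_x: float
    corrected_midline_y: Optional[float]
    applied_bias: BiasEstimate
    identity: bool = False

    def aoi(self, label: str) -> AOI:
        for a in self.aois:
            if a.label == label:
                return a
        raise KeyError(label)


def _as_sample_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        return (
            samples["t_ms"].to_numpy(dtype=float),
            samples["x_px"].to_numpy(dtype=float),
            samples["y_px"].to_numpy(dtype=float),
        )
    t, x, y = samples
    return np.asarray(t, float), np.asarray(x, float), np.asarray(y, float)


def estimate_trial_bias(
    samples,
    layout: TrialLayout,
    tail_fraction: float = 0.8,
    axes: str = "x",
    statistic: str = "mean",
) -> BiasEstimate:
    """Estimate the trial's measurement bias from its fixation period.

    Parameters
    ----------
    samples:
        Fixation-phase gaze samples: a DataFrame with ``t_ms, x_px, y_px``
        columns or a ``(t, x, y)`` triple of arrays.
    layout:
        Provides the fixation point and the fixation window.
    tail_fraction:
        Fraction of the fixation window, taken from its end *by time*, whose
        samples enter the estimate.  A sample is kept when
        ``t >= fix_start + (1 - tail_fraction) * duration``.
    axes:
        ``"x"`` estimates the horizontal component only (``dy = 0``);
        ``"xy"`` estimates both.
    statistic:
        ``"mean"`` (default) or ``"median"`` of the kept samples.

    Returns a missing estimate (never raises) when no sample falls in the
    tail window.
    """
    if not (0 < tail_fraction <= 1):
        raise ValueError("tail_fraction must be in (0, 1]")
    if axes not in ("x", "xy"):
        raise ValueError("axes must be 'x' or 'xy'")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    t, x, y = _as_sample_arrays(samples)
    t0 = layout.fix_start_ms + (1.0 - tail_fraction) * layout.fixation_duration_ms
    keep = t >= t0
    n = int(keep.sum())
    if n == 0:
        return BiasEstimate.missing_estimate()
    xs, ys = x[keep], y[keep]
    agg = np.mean if statistic == "mean" else np.median
    fx, fy = layout.fixation_point
    dx = float(agg(xs)) - fx
    dy = (float(agg(ys)) - fy) if axes == "xy" else 0.0
    sd_x = float(np.std(xs, ddof=1)) if n > 1 else 0.0
    sd_y = float(np.std(ys, ddof=1)) if n > 1 else 0.0
    return BiasEstimate(dx=dx, dy=dy, n_samples_used=n, sd_x=sd_x, sd_y=sd_y)


def correct_geometry(layout: TrialLayout, bias: BiasEstimate) -> CorrectedGeometry:
    """Shift the trial's midline(s) and AOI bounds by the estimated bias.

    A missing bias yields the identity geometry with a logged warning; the
    trial is flagged via ``CorrectedGeometry.identity`` rather than crashed.
    """
    if bias is None or bias.missing:
        logger.warning("missing bias estimate: applying identity geometry")
        return CorrectedGeometry(
            aois=list(layout.aois),
            corrected_midline_x=layout.true_midline_x,
            corrected_midline_y=layout.true_midline_y,
            applied_bias=BiasEstimate.missing_estimate(),
            identity=True,
        )
    dy = bias.dy if np.isfinite(bias.dy) else 0.0
    return CorrectedGeometry(
        aois=[a.shifted(bias.dx, dy) for a in layout.aois],
        corrected_midline_x=layout.true_midline_x + bias.dx,
        corrected_midline_y=(
            layout.true_midline_y + dy if layout.true_midline_y is not None else None
        ),
        applied_bias=bias,
    )


def correction_summary(biases) -> pd.DataFrame:
    """Absolute-magnitude summary of applied corrections, per axis.

    Accepts a sequence of :class:`BiasEstimate` or a DataFrame with
    ``dx``/``dy`` columns; missing estimates are ignored.  Returns a frame
    indexed by axis with columns ``mean, median, min, max, n``.
    """
    if isinstance(biases, pd.DataFrame):
        df = biases
    else:
        biases = list(biases)
        df = pd.DataFrame(
            {
                "dx": [b.dx for b in biases],
                "dy": [b.dy for b in biases],
            }
        )
    rows = {}
    for axis in ("dx", "dy"):
        v = df[axis].to_numpy(dtype=float) if axis in df.columns else np.array([])
        v = np.abs(v[np.isfinite(v)])
        if v.size == 0:
            continue
        rows[axis[1]] = {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
            "n": int(v.size),
        }
    if not rows:
        raise ValueError("no valid bias estimates to summarise")
    return pd.DataFrame(rows).T


def calibration_score(
    samples,
    center_region: Optional[AOI] = None,
    screen_w: float = 1280,
    screen_h: float = 720,
    half_width_px: float = 200.0,
) -> float:
    """Fraction of post-calibration fixation samples inside the centre region.

    The region defaults to a square of ``half_width_px`` half-width around
    the screen centre (the boundary of what counts as "on the centre" is a
    configuration choice, not something the score itself fixes).  Returns
    NaN when there are no samples.
    """
    t, x, y = _as_sample_arrays(samples)
    if x.size == 0:
        return float("nan")
    if center_region is None:
        cx, cy = screen_w / 2, screen_h / 2
        center_region = AOI(
            "center", cx - half_width_px, cx + half_width_px,
            cy - half_width_px, cy + half_width_px,
        )
    inside = (
        (x >= center_region.x_min)
        & (x < center_region.x_max)
        & (y >= center_region.y_min)
        & (y < center_region.y_max)
    )
    return float(inside.mean())


def calibration_scores(ds: GazeDataset, half_width_px: float = 200.0) -> pd.DataFrame:
    """Per-participant (and per-condition) calibration scores for a dataset.

    Uses the gaze recorded during the dedicated post-calibration fixation
    trials (``phase == "calibration"``).
    """
    cal = ds.gaze[ds.gaze["phase"] == "calibration"]
    if not len(cal):
        return pd.DataFrame(columns=["participant_id", "condition", "calibration_score"])
    cal = cal.merge(
        ds.trials[TRIAL_KEY + ["condition"]], on=TRIAL_KEY, how="left"
    )
    out = []
    for (pid, cond), grp in cal.groupby(["participant_id", "condition"], sort=True):
        score = calibration_score(
            grp, screen_w=ds.screen_w, screen_h=ds.screen_h, half_width_px=half_width_px
        )
        out.append({"participant_id": pid, "condition": cond, "calibration_score": score})
    return pd.DataFrame(out)


@dataclass
class PreprocessedDataset:
    """A dataset with per-trial bias estimates, corrected geometry, and AOI
    assignments attached.

    ``gaze`` carries an extra ``aoi`` column (NaN when the sample falls
    outside every corrected AOI).  ``trials`` carries ``dx, dy,
    corrected_midline_x, corrected_midline_y, sd_x, bias_missing``.
    """

    dataset: GazeDataset
    axes: str
    tail_fraction: float
    gaze: pd.DataFrame
    trials: pd.DataFrame
    aois: pd.DataFrame  # corrected bounds, original kept as *_orig
    biases: pd.DataFrame

    @property
    def paradigm(self) -> str:
        return self.dataset.paradigm

    @property
    def screen_w(self) -> float:
        return self.dataset.screen_w

    @property
    def screen_h(self) -> float:
        return self.dataset.screen_h


def preprocess_dataset(
    ds: GazeDataset,
    tail_fraction: float = 0.8,
    axes: str = "x",
    statistic: str = "mean",
) -> PreprocessedDataset:
    """Estimate biases, correct geometry, and assign AOIs for a whole study.

    Vectorised equivalent of running :func:`estimate_trial_bias`,
    :func:`correct_geometry`, and per-sample hit-testing trial by trial.
    Calibration-fixation trials get identity geometry and are not given a
    bias estimate.
    """
    if not (0 < tail_fraction <= 1):
        raise ValueError("tail_fraction must be in (0, 1]")
    if axes not in ("x", "xy"):
        raise ValueError("axes must be 'x' or 'xy'")

    trials = ds.trials.copy()
    gaze = ds.gaze

    # --- bias estimation from the tail of each fixation window ------------
    fix = gaze[gaze["phase"] == "fixation"]
    fix = fix.merge(
        trials[TRIAL_KEY + ["fix_start_ms", "fix_duration_ms", "fix_x", "fix_y"]],
        on=TRIAL_KEY,
        how="inner",
    )
    t0 = fix["fix_start_ms"] + (1.0 - tail_fraction) * fix["fix_duration_ms"]
    tail = fix[fix["t_ms"] >= t0]
    agg = "median" if statistic == "median" else "mean"
    grp = tail.groupby(TRIAL_KEY, sort=False)
    est = grp.agg(
        _mx=("x_px", agg),
        _my=("y_px", agg),
        sd_x=("x_px", "std"),
        sd_y=("y_px", "std"),
        n_samples_used=("x_px", "size"),
    ).reset_index()
    est = est.merge(tail[TRIAL_KEY + ["fix_x", "fix_y"]].drop_duplicates(), on=TRIAL_KEY)
    est["dx"] = est["_mx"] - est["fix_x"]
    est["dy"] = (est["_my"] - est["fix_y"]) if axes == "xy" else 0.0
    est.loc[est["n_samples_used"] == 1, ["sd_x", "sd_y"]] = 0.0
    biases = est[TRIAL_KEY + ["dx", "dy", "sd_x", "sd_y", "n_samples_used"]]

    trials = trials.merge(biases, on=TRIAL_KEY, how="left")
    is_cal = trials["is_calibration"].astype(bool) if "is_calibration" in trials else False
    trials["bias_missing"] = trials["dx"].isna() & ~is_cal
    n_missing = int(trials["bias_missing"].sum())
    if n_missing:
        logger.warning("%d trials have no fixation samples in the tail window", n_missing)
    # identity fallback for missing estimates and calibration trials
    applied_dx = trials["dx"].fillna(0.0)
    applied_dy = trials["dy"].fillna(0.0)
    if isinstance(is_cal, pd.Series):
        applied_dx = applied_dx.where(~is_cal, 0.0)
        applied_dy = applied_dy.where(~is_cal, 0.0)
    trials["applied_dx"] = applied_dx
    trials["applied_dy"] = applied_dy
    trials["corrected_midline_x"] = trials["true_midline_x"] + applied_dx
    if "true_midline_y" in trials.columns:
        trials["corrected_midline_y"] = trials["true_midline_y"] + applied_dy

    # --- geometry correction ---------------------------------------------
    aois = ds.aois.copy()
    aois = aois.merge(trials[TRIAL_KEY + ["applied_dx", "applied_dy"]], on=TRIAL_KEY, how="left")
    for c in ("x_min", "x_max", "y_min", "y_max"):
        aois[f"{c}_orig"] = aois[c]
    aois["x_min"] = aois["x_min_orig"] + aois["applied_dx"]
    aois["x_max"] = aois["x_max_orig"] + aois["applied_dx"]
    aois["y_min"] = aois["y_min_orig"] + aois["applied_dy"]
    aois["y_max"] = aois["y_max_orig"] + aois["applied_dy"]

    # --- AOI assignment against corrected geometry ------------------------
    gaze = gaze.copy()
    gaze["aoi"] = _assign_batch(gaze, aois)

    bias_cols = TRIAL_KEY + ["dx", "dy", "sd_x", "sd_y", "n_samples_used"]
    return PreprocessedDataset(
        dataset=ds,
        axes=axes,
        tail_fraction=tail_fraction,
        gaze=gaze,
        trials=trials,
        aois=aois.drop(columns=["applied_dx", "applied_dy"]),
        biases=trials.loc[~trials["dx"].isna(), bias_cols].reset_index(drop=True),
    )


def _assign_batch(gaze: pd.DataFrame, aois: pd.DataFrame) -> pd.Series:
    """Half-open hit-test of every sample against its trial's (corrected) AOIs."""
    out = pd.Series(np.full(len(gaze), None, dtype=object), index=gaze.index)
    bounds = aois[TRIAL_KEY + ["label", "x_min", "x_max", "y_min", "y_max"]]
    for label, sub in bounds.groupby("label", sort=True):
        merged = gaze[TRIAL_KEY + ["x_px", "y_px"]].merge(
            sub, on=TRIAL_KEY, how="left", sort=False
        )
        hit = (
            (merged["x_px"] >= merged["x_min"])
            & (merged["x_px"] < merged["x_max"])
            & (merged["y_px"] >= merged["y_min"])
            & (merged["y_px"] < merged["y_max"])
        ).to_numpy()
        out[hit & out.isna().to_numpy()] = label
    return out
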