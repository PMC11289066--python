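"""Synthetic webcam-grade gaze data with known ground truth.

The generators emulate the statistical structure of browser-based gaze
estimation: a large, per-trial constant spatial offset (participant drift
plus trial-to-trial perturbation), high per-sample isotropic noise,
irregular ~30 Hz sampling, a configurable fraction of samples that land
anywhere on the screen regardless of the looking process, and a paired
low-noise "lab" condition sampled regularly at high rate.

Each paradigm adds its own preference process on top:

* two-alternative choice ("cascade"): during the decision phase the
  probability of aiming at the eventually chosen image ramps linearly from
  0.5 to the participant's ``p_final`` at the moment of response;
* preferential looking ("novelty"): test-phase samples aim at the novel
  image with probability ``p_novel``;
* four-quadrant spoken-word display ("vwp"): target-looking probability
  ramps from 0.25 to ``p_target`` right after the target-word onset.

Aim points are drawn uniformly from the central portion of the intended
image so that, before offset and noise, every process sample lies inside an
AOI.  All randomness flows through one :class:`numpy.random.Generator`
seeded from the config, so identical configs produce bit-identical
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import GazeDataset
from .geometry import (
    AOI,
    CASCADE_IMAGE_PX,
    NOVELTY_IMAGE_PX,
    VWP_IMAGE_PX,
    quadrant_aois,
    side_by_side_aois,
)

__all__ = [
    "OffsetSpec",
    "LabSpec",
    "SimulationConfig",
    "sample_gaze_stream",
    "simulate_cascade_study",
    "simulate_novelty_study",
    "simulate_vwp_study",
    "simulate_study",
]

#: paradigm-specific defaults: trial counts and the preference process
_PARADIGM_TRIALS = {"cascade": 18, "novelty": 10, "vwp": 12}
_PREFERENCE_DEFAULTS = {
    "cascade": {
        "p_final": 0.62,
        "participant_sd": 0.15,
        "ramp_ms": 1500.0,
        "rt_median_s": 2.5,
        "rt_sigma": 0.45,
    },
    "novelty": {"p_novel": 0.57, "participant_sd": 0.15, "randomize_side": True},
    "vwp": {
        "p_target_online": 0.52,
        "p_target_lab": 0.71,
        "participant_sd": 0.12,
        "block_sd": 0.08,
        "ramp_ms": 200.0,
    },
}
#: fraction of stimulus-phase samples replaced by uniform screen positions,
#: calibrated together with the noise SD so that the simulated off-AOI
#: exclusion fractions land in the range reported for webcam studies
_OFF_AOI_DEFAULTS = {"cascade": 0.02, "novelty": 0.12, "vwp": 0.15}


@dataclass
class OffsetSpec:
    """Gaussian decomposition of the per-trial constant measurement offset.

    Each axis of a trial's offset is ``N(0, participant_sd) +
    N(0, trial_sd)`` with the first draw shared by all of a participant's
    trials.  The defaults give a mean absolute x-offset of about 120 px,
    the order of magnitude reported for uncorrected webcam gaze.
    ``y_scale`` multiplies both SDs on the vertical axis: the side-by-side
    paradigms only correct the horizontal axis, and their observed off-AOI
    fractions are only compatible with a vertical drift markedly smaller
    than the horizontal one.
    """

    participant_sd_px: float = 120.0
    trial_sd_px: float = 90.0
    y_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.participant_sd_px < 0 or self.trial_sd_px < 0:
            raise ValueError("offset SDs must be non-negative")
        if self.y_scale < 0:
            raise ValueError("y_scale must be non-negative")


@dataclass
class LabSpec:
    """Overrides applied to the laboratory block of the paired design."""

    sampling_rate_hz: float = 250.0
    jitter_frac: float = 0.0
    noise_sd_px: float = 20.0
    offset: OffsetSpec = field(default_factory=lambda: OffsetSpec(8.0, 4.0))
    off_aoi_rate: float = 0.005


_OFFSET_DEFAULTS = {
    "cascade": OffsetSpec(120.0, 90.0, y_scale=0.3),
    "novelty": OffsetSpec(120.0, 90.0, y_scale=0.3),
    "vwp": OffsetSpec(120.0, 90.0, y_scale=1.0),
}


@dataclass
class SimulationConfig:
    """Parameters shared by the three study generators.

    ``n_trials`` and ``off_aoi_rate`` default to paradigm-specific values
    when left at ``None``.  ``preference`` holds the paradigm-specific
    process parameters and is merged over the per-paradigm defaults.
    """

    n_participants: int = 45
    n_trials: Optional[int] = None
    sampling_rate_hz: float = 30.0
    jitter_frac: float = 0.2
    noise_sd_px: float = 25.0
    offset: Optional[OffsetSpec] = None
    off_aoi_rate: Optional[float] = None
    live_feed_rate: float = 0.0
    preference: dict = field(default_factory=dict)
    seed: int = 0
    screen_w: int = 1280
    screen_h: int = 720
    fixation_ms: float = 2000.0
    calibration_ms: float = 3000.0
    aim_margin: float = 0.30
    lab: LabSpec = field(default_factory=LabSpec)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_trials is not None and self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not (0 <= self.jitter_frac < 1):
            raise ValueError("jitter_frac must be in [0, 1)")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        for rate in (self.off_aoi_rate, self.live_feed_rate):
            if rate is not None and not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if not (0 <= self.aim_margin < 0.5):
            raise ValueError("aim_margin must be in [0, 0.5)")

    def resolved(self, paradigm: str) -> tuple[int, float, dict, OffsetSpec]:
        """(n_trials, off_aoi_rate, preference, offset) with paradigm defaults
        filled in for the fields left at ``None``."""
        n_trials = self.n_trials if self.n_trials is not None else _PARADIGM_TRIALS[paradigm]
        off = self.off_aoi_rate if self.off_aoi_rate is not None else _OFF_AOI_DEFAULTS[paradigm]
        pref = dict(_PREFERENCE_DEFAULTS[paradigm])
        unknown = set(self.preference) - set(pref)
        if unknown:
            raise ValueError(f"unknown preference parameters for {paradigm}: {sorted(unknown)}")
        pref.update(self.preference)
        offset = self.offset if self.offset is not None else _OFFSET_DEFAULTS[paradigm]
        return n_trials, off, pref, offset


# ---------------------------------------------------------------------------
# sampling engine
# ---------------------------------------------------------------------------

def _sample_times(
    duration_ms: float, rate_hz: float, jitter_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Strictly increasing sample times in [0, duration) at the nominal rate
    with multiplicative inter-sample jitter."""
    dt = 1000.0 / rate_hz
    n_est = int(duration_ms / dt * (1.0 + jitter_frac)) + 4
    if jitter_frac > 0:
        intervals = dt * (1.0 + rng.uniform(-jitter_frac, jitter_frac, n_est))
    else:
        intervals = np.full(n_est, dt)
    t = np.concatenate(([0.0], np.cumsum(intervals)))
    return t[t < duration_ms]


def _uniform_off_aoi(
    m: int, screen_w: float, screen_h: float, aois, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform screen positions outside every AOI (rejection sampling).

    The off-AOI process models tracking loss and stimulus-independent
    wandering; drawing its positions outside the AOI rectangles keeps it
    from leaking into the in-AOI denominators of the analyses.
    """
    x = rng.uniform(0.0, screen_w, m)
    y = rng.uniform(0.0, screen_h, m)
    if aois:
        for _ in range(1000):
            inside = np.zeros(m, dtype=bool)
            for a in aois:
                inside |= (x >= a.x_min) & (x < a.x_max) & (y >= a.y_min) & (y < a.y_max)
            k = int(inside.sum())
            if not k:
                break
            x[inside] = rng.uniform(0.0, screen_w, k)
            y[inside] = rng.uniform(0.0, screen_h, k)
    return x, y


def _emit(
    times: np.ndarray,
    tx: np.ndarray,
    ty: np.ndarray,
    bias: tuple[float, float],
    noise_sd: float,
    off_aoi_rate: float,
    live_feed_rate: float,
    screen_w: float,
    screen_h: float,
    rng: np.random.Generator,
    off_eligible: Optional[np.ndarray] = None,
    aois=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn per-sample aim points into measured gaze: add the trial offset
    and Gaussian noise, replace the off-AOI fraction with uniform
    outside-AOI screen positions, and set the live-feed flag."""
    n = times.size
    x = tx + bias[0]
    y = ty + bias[1]
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(2, n))
        x = x + noise[0]
        y = y + noise[1]
    else:
        x = x.astype(float, copy=True)
        y = y.astype(float, copy=True)
    if off_aoi_rate > 0:
        off = rng.random(n) < off_aoi_rate
        if off_eligible is not None:
            off &= off_eligible
        m = int(off.sum())
        if m:
            x[off], y[off] = _uniform_off_aoi(m, screen_w, screen_h, aois, rng)
    live = (
        rng.random(n) < live_feed_rate
        if live_feed_rate > 0
        else np.zeros(n, dtype=bool)
    )
    return x, y, live


def sample_gaze_stream(
    path,
    duration_ms: float,
    config: SimulationConfig,
    trial_bias: tuple[float, float] = (0.0, 0.0),
    rng: Optional[np.random.Generator] = None,
    off_eligible: bool = True,
) -> pd.DataFrame:
    """Sample a measured gaze stream along a piecewise-constant target path.

    ``path`` is an array-like of ``(t_ms, x, y)`` rows giving the target
    position from time ``t_ms`` onward (the first row must start at or
    before 0).  Samples are drawn at the config's nominal rate with
    multiplicative timing jitter; each measured point is target + trial
    offset + isotropic Gaussian noise, a fraction ``off_aoi_rate`` is
    replaced by uniform screen positions, and ``live_feed_rate`` of samples
    are flagged as lost.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 3:
        raise ValueError("path must be an (n, 3) array of (t_ms, x, y)")
    if path[0, 0] > 0:
        raise ValueError("path must cover the trial from t=0")
    times = _sample_times(duration_ms, config.sampling_rate_hz, config.jitter_frac, rng)
    idx = np.searchsorted(path[:, 0], times, side="right") - 1
    tx, ty = path[idx, 1], path[idx, 2]
    off_rate = config.off_aoi_rate if config.off_aoi_rate is not None else 0.0
    x, y, live = _emit(
        times, tx, ty, trial_bias, config.noise_sd_px, off_rate,
        config.live_feed_rate, config.screen_w, config.screen_h, rng,
        off_eligible=None if off_eligible else np.zeros(times.size, bool),
    )
    return pd.DataFrame({"t_ms": times, "x_px": x, "y_px": y, "live_feed": live})


def _aim_uniform(aoi: AOI, n: int, margin: float, rng: np.random.Generator):
    box = aoi.inner_box(margin) if margin > 0 else aoi
    return (
        rng.uniform(box.x_min, box.x_max, n),
        rng.uniform(box.y_min, box.y_max, n),
    )


def _clip_unit(p: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    return np.clip(p, lo, hi)


# ---------------------------------------------------------------------------
# study assembly helpers
# ---------------------------------------------------------------------------

_TRIAL_DEFAULTS = {
    "condition": "online",
    "is_calibration": False,
    "fix_start_ms": 0.0,
    "response_time_ms": np.nan,
    "chosen_label": None,
    "novel_label": None,
    "target_label": None,
    "target_onset_ms": np.nan,
    "test_start_ms": np.nan,
    "test_end_ms": np.nan,
}


def _trial_row(cfg: SimulationConfig, pid: int, tid: int, **kw) -> dict:
    row = {
        "participant_id": pid,
        "trial_id": tid,
        "screen_w": cfg.screen_w,
        "screen_h": cfg.screen_h,
        "fix_x": cfg.screen_w / 2,
        "fix_y": cfg.screen_h / 2,
        "fix_duration_ms": cfg.fixation_ms,
        "true_midline_x": cfg.screen_w / 2,
        "true_midline_y": cfg.screen_h / 2,
        **_TRIAL_DEFAULTS,
    }
    row.update(kw)
    return row


class _Collector:
    """Accumulates per-trial sample arrays and row dicts, builds the tables."""

    def __init__(self) -> None:
        self.gaze_parts: list[dict] = []
        self.trial_rows: list[dict] = []
        self.aoi_rows: list[dict] = []
        self.truth_rows: list[dict] = []

    def add_gaze(self, pid, tid, phase, t, x, y, live) -> None:
        self.gaze_parts.append(
            {
                "participant_id": np.full(t.size, pid, dtype=int),
                "trial_id": np.full(t.size, tid, dtype=int),
                "phase": phase if isinstance(phase, np.ndarray) else np.full(t.size, phase),
                "t_ms": t,
                "x_px": x,
                "y_px": y,
                "live_feed": live,
            }
        )

    def add_aois(self, pid, tid, aois: Sequence[AOI]) -> None:
        for a in aois:
            self.aoi_rows.append(
                {
                    "participant_id": pid,
                    "trial_id": tid,
                    "label": a.label,
                    "x_min": a.x_min,
                    "x_max": a.x_max,
                    "y_min": a.y_min,
                    "y_max": a.y_max,
                }
            )

    def build(self, paradigm, cfg, participants: pd.DataFrame) -> GazeDataset:
        gaze = pd.DataFrame(
            {
                col: np.concatenate([p[col] for p in self.gaze_parts])
                for col in ("participant_id", "trial_id", "phase", "t_ms", "x_px", "y_px", "live_feed")
            }
        )
        ds = GazeDataset(
            paradigm=paradigm,
            gaze=gaze,
            trials=pd.DataFrame(self.trial_rows),
            aois=pd.DataFrame(self.aoi_rows),
            truth=pd.DataFrame(self.truth_rows),
            participants=participants,
            screen_w=cfg.screen_w,
            screen_h=cfg.screen_h,
        )
        ds.validate()
        return ds


def _default_participants(n: int) -> pd.DataFrame:
    """Auxiliary fields consumed by the sensitivity filters; a clean cohort."""
    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "attention_failures": 0,
            "instruction_time_s": 30.0,
            "self_report": 5,
        }
    )


def _add_calibration_trial(
    col: _Collector, cfg: SimulationConfig, pid: int, tid: int, bias, rng,
    rate_hz: float, jitter: float, noise_sd: float, condition: str,
) -> None:
    times = _sample_times(cfg.calibration_ms, rate_hz, jitter, rng)
    cx, cy = cfg.screen_w / 2, cfg.screen_h / 2
    x, y, live = _emit(
        times, np.full(times.size, cx), np.full(times.size, cy), bias,
        noise_sd, 0.0, cfg.live_feed_rate, cfg.screen_w, cfg.screen_h, rng,
    )
    col.add_gaze(pid, tid, "calibration", times, x, y, live)
    col.trial_rows.append(
        _trial_row(
            cfg, pid, tid, condition=condition, is_calibration=True,
            fix_duration_ms=cfg.calibration_ms,
        )
    )


def _participant_bias(rng, spec: OffsetSpec) -> np.ndarray:
    sd = np.array([spec.participant_sd_px, spec.participant_sd_px * spec.y_scale])
    return rng.normal(0.0, 1.0, 2) * sd


def _draw_bias(rng, part_bias: np.ndarray, spec: OffsetSpec) -> np.ndarray:
    sd = np.array([spec.trial_sd_px, spec.trial_sd_px * spec.y_scale])
    return part_bias + rng.normal(0.0, 1.0, 2) * sd


# ---------------------------------------------------------------------------
# paradigm generators
# ---------------------------------------------------------------------------

def simulate_cascade_study(config: SimulationConfig) -> GazeDataset:
    """Two-alternative forced-choice study with a pre-decision gaze ramp.

    Every trial is a 2000-ms central fixation followed by a decision phase
    whose duration is a log-normal response time.  During the decision
    phase the probability of aiming at the eventually chosen image rises
    linearly from 0.5, starting ``ramp_ms`` before the response, to the
    participant's ``p_final`` at the response.  ``ramp_ms = 0`` means the
    probability is ``p_final`` throughout the decision phase.
    """
    n_trials, off_rate, pref, offset_spec = config.resolved("cascade")
    p_final = float(pref["p_final"])
    if not (0.5 <= p_final <= 1.0):
        raise ValueError("p_final must be in [0.5, 1]")
    rng = np.random.default_rng(config.seed)
    aois = side_by_side_aois(*CASCADE_IMAGE_PX, screen_w=config.screen_w, screen_h=config.screen_h)
    by_label = {a.label: a for a in aois}
    col = _Collector()
    fix_ms = config.fixation_ms
    cx, cy = config.screen_w / 2, config.screen_h / 2

    for pid in range(1, config.n_participants + 1):
        part_bias = _participant_bias(rng, offset_spec)
        p_i = float(_clip_unit(rng.normal(p_final, pref["participant_sd"])))
        _add_calibration_trial(
            col, config, pid, 0, _draw_bias(rng, part_bias, offset_spec), rng,
            config.sampling_rate_hz, config.jitter_frac, config.noise_sd_px, "online",
        )
        for tid in range(1, n_trials + 1):
            bias = _draw_bias(rng, part_bias, offset_spec)
            rt_ms = float(
                np.exp(rng.normal(math.log(pref["rt_median_s"] * 1000.0), pref["rt_sigma"]))
            )
            chosen = "left" if rng.random() < 0.5 else "right"
            other = "right" if chosen == "left" else "left"
            total = fix_ms + rt_ms
            times = _sample_times(total, config.sampling_rate_hz, config.jitter_frac, rng)
            in_fix = times < fix_ms
            n_dec = int((~in_fix).sum())
            tx = np.full(times.size, cx)
            ty = np.full(times.size, cy)
            if n_dec:
                t_rel = times[~in_fix] - fix_ms
                ramp = min(pref["ramp_ms"], rt_ms)
                if ramp > 0:
                    frac = np.clip((t_rel - (rt_ms - ramp)) / ramp, 0.0, 1.0)
                    p_t = 0.5 + (p_i - 0.5) * frac
                else:
                    p_t = np.full(n_dec, p_i)
                on_chosen = rng.random(n_dec) < p_t
                ax = np.empty(n_dec)
                ay = np.empty(n_dec)
                for lab, mask in ((chosen, on_chosen), (other, ~on_chosen)):
                    m = int(mask.sum())
                    if m:
                        ax[mask], ay[mask] = _aim_uniform(by_label[lab], m, config.aim_margin, rng)
                tx[~in_fix] = ax
                ty[~in_fix] = ay
            x, y, live = _emit(
                times, tx, ty, bias, config.noise_sd_px, off_rate,
                config.live_feed_rate, config.screen_w, config.screen_h, rng,
                off_eligible=~in_fix, aois=[a.shifted(*bias) for a in aois],
            )
            phase = np.where(in_fix, "fixation", "decision")
            col.add_gaze(pid, tid, phase, times, x, y, live)
            col.trial_rows.append(
                _trial_row(
                    config, pid, tid,
                    stim_start_ms=fix_ms, stim_end_ms=total,
                    response_time_ms=rt_ms, chosen_label=chosen,
                )
            )
            col.add_aois(pid, tid, aois)
            col.truth_rows.append(
                {
                    "participant_id": pid, "trial_id": tid, "condition": "online",
                    "bias_x": bias[0], "bias_y": bias[1], "p_true": p_i,
                }
            )
    return col.build("cascade", config, _default_participants(config.n_participants))


def simulate_novelty_study(config: SimulationConfig) -> GazeDataset:
    """Preferential-looking study: familiarization, gap, then a test phase
    whose samples aim at the novel image with probability ``p_novel``.

    Timeline per trial (ms): fixation [0, 2000), familiarization
    [2000, 7000) with two identical images (gaze splits evenly), blank gap
    [7000, 9000) (gaze wanders uniformly), test [9000, 14000).
    The novel side is randomised per trial, or alternates left/right with
    trial parity when ``randomize_side`` is false.
    """
    n_trials, off_rate, pref, offset_spec = config.resolved("novelty")
    p_novel = float(pref["p_novel"])
    if not (0.0 <= p_novel <= 1.0):
        raise ValueError("p_novel must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    aois = side_by_side_aois(*NOVELTY_IMAGE_PX, screen_w=config.screen_w, screen_h=config.screen_h)
    by_label = {a.label: a for a in aois}
    col = _Collector()
    fix_ms = config.fixation_ms
    fam_ms, gap_ms, test_ms = 5000.0, 2000.0, 5000.0
    t_fam, t_gap, t_test = fix_ms, fix_ms + fam_ms, fix_ms + fam_ms + gap_ms
    total = t_test + test_ms
    cx, cy = config.screen_w / 2, config.screen_h / 2

    for pid in range(1, config.n_participants + 1):
        part_bias = _participant_bias(rng, offset_spec)
        p_i = float(_clip_unit(rng.normal(p_novel, pref["participant_sd"])))
        _add_calibration_trial(
            col, config, pid, 0, _draw_bias(rng, part_bias, offset_spec), rng,
            config.sampling_rate_hz, config.jitter_frac, config.noise_sd_px, "online",
        )
        for tid in range(1, n_trials + 1):
            bias = _draw_bias(rng, part_bias, offset_spec)
            if pref["randomize_side"]:
                novel = "left" if rng.random() < 0.5 else "right"
            else:
                novel = "left" if tid % 2 == 1 else "right"
            familiar = "right" if novel == "left" else "left"
            times = _sample_times(total, config.sampling_rate_hz, config.jitter_frac, rng)
            phase = np.where(
                times < t_fam, "fixation",
                np.where(times < t_gap, "familiarization",
                         np.where(times < t_test, "gap", "test")),
            )
            tx = np.full(times.size, cx)
            ty = np.full(times.size, cy)
            fam_mask = phase == "familiarization"
            n_fam = int(fam_mask.sum())
            if n_fam:
                left = rng.random(n_fam) < 0.5
                ax = np.empty(n_fam)
                ay = np.empty(n_fam)
                for lab, m in (("left", left), ("right", ~left)):
                    k = int(m.sum())
                    if k:
                        ax[m], ay[m] = _aim_uniform(by_label[lab], k, config.aim_margin, rng)
                tx[fam_mask], ty[fam_mask] = ax, ay
            gap_mask = phase == "gap"
            n_gapped = int(gap_mask.sum())
            if n_gapped:
                tx[gap_mask] = rng.uniform(0, config.screen_w, n_gapped)
                ty[gap_mask] = rng.uniform(0, config.screen_h, n_gapped)
            test_mask = phase == "test"
            n_test = int(test_mask.sum())
            if n_test:
                on_novel = rng.random(n_test) < p_i
                ax = np.empty(n_test)
                ay = np.empty(n_test)
                for lab, m in ((novel, on_novel), (familiar, ~on_novel)):
                    k = int(m.sum())
                    if k:
                        ax[m], ay[m] = _aim_uniform(by_label[lab], k, config.aim_margin, rng)
                tx[test_mask], ty[test_mask] = ax, ay
            x, y, live = _emit(
                times, tx, ty, bias, config.noise_sd_px, off_rate,
                config.live_feed_rate, config.screen_w, config.screen_h, rng,
                off_eligible=fam_mask | test_mask,
                aois=[a.shifted(*bias) for a in aois],
            )
            col.add_gaze(pid, tid, phase, times, x, y, live)
            col.trial_rows.append(
                _trial_row(
                    config, pid, tid,
                    stim_start_ms=t_fam, stim_end_ms=total,
                    novel_label=novel, test_start_ms=t_test, test_end_ms=total,
                )
            )
            col.add_aois(pid, tid, aois)
            col.truth_rows.append(
                {
                    "participant_id": pid, "trial_id": tid, "condition": "online",
                    "bias_x": bias[0], "bias_y": bias[1], "p_true": p_i,
                    "novel_label": novel,
                }
            )
    return col.build("novelty", config, _default_participants(config.n_participants))


_QUADRANTS = ("top_left", "top_right", "bottom_left", "bottom_right")


def simulate_vwp_study(config: SimulationConfig) -> GazeDataset:
    """Paired four-quadrant looking-while-listening study (online + lab).

    Every participant contributes an online block (webcam offset/noise,
    jittered ~30 Hz sampling; trials 1..n) and a lab block (near-zero
    offset, low noise, regular high-rate sampling; trials 101..100+n).
    Timeline per trial (ms): fixation [0, 2000), four images
    [2000, 11000); the spoken sentence starts at 3000 after a 1000-ms
    preview and the target word onset falls 4000 +- 500 ms later.  After
    the onset the probability of aiming at the target quadrant ramps from
    0.25 to the participant's block-specific ``p_target`` over ``ramp_ms``.
    """
    n_trials, off_rate, pref, offset_spec = config.resolved("vwp")
    for key in ("p_target_online", "p_target_lab"):
        if float(pref[key]) < 0.25:
            raise ValueError(f"{key} must be >= 0.25 (chance for four AOIs)")
    rng = np.random.default_rng(config.seed)
    aois = quadrant_aois(*VWP_IMAGE_PX, screen_w=config.screen_w, screen_h=config.screen_h)
    by_label = {a.label: a for a in aois}
    col = _Collector()
    fix_ms = config.fixation_ms
    image_ms = 9000.0
    total = fix_ms + image_ms
    sentence_on = fix_ms + 1000.0
    cx, cy = config.screen_w / 2, config.screen_h / 2
    ramp_ms = float(pref["ramp_ms"])

    blocks = (
        ("online", 0, float(pref["p_target_online"]), config.sampling_rate_hz,
         config.jitter_frac, config.noise_sd_px, offset_spec, off_rate),
        ("lab", 100, float(pref["p_target_lab"]), config.lab.sampling_rate_hz,
         config.lab.jitter_frac, config.lab.noise_sd_px, config.lab.offset,
         config.lab.off_aoi_rate),
    )

    for pid in range(1, config.n_participants + 1):
        shared = rng.normal(0.0, pref["participant_sd"])
        block_dev = rng.normal(0.0, pref["block_sd"], 2)
        for bi, (cond, tid0, p_block, rate, jit, noise_sd, block_offset, block_off) in enumerate(blocks):
            part_bias = _participant_bias(rng, block_offset)
            p_i = float(np.clip(p_block + shared + block_dev[bi], 0.25, 1.0))
            _add_calibration_trial(
                col, config, pid, tid0, _draw_bias(rng, part_bias, block_offset), rng,
                rate, jit, noise_sd, cond,
            )
            for k in range(1, n_trials + 1):
                tid = tid0 + k
                bias = _draw_bias(rng, part_bias, block_offset)
                target = _QUADRANTS[rng.integers(0, 4)]
                distractors = [q for q in _QUADRANTS if q != target]
                onset = sentence_on + 4000.0 + rng.uniform(-500.0, 500.0)
                times = _sample_times(total, rate, jit, rng)
                in_fix = times < fix_ms
                img_mask = ~in_fix
                tx = np.full(times.size, cx)
                ty = np.full(times.size, cy)
                n_img = int(img_mask.sum())
                if n_img:
                    t_img = times[img_mask]
                    if ramp_ms > 0:
                        frac = np.clip((t_img - onset) / ramp_ms, 0.0, 1.0)
                    else:
                        frac = (t_img >= onset).astype(float)
                    p_t = 0.25 + (p_i - 0.25) * frac
                    u = rng.random(n_img)
                    on_target = u < p_t
                    which = rng.integers(0, 3, n_img)
                    ax = np.empty(n_img)
                    ay = np.empty(n_img)
                    m = int(on_target.sum())
                    if m:
                        ax[on_target], ay[on_target] = _aim_uniform(
                            by_label[target], m, config.aim_margin, rng
                        )
                    for j, q in enumerate(distractors):
                        sel = (~on_target) & (which == j)
                        k2 = int(sel.sum())
                        if k2:
                            ax[sel], ay[sel] = _aim_uniform(by_label[q], k2, config.aim_margin, rng)
                    tx[img_mask], ty[img_mask] = ax, ay
                x, y, live = _emit(
                    times, tx, ty, bias, noise_sd, block_off,
                    config.live_feed_rate, config.screen_w, config.screen_h, rng,
                    off_eligible=img_mask, aois=[a.shifted(*bias) for a in aois],
                )
                phase = np.where(in_fix, "fixation", "images")
                col.add_gaze(pid, tid, phase, times, x, y, live)
                col.trial_rows.append(
                    _trial_row(
                        config, pid, tid, condition=cond,
                        stim_start_ms=fix_ms, stim_end_ms=total,
                        target_label=target, target_onset_ms=onset,
                    )
                )
                col.add_aois(pid, tid, aois)
                col.truth_rows.append(
                    {
                        "participant_id": pid, "trial_id": tid, "condition": cond,
                        "bias_x": bias[0], "bias_y": bias[1], "p_true": p_i,
                        "target_label": target,
                    }
                )
    return col.build("vwp", config, _default_participants(config.n_participants))


def simulate_study(paradigm: str, config: SimulationConfig) -> GazeDataset:
    """Dispatch to the paradigm-specific generator."""
    try:
        fn = {
            "cascade": simulate_cascade_study,
            "novelty": simulate_novelty_study,
            "vwp": simulate_vwp_study,
        }[paradigm]
    except KeyError:
        raise ValueError(f"unknown paradigm {paradigm!r}") from None
    return fn(config)
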