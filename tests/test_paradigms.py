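import numpy as np
import pandas as pd
import pytest

import gazepipe as gp
from gazepipe.paradigms import (
    aggregate_participants,
    cascade_proportion,
    cascade_trial_results,
    compare_conditions,
    decision_locked_timecourse,
    novelty_proportion,
    novelty_trial_results,
    stimulus_locked_timecourse,
    vwp_proportion,
    vwp_trial_results,
)
from gazepipe.preprocess import preprocess_dataset


def _win_samples(t, aoi):
    return pd.DataFrame({"t_ms": t, "aoi": aoi})


class TestCascadeProportion:
    def test_count_ratio_seven_of_nine(self):
        t = np.linspace(1905, 1995, 9)
        aoi = ["left"] * 7 + ["right"] * 2
        res = cascade_proportion(_win_samples(t, aoi), "left", 2000.0)
        assert res.proportion == pytest.approx(7 / 9)
        assert res.n_in_aoi == 9

    def test_all_on_chosen_gives_one(self):
        t = np.linspace(1910, 1990, 5)
        res = cascade_proportion(_win_samples(t, ["right"] * 5), "right", 2000.0)
        assert res.proportion == 1.0

    def test_equal_split_gives_half(self):
        t = np.linspace(1905, 1995, 8)
        res = cascade_proportion(_win_samples(t, ["left", "right"] * 4), "left", 2000.0)
        assert res.proportion == 0.5

    def test_window_is_right_open_at_response(self):
        """A sample exactly at the response timestamp is excluded."""
        s = _win_samples([1900.0, 1950.0, 2000.0], ["left"] * 3)
        res = cascade_proportion(s, "left", 2000.0)
        assert res.n_in_aoi == 2

    def test_off_aoi_samples_not_in_denominator(self):
        s = _win_samples([1910.0, 1940.0, 1970.0, 1990.0], ["left", None, None, "right"])
        res = cascade_proportion(s, "left", 2000.0)
        assert res.n_in_aoi == 2
        assert res.n_total == 4
        assert res.proportion == 0.5

    def test_no_in_aoi_samples_is_missing(self):
        s = _win_samples([1950.0], [None])
        assert cascade_proportion(s, "left", 2000.0) is None


class TestNoveltyAndVWPProportions:
    def test_all_on_familiar_gives_zero(self):
        s = _win_samples(np.linspace(9000, 13999, 10), ["right"] * 10)
        res = novelty_proportion(s, "left", (9000.0, 14000.0))
        assert res.proportion == 0.0

    def test_half_split_is_chance(self):
        s = _win_samples(np.linspace(9000, 13999, 60), ["left", "right"] * 30)
        res = novelty_proportion(s, "left", (9000.0, 14000.0))
        assert res.proportion == 0.5

    def test_vwp_role_proportions_partition_unity(self):
        labels = ["top_left", "top_right", "bottom_left", "bottom_right"]
        aoi = ["top_left"] * 26 + ["top_right"] * 8 + ["bottom_left"] * 8 + ["bottom_right"] * 8
        s = _win_samples(np.linspace(7200, 7599, 50), aoi)
        res, roles = vwp_proportion(s, "top_left", labels, (7200.0, 7600.0))
        assert res.proportion == pytest.approx(0.52)
        assert roles["top_right"] == pytest.approx(0.16)
        assert sum(roles.values()) == pytest.approx(1.0)

    def test_vwp_uniform_sampling_is_chance(self):
        labels = ["top_left", "top_right", "bottom_left", "bottom_right"]
        s = _win_samples(np.linspace(7200, 7599, 40), labels * 10)
        res, _ = vwp_proportion(s, "bottom_right", labels, (7200.0, 7600.0))
        assert res.proportion == pytest.approx(0.25)


class TestAggregation:
    def test_unweighted_mean_of_trials(self):
        tr = pd.DataFrame(
            {
                "participant_id": [1, 1, 2],
                "trial_id": [1, 2, 1],
                "proportion": [0.4, 0.6, 0.62],
                "n_in_aoi": [10, 10, 10],
            }
        )
        out = aggregate_participants(tr).set_index("participant_id")
        assert out.loc[1, "mean_proportion"] == pytest.approx(0.5)
        assert out.loc[2, "mean_proportion"] == pytest.approx(0.62)

    def test_unequal_sample_counts_do_not_weight(self):
        """Trials with 10 and 90 samples average to 0.5, not 0.9."""
        tr = pd.DataFrame(
            {
                "participant_id": [1, 1],
                "trial_id": [1, 2],
                "proportion": [0.0, 1.0],
                "n_in_aoi": [10, 90],
            }
        )
        out = aggregate_participants(tr)
        assert out.loc[0, "mean_proportion"] == pytest.approx(0.5)

    def test_participant_without_valid_trials_dropped(self):
        tr = pd.DataFrame(
            {
                "participant_id": [1, 2],
                "trial_id": [1, 1],
                "proportion": [0.7, np.nan],
                "n_in_aoi": [10, 0],
            }
        )
        out = aggregate_participants(tr)
        assert list(out.participant_id) == [1]


class TestTimecourses:
    def test_single_trial_fully_on_chosen_is_flat_one(self):
        trials = pd.DataFrame(
            {
                "participant_id": [1], "trial_id": [1],
                "stim_start_ms": [2000.0], "response_time_ms": [1500.0],
                "chosen_label": ["left"],
            }
        )
        gaze = pd.DataFrame(
            {
                "participant_id": 1, "trial_id": 1,
                "t_ms": np.linspace(2600, 3450, 18),
                "aoi": ["left"] * 18,
            }
        )
        tc = decision_locked_timecourse(gaze, trials, bin_ms=100, span_ms=800)
        got = tc.mean[~np.isnan(tc.mean)]
        assert (got == 1.0).all()

    def test_null_simulation_flat_near_half_and_ramp_rises(self):
        null_cfg = gp.SimulationConfig(
            n_participants=25, n_trials=8, seed=501,
            preference={"p_final": 0.5, "participant_sd": 0.0},
        )
        ramp_cfg = gp.SimulationConfig(
            n_participants=25, n_trials=8, seed=502,
            preference={"p_final": 0.95, "participant_sd": 0.0, "ramp_ms": 1200.0},
        )
        for cfg, kind in ((null_cfg, "null"), (ramp_cfg, "ramp")):
            ds = gp.simulate_cascade_study(cfg)
            pre = preprocess_dataset(ds, axes="x")
            gaze = pre.gaze[pre.gaze.phase == "decision"]
            tc = decision_locked_timecourse(gaze, ds.task_trials, bin_ms=200, span_ms=1200)
            m = tc.mean[~np.isnan(tc.mean)]
            if kind == "null":
                assert np.nanmax(np.abs(m - 0.5)) < 0.1
            else:
                # monotone rise toward the decision (within noise)
                assert m[-1] > 0.8
                assert m[-1] > m[0] + 0.2

    def test_stimulus_locked_prebins_at_chance_postbins_rise(self):
        cfg = gp.SimulationConfig(
            n_participants=20, n_trials=8, seed=503,
            preference={"p_target_online": 0.8, "p_target_lab": 0.8,
                        "participant_sd": 0.0, "block_sd": 0.0},
        )
        ds = gp.simulate_vwp_study(cfg)
        pre = preprocess_dataset(ds, axes="xy")
        gaze = pre.gaze[pre.gaze.phase == "images"]
        tc = stimulus_locked_timecourse(gaze, ds.task_trials, bin_ms=250, pre_ms=1000, post_ms=1500)
        edges = tc.bin_edges
        pre_bins = tc.mean[edges[1:] <= 0]
        post_bins = tc.mean[edges[:-1] >= 500]
        assert np.nanmean(pre_bins) == pytest.approx(0.25, abs=0.05)
        assert np.nanmean(post_bins) > 0.7

    def test_timecourse_window_mean_matches_scalar_outcome(self):
        """Averaging the time-course bins covering the analysis window
        reproduces the windowed proportion (consistency of curve and
        scalar)."""
        cfg = gp.SimulationConfig(n_participants=10, n_trials=6, seed=504)
        ds = gp.simulate_cascade_study(cfg)
        pre = preprocess_dataset(ds, axes="x")
        gaze = pre.gaze[pre.gaze.phase == "decision"]
        tc = decision_locked_timecourse(gaze, ds.task_trials, bin_ms=100, span_ms=100)
        tr = cascade_trial_results(gaze, ds.task_trials, window_ms=100)
        summ = aggregate_participants(tr)
        # same averaging path: trials -> participants -> group
        per_part = (
            tr.dropna(subset=["proportion"])
            .groupby("participant_id")["proportion"].mean()
        )
        assert tc.mean[-1] == pytest.approx(per_part.mean(), abs=1e-9)
        assert summ["mean_proportion"].mean() == pytest.approx(per_part.mean(), abs=1e-12)


class TestCompareConditions:
    def _summ(self, pids, vals, cond):
        return pd.DataFrame(
            {"participant_id": pids, "condition": cond, "mean_proportion": vals,
             "n_trials_retained": 10}
        )

    def test_identical_conditions_t_zero_ratios_one(self):
        vals = [0.4, 0.55, 0.7, 0.6]
        on = self._summ([1, 2, 3, 4], vals, "online")
        lab = self._summ([1, 2, 3, 4], vals, "lab")
        comp = compare_conditions(on, lab, chance=0.25, compute_bf=False)
        assert comp.result.t == 0.0
        assert comp.numerator_ratio == pytest.approx(1.0)
        assert comp.sd_ratio == pytest.approx(1.0)

    def test_constant_shift_recovers_offset_in_numerator_ratio(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.4, 0.6, 12)
        on = self._summ(range(12), base, "online")
        lab = self._summ(range(12), base + 0.19, "lab")
        comp = compare_conditions(on, lab, chance=0.25, compute_bf=False)
        assert comp.result.t == np.inf  # zero-variance differences diverge
        expect = (base.mean() - 0.25) / (base.mean() + 0.19 - 0.25)
        assert comp.numerator_ratio == pytest.approx(expect, abs=1e-12)
        assert comp.sd_ratio == pytest.approx(1.0)
        assert comp.mean_lab - comp.mean_online == pytest.approx(0.19)

    def test_unmatched_participants_listed_in_error(self):
        on = self._summ([1, 2, 3], [0.5, 0.6, 0.7], "online")
        lab = self._summ([1, 2, 4], [0.5, 0.6, 0.7], "lab")
        with pytest.raises(ValueError, match=r"online-only \[3\], lab-only \[4\]"):
            compare_conditions(on, lab)

    def test_paired_synthetic_study_recovers_lab_advantage(self, small_vwp):
        pre = preprocess_dataset(small_vwp, axes="xy")
        gaze = pre.gaze[pre.gaze.phase == "images"]
        tr = vwp_trial_results(gaze, small_vwp.task_trials)
        summ = aggregate_participants(tr)
        on = summ[summ.condition == "online"]
        lab = summ[summ.condition == "lab"]
        comp = compare_conditions(on, lab, chance=0.25, compute_bf=False)
        assert comp.mean_lab > comp.mean_online
        assert comp.result.t > 0


class TestBatchAgainstPerTrial:
    def test_batch_cascade_matches_scalar_function(self, small_cascade):
        pre = preprocess_dataset(small_cascade, axes="x")
        gaze = pre.gaze[pre.gaze.phase == "decision"]
        batch = cascade_trial_results(gaze, small_cascade.task_trials)
        for _, row in batch.head(10).iterrows():
            tr = small_cascade.task_trials.set_index(["participant_id", "trial_id"]).loc[
                (row.participant_id, row.trial_id)
            ]
            g = gaze[(gaze.participant_id == row.participant_id) & (gaze.trial_id == row.trial_id)]
            res = cascade_proportion(g, tr.chosen_label, tr.stim_start_ms + tr.response_time_ms)
            if res is None:
                assert bool(row.missing)
            else:
                assert row.proportion == pytest.approx(res.proportion, abs=1e-12)
                assert row.n_in_aoi == res.n_in_aoi

    def test_batch_novelty_matches_scalar_function(self, small_novelty):
        pre = preprocess_dataset(small_novelty, axes="x")
        gaze = pre.gaze[pre.gaze.phase.isin(["familiarization", "test"])]
        batch = novelty_trial_results(gaze, small_novelty.task_trials)
        for _, row in batch.head(8).iterrows():
            tr = small_novelty.task_trials.set_index(["participant_id", "trial_id"]).loc[
                (row.participant_id, row.trial_id)
            ]
            g = gaze[(gaze.participant_id == row.participant_id) & (gaze.trial_id == row.trial_id)]
            res = novelty_proportion(g, tr.novel_label, (tr.test_start_ms, tr.test_end_ms))
            if res is None:
                assert bool(row.missing)
            else:
                assert row.proportion == pytest.approx(res.proportion, abs=1e-12)
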