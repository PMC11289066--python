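import numpy as np
import pandas as pd
import pytest

import gazepipe as gp
from gazepipe.exclusion import (
    ExclusionCriteria,
    SENSITIVITY_LEVELS,
    apply_exclusions,
    filter_samples,
    flag_participants,
    flag_trials,
    sensitivity_filter,
)
from gazepipe.preprocess import preprocess_dataset


@pytest.fixture(scope="module")
def pre_cascade(request):
    cfg = gp.SimulationConfig(n_participants=10, n_trials=8, seed=401)
    ds = gp.simulate_cascade_study(cfg)
    return preprocess_dataset(ds, axes="x")


def _freeze_participant(ds, pid, x=640.0, y=360.0):
    """Overwrite a participant's every sample with one constant position."""
    m = ds.gaze.participant_id == pid
    ds.gaze.loc[m, "x_px"] = x
    ds.gaze.loc[m, "y_px"] = y


class TestParticipantRules:
    def test_frozen_gaze_flagged_first(self):
        cfg = gp.SimulationConfig(n_participants=4, n_trials=4, seed=402)
        ds = gp.simulate_cascade_study(cfg)
        _freeze_participant(ds, 2)
        flags = flag_participants(preprocess_dataset(ds, axes="x"))
        row = flags.set_index("participant_id").loc[2]
        assert row.excluded and row.rule == "no_gaze_variation"

    def test_identical_responses_flagged(self):
        cfg = gp.SimulationConfig(n_participants=4, n_trials=6, seed=403)
        ds = gp.simulate_cascade_study(cfg)
        ds.trials.loc[ds.trials.participant_id == 3, "chosen_label"] = "left"
        flags = flag_participants(preprocess_dataset(ds, axes="x"))
        row = flags.set_index("participant_id").loc[3]
        assert row.excluded and row.rule == "no_response_variation"

    def test_off_aoi_over_half_flagged_strictly(self):
        """60 of 100 stimulus samples outside AOIs -> excluded (0.6 > 0.5);
        exactly half is retained (strict inequality)."""
        cfg = gp.SimulationConfig(n_participants=3, n_trials=4, seed=404,
                                  noise_sd_px=0.0, off_aoi_rate=0.0,
                                  offset=gp.OffsetSpec(0.0, 0.0))
        ds = gp.simulate_cascade_study(cfg)
        pre = preprocess_dataset(ds, axes="x")
        dec_idx = pre.gaze.index[(pre.gaze.participant_id == 1) & (pre.gaze.phase == "decision")]
        n = len(dec_idx)
        k_out = int(np.ceil(0.6 * n))
        pre.gaze.loc[dec_idx[:k_out], "aoi"] = None
        flags = flag_participants(pre)
        assert flags.set_index("participant_id").loc[1].rule == "off_aoi"
        # boundary: exactly 50% out is retained
        pre2 = preprocess_dataset(ds, axes="x")
        dec2 = pre2.gaze.index[(pre2.gaze.participant_id == 2) & (pre2.gaze.phase == "decision")]
        half = len(dec2) // 2
        pre2.gaze.loc[dec2[:half], "aoi"] = None
        frac = pre2.gaze.loc[dec2, "aoi"].isna().mean()
        if frac <= 0.5:
            assert not flags.set_index("participant_id").loc[2].excluded

    def test_missing_data_over_half_flagged(self, pre_cascade):
        pre = preprocess_dataset(pre_cascade.dataset.copy(), axes="x")
        keep = ~((pre.gaze.participant_id == 5) & (pre.gaze.trial_id > 3))
        pre.gaze = pre.gaze[keep].reset_index(drop=True)
        flags = flag_participants(pre)
        row = flags.set_index("participant_id").loc[5]
        assert row.excluded and row.rule == "missing"  # 5 of 8 trials gone

    def test_empty_dataset_errors(self, pre_cascade):
        import copy

        pre = copy.copy(pre_cascade)
        pre.gaze = pre.gaze.iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            flag_participants(pre)


class TestTrialRules:
    def test_midline_deviation_threshold_two_aoi(self, pre_cascade):
        """Deviation of 330 px on a 1280-px screen exceeds the 25% limit
        (320 px); 310 px does not."""
        pre = preprocess_dataset(pre_cascade.dataset.copy(), axes="x")
        t = pre.trials
        i1 = t.index[(t.participant_id == 1) & (t.trial_id == 1)][0]
        i2 = t.index[(t.participant_id == 1) & (t.trial_id == 2)][0]
        t.loc[i1, "corrected_midline_x"] = t.loc[i1, "true_midline_x"] + 330.0
        t.loc[i2, "corrected_midline_x"] = t.loc[i2, "true_midline_x"] - 310.0
        t.loc[[i1, i2], "sd_x"] = 0.0
        flags = flag_trials(pre, study_mode="two_aoi").set_index(["participant_id", "trial_id"])
        assert flags.loc[(1, 1)].rule == "midline_deviation"
        assert flags.loc[(1, 2)].rule != "midline_deviation"

    def test_four_aoi_rule_requires_both_axes(self):
        cfg = gp.SimulationConfig(n_participants=2, n_trials=3, seed=405)
        ds = gp.simulate_vwp_study(cfg)
        pre = preprocess_dataset(ds, axes="xy")
        t = pre.trials
        task = t[~t.is_calibration.astype(bool)]
        i0, i1, i2 = task.index[:3]
        # y over 25% of 720 (=180) AND x over 37.5% of 1280 (=480): excluded
        t.loc[i0, "corrected_midline_y"] = t.loc[i0, "true_midline_y"] + 200.0
        t.loc[i0, "corrected_midline_x"] = t.loc[i0, "true_midline_x"] + 500.0
        # only y beyond its limit: retained by the conjunction
        t.loc[i1, "corrected_midline_y"] = t.loc[i1, "true_midline_y"] + 200.0
        t.loc[i1, "corrected_midline_x"] = t.loc[i1, "true_midline_x"] + 100.0
        # only x beyond its limit: retained
        t.loc[i2, "corrected_midline_x"] = t.loc[i2, "true_midline_x"] + 500.0
        t.loc[i2, "corrected_midline_y"] = t.loc[i2, "true_midline_y"] + 50.0
        t.loc[[i0, i1, i2], "sd_x"] = 0.0
        flags = flag_trials(pre, study_mode="four_aoi")
        flags = flags.set_index(["participant_id", "trial_id"])
        k0 = tuple(task.loc[i0, ["participant_id", "trial_id"]])
        k1 = tuple(task.loc[i1, ["participant_id", "trial_id"]])
        k2 = tuple(task.loc[i2, ["participant_id", "trial_id"]])
        assert flags.loc[k0].rule == "midline_deviation"
        assert flags.loc[k1].rule != "midline_deviation"
        assert flags.loc[k2].rule != "midline_deviation"

    def test_rt_bounds(self, pre_cascade):
        pre = preprocess_dataset(pre_cascade.dataset.copy(), axes="x")
        t = pre.trials
        task = t[~t.is_calibration.astype(bool)]
        fast, slow, fine = task.index[:3]
        t.loc[fast, "response_time_ms"] = 400.0   # < 0.5 s
        t.loc[slow, "response_time_ms"] = 31_000.0  # > 30 s
        t.loc[fine, "response_time_ms"] = 2000.0
        # avoid earlier rules interfering on these rows
        t.loc[[fast, slow, fine], "dx"] = 0.0
        t.loc[[fast, slow, fine], "corrected_midline_x"] = 640.0
        t.loc[[fast, slow, fine], "sd_x"] = 0.0
        flags = flag_trials(pre, study_mode="two_aoi").set_index(["participant_id", "trial_id"])
        kf = tuple(task.loc[fast, ["participant_id", "trial_id"]])
        ks = tuple(task.loc[slow, ["participant_id", "trial_id"]])
        ko = tuple(task.loc[fine, ["participant_id", "trial_id"]])
        assert flags.loc[kf].rule == "response_time"
        assert flags.loc[ks].rule == "response_time"
        assert not flags.loc[ko].excluded

    def test_sd_rule_and_missing_bias(self, pre_cascade):
        pre = preprocess_dataset(pre_cascade.dataset.copy(), axes="x")
        t = pre.trials
        task = t[~t.is_calibration.astype(bool)]
        sdy, nob = task.index[:2]
        t.loc[sdy, "sd_x"] = 0.26 * 1280
        t.loc[sdy, "corrected_midline_x"] = 640.0
        t.loc[nob, "bias_missing"] = True
        flags = flag_trials(pre, study_mode="two_aoi").set_index(["participant_id", "trial_id"])
        assert flags.loc[tuple(task.loc[sdy, ["participant_id", "trial_id"]])].rule == "midline_sd"
        assert flags.loc[tuple(task.loc[nob, ["participant_id", "trial_id"]])].rule == "no_bias_estimate"


class TestSampleFilter:
    def test_off_aoi_fraction_reported(self, pre_cascade):
        g = pre_cascade.gaze[pre_cascade.gaze.phase == "decision"].head(100).copy()
        g["aoi"] = ["left"] * 88 + [None] * 12
        kept, counts = filter_samples(g)
        assert counts["n_off_aoi"] == 12
        assert counts["frac_off_aoi"] == pytest.approx(0.12)
        assert len(kept) == 88

    def test_live_feed_counted_separately(self, pre_cascade):
        g = pre_cascade.gaze[pre_cascade.gaze.phase == "decision"].head(50).copy()
        g["aoi"] = "left"
        g["live_feed"] = [True] * 5 + [False] * 45
        kept, counts = filter_samples(g, drop_live_feed=True)
        assert counts["n_live_feed"] == 5
        assert len(kept) == 45
        _, counts_off = filter_samples(g, drop_live_feed=False)
        assert counts_off["n_live_feed"] == 0

    def test_all_in_aoi_is_identity(self, pre_cascade):
        g = pre_cascade.gaze[pre_cascade.gaze.phase == "decision"].head(40).copy()
        g["aoi"] = "right"
        kept, counts = filter_samples(g)
        assert len(kept) == 40 and counts["n_off_aoi"] == 0


class TestSensitivityCascade:
    @pytest.fixture
    def pre_aux(self):
        cfg = gp.SimulationConfig(n_participants=6, n_trials=4, seed=406)
        ds = gp.simulate_novelty_study(cfg)
        ds.participants.loc[ds.participants.participant_id == 2, "attention_failures"] = 2
        ds.participants.loc[ds.participants.participant_id == 3, "instruction_time_s"] = 7.0
        ds.participants.loc[ds.participants.participant_id == 4, "self_report"] = 1
        return preprocess_dataset(ds, axes="x")

    def test_cumulative_levels_follow_hierarchy(self, pre_aux):
        kept_base, _, _ = sensitivity_filter(pre_aux, "base")
        kept_att, _, _ = sensitivity_filter(pre_aux, "attention")
        kept_ins, _, _ = sensitivity_filter(pre_aux, "instruction")
        kept_rep, _, _ = sensitivity_filter(pre_aux, "self_report")
        assert set(kept_base.participant_id) == {1, 2, 3, 4, 5, 6}
        assert set(kept_att.participant_id) == {1, 3, 4, 5, 6}
        assert set(kept_ins.participant_id) == {1, 4, 5, 6}
        assert set(kept_rep.participant_id) == {1, 5, 6}

    def test_instruction_boundary_is_strict_less_than(self, pre_aux):
        """7.0 s < 7.5 s threshold -> excluded at the instruction level."""
        kept, _, _ = sensitivity_filter(pre_aux, "instruction")
        assert 3 not in set(kept.participant_id)

    def test_self_report_only_triggers_at_its_level(self, pre_aux):
        kept_att, _, _ = sensitivity_filter(pre_aux, "attention")
        assert 4 in set(kept_att.participant_id)
        kept_rep, _, _ = sensitivity_filter(pre_aux, "self_report")
        assert 4 not in set(kept_rep.participant_id)

    def test_order_stability_excluded_stays_excluded(self, pre_aux):
        previous = None
        for level in SENSITIVITY_LEVELS:
            kept, _, _ = sensitivity_filter(pre_aux, level)
            ids = set(kept.participant_id)
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_live_feed_level_sets_sample_flag(self, pre_aux):
        _, drop_live, table = sensitivity_filter(pre_aux, "live_feed")
        assert drop_live
        assert list(table.level) == list(SENSITIVITY_LEVELS)

    def test_missing_aux_field_named_in_error(self, pre_aux):
        pre_aux.dataset.participants = pre_aux.dataset.participants.drop(
            columns=["instruction_time_s"]
        )
        with pytest.raises(KeyError, match="instruction_time_s"):
            sensitivity_filter(pre_aux, "instruction")

    def test_clean_cohort_unchanged_at_every_level(self):
        cfg = gp.SimulationConfig(n_participants=5, n_trials=3, seed=407)
        ds = gp.simulate_novelty_study(cfg)
        pre = preprocess_dataset(ds, axes="x")
        for level in SENSITIVITY_LEVELS:
            kept, _, _ = sensitivity_filter(pre, level)
            assert len(kept) == 5


class TestFullCascade:
    def test_clean_data_fires_no_rules(self, clean_cascade):
        """Noise-free, offset-free data with sane response times loses
        nothing at any level."""
        pre = preprocess_dataset(clean_cascade, axes="x")
        gaze_f, report = apply_exclusions(pre, study_mode="two_aoi")
        assert report.participants["excluded"].sum() == 0
        assert report.trials["excluded"].sum() == 0
        assert report.sample_counts["n_off_aoi"] == 0

    def test_retention_sums_are_consistent(self, pre_cascade):
        _, report = apply_exclusions(pre_cascade, study_mode="two_aoi")
        report.check_sums()
        r = report.retention.set_index("stage")
        assert r.loc["participants", "n_total"] == 10
        p_kept = r.loc["participants", "n_retained"]
        assert r.loc["trials", "n_total"] == p_kept * 8

    def test_first_triggered_rule_unique_per_entity(self, pre_cascade):
        _, report = apply_exclusions(pre_cascade, study_mode="two_aoi")
        excluded = report.participants[report.participants.excluded]
        assert excluded["rule"].notna().all()
        retained = report.participants[~report.participants.excluded]
        assert retained["rule"].isna().all()
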