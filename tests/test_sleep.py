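"""SPT-window detection, the onset clock transform, bout accounting, and
per-subject aggregation rules."""

import numpy as np
import pandas as pd
import pytest

from somnoscope import sleep


def labels_from_runs(*runs):
    """runs: (state, length) pairs -> label array."""
    return np.concatenate([np.full(n, s, dtype=int) for s, n in runs])


def minute_frame(label_array, start_dow=2, subject_id=1):
    n = len(label_array)
    minutes = np.arange(n)
    return pd.DataFrame({
        "subject_id": subject_id,
        "day_index": 1 + minutes // 1440,
        "minute_of_day": minutes % 1440,
        "calendar_dow": ((start_dow - 1 + minutes // 1440) % 7) + 1,
        "sleep": label_array,
    })


class TestSplitNoonDays:
    def test_window_counts_for_week(self):
        df = minute_frame(np.zeros(7 * 1440, dtype=int))
        out = sleep.split_noon_days(df)
        sizes = out.groupby("window").size()
        complete = sizes[sizes == 1440]
        assert list(complete.index) == [1, 2, 3, 4, 5, 6]
        assert sizes.loc[0] == 720 and sizes.loc[7] == 720

    def test_noon_day1_is_window1_offset0(self):
        df = minute_frame(np.zeros(2 * 1440, dtype=int))
        out = sleep.split_noon_days(df)
        row = out[(out["day_index"] == 1) & (out["minute_of_day"] == 720)]
        assert row["window"].iloc[0] == 1
        assert row["window_offset"].iloc[0] == 0

    def test_windows_partition_series(self):
        df = minute_frame(np.zeros(3 * 1440, dtype=int))
        out = sleep.split_noon_days(df)
        assert len(out) == len(df)
        assert out.groupby(["window", "window_offset"]).size().max() == 1


class TestFindSPT:
    def test_longest_block_when_gap_too_wide(self):
        lab = labels_from_runs((0, 100), (1, 300), (0, 120), (1, 400), (0, 80))
        s, e = sleep.find_spt_window(lab)
        assert (s, e) == (520, 920)

    def test_merge_short_gap(self):
        lab = labels_from_runs((0, 50), (1, 200), (0, 20), (1, 250), (0, 30))
        s, e = sleep.find_spt_window(lab)
        assert (s, e) == (50, 520)          # merged 200+20+250
        bouts = sleep.wake_bouts(lab, (s, e))
        assert bouts == [(250, 20)]

    def test_all_wake_returns_none(self):
        assert sleep.find_spt_window(np.zeros(1440, dtype=int)) is None

    def test_tie_broken_earliest(self):
        lab = labels_from_runs((1, 100), (0, 200), (1, 100))
        assert sleep.find_spt_window(lab) == (0, 100)

    def test_window_starts_and_ends_in_sleep(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lab = (rng.random(1440) < 0.4).astype(int)
            spt = sleep.find_spt_window(lab)
            if spt:
                assert lab[spt[0]] == 1 and lab[spt[1] - 1] == 1


class TestOnsetClock:
    @pytest.mark.parametrize("minute,expect", [
        (780, 25.0),    # 01:00 -> 25 h
        (690, 23.5),    # 23:30
        (720, 24.0),    # midnight
        (0, 12.0),      # noon itself
    ])
    def test_transform(self, minute, expect):
        assert sleep.onset_clock_transform(minute) == expect

    def test_out_of_window_rejected(self):
        with pytest.raises(ValueError):
            sleep.onset_clock_transform(1440)


class TestNightParameters:
    def test_duration_and_efficiency_formulas(self):
        p = sleep.night_parameters((600, 1080), [(700, 20), (800, 10)])
        assert p["spt_len_h"] == 8.0
        assert p["sleep_duration_h"] == 7.5
        assert p["sleep_efficiency"] == 0.9375
        assert p["valid"]

    def test_short_spt_invalid(self):
        p = sleep.night_parameters((600, 770), [])   # 170 min < 3 h
        assert not p["valid"]
        p = sleep.night_parameters((0, 960), [])     # 16 h > 15 h
        assert not p["valid"]

    def test_no_bouts_means_full_efficiency(self):
        p = sleep.night_parameters((600, 1080), [])
        assert p["sleep_efficiency"] == 1.0

    def test_adding_bout_decreases_duration_not_spt(self):
        a = sleep.night_parameters((600, 1080), [(700, 20)])
        b = sleep.night_parameters((600, 1080), [(700, 20), (900, 15)])
        assert b["spt_len_h"] == a["spt_len_h"]
        assert b["sleep_duration_h"] < a["sleep_duration_h"]
        assert b["sleep_efficiency"] < a["sleep_efficiency"]


class TestWeekend:
    def test_friday_saturday_are_weekend(self):
        assert sleep.weekend_classification(6)       # Friday (1 = Sunday)
        assert sleep.weekend_classification(7)       # Saturday
        assert not sleep.weekend_classification(1)   # Sunday noon anchor
        assert not sleep.weekend_classification(2)

    def test_week_recording_covers_both_classes(self):
        for start_dow in range(1, 8):
            dows = ((start_dow - 1 + np.arange(1, 7)) % 7) + 1
            flags = [sleep.weekend_classification(d) for d in dows]
            assert any(flags) and not all(flags)


def _night(sid, day, onset, dur, eff, valid=True, weekend=False):
    return {"subject_id": sid, "sleep_day_index": day,
            "onset_clock": onset, "wakeup_clock": onset + dur,
            "sleep_duration_h": dur, "sleep_efficiency": eff,
            "spt_len_h": dur / eff, "is_weekend_night": weekend,
            "valid": valid}


class TestAggregate:
    def test_three_night_inclusion_rule(self):
        nights = pd.DataFrame([
            _night(1, d, 23 + d, 8, 0.95) for d in (1, 2)
        ] + [
            _night(2, d, 23, 8, 0.95) for d in (1, 2, 3)
        ])
        out = sleep.aggregate_subject(nights).set_index("subject_id")
        assert not out.loc[1, "included"]
        assert out.loc[2, "included"]

    def test_means_over_valid_nights_only(self):
        nights = pd.DataFrame([
            _night(1, 1, 23.0, 8, 1.0),
            _night(1, 2, 24.0, 8, 1.0),
            _night(1, 3, 25.0, 8, 1.0),
            _night(1, 4, 30.0, 2, 1.0, valid=False),
        ])
        out = sleep.aggregate_subject(nights)
        assert out["mean_onset_clock"].iloc[0] == 24.0
        assert out["n_valid_nights"].iloc[0] == 3

    def test_all_weekday_leaves_weekend_missing(self):
        nights = pd.DataFrame([_night(1, d, 23, 8, 1.0) for d in (1, 2, 3)])
        out = sleep.aggregate_subject(nights)
        assert np.isnan(out["weekend_onset"].iloc[0])
        assert out["weekday_onset"].iloc[0] == 23.0


def test_scored_nights_satisfy_identities(nights):
    """duration = SPT - bouts and efficiency = duration / SPT on every
    scored night, to 1e-12."""
    val = nights[nights["valid"]]
    assert len(val) > 0
    lhs = val["sleep_duration_h"]
    rhs = val["spt_len_h"] - val["bout_minutes"] / 60
    assert np.max(np.abs(lhs - rhs)) < 1e-12
    assert np.max(np.abs(val["sleep_efficiency"] * val["spt_len_h"]
                         - val["sleep_duration_h"])) < 1e-12
    assert val["onset_clock"].between(12, 36).all()


def test_recovered_nights_match_truth_to_minutes(cohort):
    """With truth-labelled minutes (zero decoding error), onset is exact to
    1 minute and duration to 2 minutes."""
    minutes, _, truth = cohort
    lab = minutes.rename(columns={"true_state": "sleep"})
    nights = sleep.score_nights(lab)
    j = nights[nights["valid"]].merge(
        truth, on=["subject_id", "sleep_day_index"])
    assert len(j) > 50
    assert (np.abs(j["onset_clock"] - j["true_onset"]) * 60).max() <= 1
    assert (np.abs(j["sleep_duration_h"] - j["true_duration"]) * 60).max() <= 2
    assert (j["is_weekend_night_x"] == j["is_weekend_night_y"]).all()


def test_truncated_partial_window_not_scored():
    # sleep run touching the recording start (window 0 is partial)
    lab = np.zeros(2 * 1440, dtype=int)
    lab[:300] = 1           # midnight-03:00 on day 1, continues off-record
    df = minute_frame(lab)
    nights = sleep.score_nights(df)
    w0 = nights[nights["sleep_day_index"] == 0]
    assert not w0["valid"].any()
    assert (w0["invalid_reason"] == "truncated_spt").all()
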