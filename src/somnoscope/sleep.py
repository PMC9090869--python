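"""Nightly sleep parameters from per-minute sleep/wake labels.

The analysis unit is the *night*: a noon-to-noon window (1440 minutes,
half-open, anchored on the calendar day whose noon starts it).  Within each
window the sleep period time (SPT) window is the longest block of sleep
after merging sleep runs separated by wake gaps shorter than
``merge_gap_max`` (default 60 min); the block is trimmed to start and end
in sleep.  Derived quantities:

* clock time of sleep onset (CTSO): SPT start mapped to a continuous
  12-36 h clock (23:00 -> 23, 01:00 -> 25), so post-midnight onsets stay
  linear;
* wake bouts: maximal wake runs strictly inside the SPT window (each
  shorter than the merge gap, by construction);
* sleep duration = SPT duration − summed wake-bout duration;
* sleep efficiency = sleep duration / SPT duration.

Nights with an SPT shorter than 3 h or longer than 15 h are invalid, and
subjects need at least 3 valid nights to enter the analysis.  A night is
a weekend night iff its anchor day is Friday or Saturday (the sleep
episode precedes a free morning); day-of-week is coded 1 = Sunday.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
NOON = 720
DEFAULT_MERGE_GAP = 60
SPT_MIN_H = 3.0
SPT_MAX_H = 15.0
MIN_VALID_NIGHTS = 3
WEEKEND_ANCHOR_DOWS = (6, 7)   # Friday, Saturday (1 = Sunday)


def _runs(mask: np.ndarray):
    """(start, end) half-open for maximal True runs."""
    d = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def split_noon_days(labels: pd.DataFrame) -> pd.DataFrame:
    """Assign each minute to its noon-to-noon window.

    Adds ``window`` (anchor day index; minutes before noon of day d belong
    to window d-1) and ``window_offset`` (0..1439 from the anchoring noon).
    Window 0 and the last window are partial for midnight-aligned
    recordings.
    """
    df = labels.copy()
    mod = df["minute_of_day"].to_numpy()
    day = df["day_index"].to_numpy()
    after_noon = mod >= NOON
    df["window"] = np.where(after_noon, day, day - 1)
    df["window_offset"] = np.where(after_noon, mod - NOON, mod + NOON)
    return df


def find_spt_window(window_labels: np.ndarray,
                    merge_gap_max: int = DEFAULT_MERGE_GAP):
    """Longest merged sleep block in a labelled window.

    ``window_labels`` is 0/1 (1 = sleep) over the window's recorded
    minutes.  Sleep runs separated by wake gaps shorter than
    ``merge_gap_max`` are merged; the longest merged block wins, ties to
    the earliest; returns half-open (start, end) indices or None when no
    sleep minute exists.  The block starts and ends in sleep by
    construction.
    """
    labels = np.asarray(window_labels)
    sleep_runs = _runs(labels == 1)
    if not sleep_runs:
        return None
    blocks = []
    cur_s, cur_e = sleep_runs[0]
    for s, e in sleep_runs[1:]:
        if s - cur_e < merge_gap_max:
            cur_e = e
        else:
            blocks.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    blocks.append((cur_s, cur_e))
    best = max(blocks, key=lambda b: (b[1] - b[0], -b[0]))
    return int(best[0]), int(best[1])


def onset_clock_transform(spt_start_min: float) -> float:
    """Minutes-from-noon -> continuous 12-36 h clock (1 am -> 25 h)."""
    if not 0 <= spt_start_min < MINUTES_PER_DAY:
        raise ValueError("SPT start must lie within the noon-to-noon window")
    return 12.0 + spt_start_min / 60.0


def wake_bouts(window_labels: np.ndarray, spt: tuple[int, int]):
    """Maximal wake runs strictly inside the SPT window, as
    (start, length) in window offsets."""
    s, e = spt
    inner = np.asarray(window_labels)[s:e]
    return [(int(s + a), int(b - a)) for a, b in _runs(inner == 0)]


def night_parameters(spt: tuple[int, int], bouts) -> dict:
    """SPT length, sleep duration, efficiency and the 3-15 h validity flag."""
    s, e = spt
    assert e > s, "zero-length SPT cannot arise from a trimmed sleep block"
    spt_len_h = (e - s) / 60.0
    bout_min = sum(ln for _, ln in bouts)
    duration_h = spt_len_h - bout_min / 60.0
    return {
        "spt_start_min": s,
        "spt_end_min": e,
        "onset_clock": onset_clock_transform(s),
        "wakeup_clock": 12.0 + e / 60.0,
        "spt_len_h": spt_len_h,
        "n_bouts": len(bouts),
        "bout_minutes": bout_min,
        "sleep_duration_h": duration_h,
        "sleep_efficiency": duration_h / spt_len_h,
        "valid": SPT_MIN_H <= spt_len_h <= SPT_MAX_H,
    }


def weekend_classification(anchor_dow: int) -> bool:
    """Weekend night iff the window's anchor day is Friday or Saturday."""
    return anchor_dow in WEEKEND_ANCHOR_DOWS


def score_nights(labels: pd.DataFrame,
                 merge_gap_max: int = DEFAULT_MERGE_GAP) -> pd.DataFrame:
    """Per-night sleep parameters for every subject in a labelled table.

    ``labels`` needs subject_id, day_index, minute_of_day, calendar_dow and
    ``sleep`` (0/1).  Partial first/last windows are scored only when the
    SPT does not touch the recorded edge (a truncated SPT would fake a
    short night); full windows always score.  Nights without any sleep, or
    failing the 3-15 h SPT bounds, appear with ``valid = False``.
    """
    df = split_noon_days(labels)
    rows = []
    for (sid, win), sub in df.groupby(["subject_id", "window"], sort=True):
        sub = sub.sort_values("window_offset")
        offs = sub["window_offset"].to_numpy()
        lab = sub["sleep"].to_numpy()
        complete = len(sub) == MINUTES_PER_DAY
        # anchor day-of-week: dow of the day whose noon starts the window
        if (sub["day_index"] == win).any():
            anchor_dow = int(sub.loc[sub["day_index"] == win,
                                     "calendar_dow"].iloc[0])
        else:  # window 0: anchor day precedes the recording
            anchor_dow = int((sub["calendar_dow"].iloc[0] - 2) % 7 + 1)
        base = {
            "subject_id": sid,
            "sleep_day_index": int(win),
            "anchor_dow": anchor_dow,
            "is_weekend_night": weekend_classification(anchor_dow),
            "complete_window": complete,
        }
        spt = find_spt_window(lab, merge_gap_max)
        if spt is None:
            rows.append({**base, "valid": False, "invalid_reason": "no_sleep"})
            continue
        s, e = spt
        if not complete:
            touches_edge = (offs[s] == offs[0] and offs[0] > 0) or \
                           (offs[e - 1] == offs[-1] and offs[-1] < MINUTES_PER_DAY - 1)
            if touches_edge:
                rows.append({**base, "valid": False,
                             "invalid_reason": "truncated_spt"})
                continue
        # map run indices to true window offsets (contiguous within a run)
        s_off, e_off = int(offs[s]), int(offs[e - 1]) + 1
        bouts = wake_bouts(lab, spt)
        bouts = [(int(offs[a]), ln) for a, ln in bouts]
        params = night_parameters((s_off, e_off), bouts)
        reason = "" if params["valid"] else "spt_bounds"
        rows.append({**base, **params, "invalid_reason": reason})
    out = pd.DataFrame(rows)
    if "valid" not in out.columns:
        out["valid"] = False
    out["valid"] = out["valid"].fillna(False).astype(bool)
    return out


def aggregate_subject(nights: pd.DataFrame,
                      demographics: pd.DataFrame | None = None,
                      min_valid_nights: int = MIN_VALID_NIGHTS) -> pd.DataFrame:
    """Per-subject means over valid nights; inclusion needs >= 3 of them.

    Weekday/weekend sub-means of onset and wakeup are reported only when
    the corresponding side has at least one valid night (otherwise NaN,
    never zero).
    """
    val = nights[nights["valid"]].copy()
    counts = (nights.groupby("subject_id").size()
              .rename("n_nights").reset_index())
    if val.empty:
        out = counts.assign(n_valid_nights=0, included=False)
    else:
        agg = val.groupby("subject_id").agg(
            n_valid_nights=("valid", "size"),
            mean_onset_clock=("onset_clock", "mean"),
            mean_duration_h=("sleep_duration_h", "mean"),
            mean_efficiency=("sleep_efficiency", "mean"),
        ).reset_index()
        wk = (val.groupby(["subject_id", "is_weekend_night"])
              [["onset_clock", "wakeup_clock"]].mean().unstack())
        for col, label in (("onset_clock", "onset"), ("wakeup_clock", "wakeup")):
            for flag, tag in ((False, "weekday"), (True, "weekend")):
                name = f"{tag}_{label}"
                if (col, flag) in wk.columns:
                    agg = agg.merge(wk[(col, flag)].rename(name).reset_index(),
                                    on="subject_id", how="left")
                else:
                    agg[name] = np.nan
        out = counts.merge(agg, on="subject_id", how="left")
        out["n_valid_nights"] = out["n_valid_nights"].fillna(0).astype(int)
        out["included"] = out["n_valid_nights"] >= min_valid_nights
    if demographics is not None:
        out = out.merge(demographics, on="subject_id", how="left")
    return out


class SleepParameterExtractor:
    """Thin transform-style wrapper: labelled minutes -> night and subject
    tables (kept on ``nights_`` and ``subjects_`` after ``transform``)."""

    def __init__(self, merge_gap_max: int = DEFAULT_MERGE_GAP,
                 min_valid_nights: int = MIN_VALID_NIGHTS):
        self.merge_gap_max = merge_gap_max
        self.min_valid_nights = min_valid_nights

    def transform(self, labels: pd.DataFrame,
                  demographics: pd.DataFrame | None = None) -> pd.DataFrame:
        self.nights_ = score_nights(labels, self.merge_gap_max)
        self.subjects_ = aggregate_subject(
            self.nights_, demographics, self.min_valid_nights)
        return self.subjects_
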