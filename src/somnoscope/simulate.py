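"""Synthetic accelerometer cohort with known true sleep schedules.

The generator emits what a 7-day, noon-anchored, minute-level wrist
accelerometer deployment would produce for a stratified two-PSU-per-stratum
survey sample: per-minute MIMS activity values with wear predictions and
quality flags, a demographics/design table, and a night-level ground-truth
table against which the whole pipeline (masking, imputation, HMM scoring,
SPT-window extraction, survey estimation) can be validated.

True sleep schedules are structured by age, sex and race:

* quartic age curves for sleep onset (on the continuous 12-36 h clock) and
  sleep duration, peaking/dipping where population actigraphy studies place
  them (latest onset near age 20, shortest sleep near ages 40-50);
* a female shift of +5 min onset and +4 min duration;
* race offsets (vs NH White): NH Black onset +10 min and duration -15 min,
  Mexican American onset -11 min, Other onset +10 min and duration -8 min,
  with a small efficiency penalty ordering White > Other > MexAm > Black;
* weekend nights (noon anchor on Friday or Saturday) delayed in onset and,
  more, in wakeup.

Activity is emitted log-normally per sleep/wake state on the log(1+MIMS)
scale, matching the transform the HMM scorer applies.  Non-wear blocks,
quality flags and -0.01 sentinels are injected so preprocessing has real
work to do.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MIMS_SENTINEL

#: Quartic coefficients (lowest order first, raw age in years) fitted through
#: landmark ages so that onset peaks near age 20 and duration dips near 40-50.
DEFAULT_ONSET_COEFFS = (19.4076, 0.510096, -0.0198258, 0.000284959, -1.38571e-06)
DEFAULT_DURATION_COEFFS = (9.48213, -0.0898929, 0.00148563, -6.9163e-06, -4.57833e-10)

#: (onset shift h, duration shift h, efficiency shift) relative to NH White.
DEFAULT_RACE_SHIFTS = {
    "NH White": (0.0, 0.0, 0.0),
    "NH Black": (10 / 60, -15 / 60, -0.012),
    "Mexican American": (-11 / 60, 0.0, -0.008),
    "Other": (10 / 60, -8 / 60, -0.004),
}

#: Population race mix (NH White / NH Black / Mexican American / Other).
DEFAULT_RACE_PROBS = (0.6444, 0.1148, 0.1010, 0.1398)

MINUTES_PER_DAY = 1440
NOON = 720


class ConfigError(ValueError):
    """Generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Onset/duration curves are quartic polynomials of raw age (hours; onset on
    the 12-36 clock).  Night-level jitter is Normal(0, onset_sd); subjects
    additionally carry persistent Normal random effects so between-person
    variance is realistic for survey estimation.
    """

    n_subjects: int = 300
    seed: int = 0
    n_days: int = 7
    age_range: tuple[int, int] = (6, 85)
    onset_curve_coeffs: tuple[float, ...] = DEFAULT_ONSET_COEFFS
    duration_curve_coeffs: tuple[float, ...] = DEFAULT_DURATION_COEFFS
    sex_onset_shift: float = 5 / 60      # female onset later, hours
    sex_duration_shift: float = 4 / 60   # female duration longer, hours
    race_shifts: dict = field(default_factory=lambda: dict(DEFAULT_RACE_SHIFTS))
    race_probs: tuple[float, ...] = DEFAULT_RACE_PROBS
    onset_sd: float = 0.5                # nightly onset jitter, hours
    duration_sd: float = 0.4             # nightly duration jitter, hours
    subject_onset_sd: float = 0.75       # between-person onset RE, hours
    subject_duration_sd: float = 0.5     # between-person duration RE, hours
    wake_bout_rate: float = 2.0          # expected wake bouts per night
    wake_bout_mean_len: float = 8.0      # minutes; capped at 45 (< SPT merge gap)
    emission_wake: tuple[float, float] = (2.5, 0.8)   # log(1+MIMS) mean, sd
    emission_sleep: tuple[float, float] = (0.3, 0.3)
    nonwear_block_prob: float = 0.15     # per-day probability of a non-wear block
    nonwear_block_len: int = 120         # minutes
    flag_prob: float = 0.001             # per-minute quality-flag probability
    sentinel_prob: float = 0.0005        # per-minute -0.01 sentinel probability
    n_strata: int = 8
    psus_per_stratum: int = 2
    weight_range: tuple[float, float] = (4000.0, 60000.0)
    weekend_onset_delay: float = 45.0    # minutes
    weekend_wake_delay: float = 75.0     # minutes

    def validate(self) -> None:
        if self.psus_per_stratum != 2:
            raise ConfigError("design requires exactly 2 PSUs per stratum")
        for name in ("onset_sd", "duration_sd", "subject_onset_sd",
                     "subject_duration_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        ages = np.arange(self.age_range[0], self.age_range[1] + 1)
        dur = np.polynomial.polynomial.polyval(
            ages, np.asarray(self.duration_curve_coeffs))
        shift = max(abs(s[1]) for s in self.race_shifts.values())
        shift += abs(self.sex_duration_shift)
        if (dur - shift).min() <= 3 or (dur + shift).max() >= 15:
            raise ConfigError(
                "duration curve (plus group shifts) exits the (3, 15) h band; "
                "such a cohort would be excluded wholesale by the SPT filter")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["race_shifts"] = {k: list(v) for k, v in self.race_shifts.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "race_shifts" in d:
            d["race_shifts"] = {k: tuple(v) for k, v in d["race_shifts"].items()}
        for key in ("age_range", "onset_curve_coeffs", "duration_curve_coeffs",
                    "emission_wake", "emission_sleep", "race_probs",
                    "weight_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _poly(coeffs, x):
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs))


def _draw_demographics(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    races = list(cfg.race_shifts)
    probs = np.asarray(cfg.race_probs, float)
    probs = probs / probs.sum()
    age = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    race = rng.choice(races, n, p=probs)
    cycle = np.where(rng.random(n) < 0.5, "A", "B")

    # Oversampled age bands get smaller weights (inverse sampling rate).
    rate = np.select([age < 18, age >= 60], [2.0, 1.5], default=1.0)
    w = np.exp(rng.normal(0.0, 0.35, n)) / rate
    lo, hi = cfg.weight_range
    w = lo + (hi - lo) * (w - w.min()) / (w.max() - w.min() + 1e-12)

    stratum = rng.integers(1, cfg.n_strata + 1, n)
    psu = rng.integers(1, cfg.psus_per_stratum + 1, n)
    return pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "age_years": age,
        "sex": sex,
        "race": race,
        "weight_2yr": w,
        "stratum": stratum,
        "psu": psu,
        "cycle": cycle,
        "eligible": age >= 6,
    })


def _place_bouts(rng, onset_min, wake_min, rate, mean_len):
    """Non-overlapping wake bouts strictly inside (onset, wake), each < 60 min."""
    n = rng.poisson(rate)
    spt = wake_min - onset_min
    bouts = []
    if n == 0 or spt < 30:
        return bouts
    lens = 1 + rng.poisson(max(mean_len - 1, 0.1), n)
    lens = np.minimum(lens, 45)
    starts = np.sort(rng.integers(onset_min + 2, wake_min - 47, n))
    last_end = onset_min + 1
    for s, ln in zip(starts, lens):
        if s <= last_end + 1:
            continue
        e = min(s + int(ln), wake_min - 2)
        if e > s:
            bouts.append((int(s), int(e - s)))
            last_end = e
    return bouts


def generate_cohort(config: GeneratorConfig | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (minute table, demographics table, truth table).

    The minute table covers ``n_days`` consecutive midnight-aligned days per
    subject; true sleep periods are generated for each complete noon-to-noon
    window (anchor days 1..n_days-1), one main sleep period per night.
    All randomness flows from ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    demo = _draw_demographics(cfg, rng)

    n_min = cfg.n_days * MINUTES_PER_DAY
    mu_w, sd_w = cfg.emission_wake
    mu_s, sd_s = cfg.emission_sleep

    minute_frames = []
    truth_rows = []
    for row in demo.itertuples(index=False):
        sid = row.subject_id
        female = row.sex == "female"
        r_on, r_dur, r_eff = cfg.race_shifts[row.race]
        on_re = rng.normal(0.0, cfg.subject_onset_sd)
        dur_re = rng.normal(0.0, cfg.subject_duration_sd)
        start_dow = int(rng.integers(1, 8))
        dows = ((start_dow - 1 + np.arange(cfg.n_days)) % 7) + 1

        state = np.zeros(n_min, dtype=np.int8)   # 0 = wake, 1 = sleep
        for d in range(1, cfg.n_days):           # complete noon windows
            anchor_dow = int(dows[d - 1])
            weekend = anchor_dow in (6, 7)       # Friday / Saturday anchor
            onset_h = (_poly(cfg.onset_curve_coeffs, row.age_years)
                       + female * cfg.sex_onset_shift + r_on + on_re
                       + rng.normal(0.0, cfg.onset_sd)
                       + weekend * cfg.weekend_onset_delay / 60)
            dur_h = (_poly(cfg.duration_curve_coeffs, row.age_years)
                     + female * cfg.sex_duration_shift + r_dur + dur_re
                     + rng.normal(0.0, cfg.duration_sd)
                     + weekend * (cfg.weekend_wake_delay
                                  - cfg.weekend_onset_delay) / 60)
            # efficiency shift realized through the bout load
            bout_rate = cfg.wake_bout_rate * (1 - r_eff / 0.012 * 0.6) \
                if r_eff < 0 else cfg.wake_bout_rate
            dur_h = float(np.clip(dur_h, 3.5, 14.5))
            onset_h = float(np.clip(onset_h, 18.0, 30.0))

            onset_min = int(round((onset_h - 12) * 60))
            # provisional SPT: duration plus planned bout load
            planned = _place_bouts(
                rng, onset_min,
                onset_min + int(round(dur_h * 60)) + 120, bout_rate,
                cfg.wake_bout_mean_len)
            bout_total = sum(ln for _, ln in planned)
            spt_min = int(round(dur_h * 60)) + bout_total
            if onset_min + spt_min > MINUTES_PER_DAY - 5:
                onset_min = MINUTES_PER_DAY - 5 - spt_min
                onset_h = 12 + onset_min / 60
            wake_min = onset_min + spt_min
            bouts = _place_bouts(rng, onset_min, wake_min,
                                 bout_rate, cfg.wake_bout_mean_len)
            bout_total = sum(ln for _, ln in bouts)
            true_dur = (spt_min - bout_total) / 60

            g0 = (d - 1) * MINUTES_PER_DAY + NOON
            state[g0 + onset_min: g0 + wake_min] = 1
            for s, ln in bouts:
                state[g0 + s: g0 + s + ln] = 0

            truth_rows.append({
                "subject_id": sid,
                "sleep_day_index": d,
                "anchor_dow": anchor_dow,
                "is_weekend_night": weekend,
                "true_onset": onset_h,
                "true_wake": 12 + wake_min / 60,
                "true_spt_h": spt_min / 60,
                "true_duration": true_dur,
                "true_efficiency": true_dur / (spt_min / 60),
                "n_bouts": len(bouts),
                "bout_minutes": bout_total,
            })

        y = np.where(state == 1,
                     rng.normal(mu_s, sd_s, n_min),
                     rng.normal(mu_w, sd_w, n_min))
        y = np.maximum(y, 0.0)
        mims = np.expm1(y)

        wear = np.where(state == 1, "sleep-wear", "wake-wear").astype(object)
        for d in range(cfg.n_days):
            if rng.random() < cfg.nonwear_block_prob:
                day_lo = d * MINUTES_PER_DAY
                wake_idx = np.flatnonzero(state[day_lo:day_lo + MINUTES_PER_DAY] == 0)
                ok = wake_idx[wake_idx <= MINUTES_PER_DAY - cfg.nonwear_block_len]
                if ok.size:
                    s = day_lo + int(rng.choice(ok))
                    e = min(s + cfg.nonwear_block_len, day_lo + MINUTES_PER_DAY)
                    wear[s:e] = "non-wear"
                    mims[s:e] = np.expm1(np.maximum(
                        rng.normal(0.05, 0.1, e - s), 0.0))

        flags = (rng.random(n_min) < cfg.flag_prob).astype(np.int64)
        sent = rng.random(n_min) < cfg.sentinel_prob
        mims[sent] = MIMS_SENTINEL

        minute_frames.append(pd.DataFrame({
            "subject_id": sid,
            "day_index": np.repeat(np.arange(1, cfg.n_days + 1), MINUTES_PER_DAY),
            "minute_of_day": np.tile(np.arange(MINUTES_PER_DAY), cfg.n_days),
            "calendar_dow": np.repeat(dows, MINUTES_PER_DAY),
            "mims_triaxial": mims,
            "wear_pred": wear,
            "quality_flag_count": flags,
            "true_state": state,
        }))

    minutes = pd.concat(minute_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return minutes, demo, truth


def truth_summary(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean true onset/duration/efficiency over generated nights."""
    if truth.empty:
        raise ValueError("truth table is empty")
    g = truth.groupby("subject_id")
    out = g.agg(
        n_nights=("true_onset", "size"),
        true_mean_onset=("true_onset", "mean"),
        true_mean_duration=("true_duration", "mean"),
        true_mean_efficiency=("true_efficiency", "mean"),
    ).reset_index()
    wk = (truth.groupby(["subject_id", "is_weekend_night"])
          [["true_onset", "true_wake"]].mean().unstack())
    for col, label in (("true_onset", "onset"), ("true_wake", "wake")):
        for flag, tag in ((False, "weekday"), (True, "weekend")):
            if (col, flag) in wk.columns:
                out = out.merge(
                    wk[(col, flag)].rename(f"true_{tag}_{label}").reset_index(),
                    on="subject_id", how="left")
    return out
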