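"""Minute-level cleaning: missing-marking, wear-day validity, imputation.

The cleaning rules, applied in order per subject:

1. A minute is *missing* iff its MIMS value is the -0.01 sentinel, OR its
   wear prediction is non-wear, OR its quality-flag count exceeds 0.
   ("unknown" wear predictions count as wear.)
2. Maximal missing runs of at least ``min_interval`` (default 60) minutes
   are *imputable intervals*; shorter missing runs contribute a value of 0.
3. A recording day is *valid* iff it has strictly more than ``wear_min``
   (default 960 = 16 h) non-missing wear minutes.
4. A subject is *eligible for imputation* (and hence for sleep scoring) iff
   they have at least ``min_valid_days`` (default 4) valid days.
5. Minutes inside imputable intervals are filled either from the subject's
   own minute-of-day profile (deterministic default) or by a seeded draw
   from a zero-inflated count model of that profile.

The output "clean series" is a DataFrame with one row per subject-minute:
``value`` (imputed, sentinel-free), ``missing`` / ``imputable`` /
``wear`` flags, plus per-day and per-subject QC tables.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MIMS_SENTINEL

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
DEFAULT_MIN_INTERVAL = 60
DEFAULT_WEAR_MINUTES = 960      # "> 16 h" read strictly
DEFAULT_MIN_VALID_DAYS = 4


def _sorted(records: pd.DataFrame) -> pd.DataFrame:
    return records.sort_values(
        ["subject_id", "day_index", "minute_of_day"], kind="mergesort"
    ).reset_index(drop=True)


def mask_invalid_minutes(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the three missing-marking triggers; idempotent.

    Adds ``missing`` (bool), ``wear`` (bool: wear prediction is not
    non-wear) and ``value`` (MIMS with missing minutes as NaN, sentinel
    removed).  Original columns are preserved.
    """
    df = _sorted(records).copy()
    mims = df["mims_triaxial"].astype(float)
    missing = (
        (mims == MIMS_SENTINEL)
        | (df["wear_pred"] == "non-wear")
        | (df["quality_flag_count"] > 0)
    )
    df["missing"] = missing.to_numpy()
    df["wear"] = (df["wear_pred"] != "non-wear").to_numpy()
    df["value"] = np.where(df["missing"], np.nan, mims)
    return df


def missing_intervals(series: pd.DataFrame,
                      min_len: int = DEFAULT_MIN_INTERVAL) -> pd.DataFrame:
    """Maximal missing runs of length >= ``min_len``, per subject.

    Runs are scanned over each subject's concatenated minute timeline (they
    may span midnight).  Returns one row per qualifying interval with the
    start day/minute and length; shorter missing runs are not imputable.
    """
    rows = []
    for sid, sub in series.groupby("subject_id", sort=False):
        miss = sub["missing"].to_numpy()
        if not miss.any():
            continue
        padded = np.diff(np.concatenate(([0], miss.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                rows.append({
                    "subject_id": sid,
                    "start_day": int(sub["day_index"].iloc[s]),
                    "start_minute": int(sub["minute_of_day"].iloc[s]),
                    "length": int(e - s),
                    "start_pos": int(s),
                })
    return pd.DataFrame(
        rows, columns=["subject_id", "start_day", "start_minute",
                       "length", "start_pos"])


def flag_valid_days(series: pd.DataFrame,
                    wear_min: int = DEFAULT_WEAR_MINUTES) -> pd.DataFrame:
    """Per (subject, day): non-missing wear minutes and the strict > 16 h flag."""
    ok = (~series["missing"]) & series["wear"]
    per_day = (series.assign(_ok=ok)
               .groupby(["subject_id", "day_index"], sort=False)["_ok"]
               .sum().reset_index(name="wear_minutes"))
    per_day["valid_day"] = per_day["wear_minutes"] > wear_min
    return per_day


def imputation_eligibility(valid_days: pd.DataFrame,
                           min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                           ) -> pd.DataFrame:
    """Subjects with >= ``min_valid_days`` valid days survive to scoring."""
    per_subj = (valid_days.groupby("subject_id", sort=False)["valid_day"]
                .sum().reset_index(name="n_valid_days"))
    per_subj["eligible"] = per_subj["n_valid_days"] >= min_valid_days
    return per_subj


def _minute_profile_impute(sub: pd.DataFrame, imputable: np.ndarray,
                           valid_day_set: set) -> np.ndarray:
    """Mean non-missing value at the same minute-of-day across valid days."""
    donor = sub.loc[~sub["missing"] & sub["day_index"].isin(valid_day_set)]
    prof = donor.groupby("minute_of_day")["value"].mean()
    overall = donor["value"].mean()
    vals = sub["value"].to_numpy(copy=True)
    mod = sub["minute_of_day"].to_numpy()
    fill = prof.reindex(mod[imputable]).to_numpy()
    orphan = np.isnan(fill)
    if orphan.any():
        logger.info("subject %s: %d minutes with no same-minute donors; "
                    "day-level mean fallback", sub["subject_id"].iloc[0],
                    int(orphan.sum()))
        fill[orphan] = overall if np.isfinite(overall) else 0.0
    vals[imputable] = fill
    return vals


def _zip_impute(sub: pd.DataFrame, imputable: np.ndarray,
                valid_day_set: set, rng: np.random.Generator) -> np.ndarray:
    """Seeded draw from a zero-inflated model of the minute-of-day profile.

    Within 30-minute bins of the day, the donor minutes (non-missing, valid
    days) give a zero probability and a log-normal fit to the positive
    values; imputed minutes are drawn bin-wise.
    """
    donor = sub.loc[~sub["missing"] & sub["day_index"].isin(valid_day_set)]
    vals = sub["value"].to_numpy(copy=True)
    mod = sub["minute_of_day"].to_numpy()
    bins = mod // 30
    donor_bins = donor["minute_of_day"].to_numpy() // 30
    dvals = donor["value"].to_numpy()
    fallback_p0 = float(np.mean(dvals <= 0)) if dvals.size else 0.5
    pos_all = np.log(dvals[dvals > 0]) if (dvals > 0).any() else np.array([0.0])
    for b in np.unique(bins[imputable]):
        sel = imputable & (bins == b)
        dv = dvals[donor_bins == b]
        if dv.size >= 5:
            p0 = float(np.mean(dv <= 0))
            pos = np.log(dv[dv > 0]) if (dv > 0).any() else pos_all
        else:
            p0, pos = fallback_p0, pos_all
        n = int(sel.sum())
        draw = np.exp(rng.normal(pos.mean(), max(pos.std(), 1e-6), n))
        draw[rng.random(n) < p0] = 0.0
        vals[sel] = draw
    return vals


def impute_missing(series: pd.DataFrame,
                   method: str = "minute_profile",
                   min_interval: int = DEFAULT_MIN_INTERVAL,
                   wear_min: int = DEFAULT_WEAR_MINUTES,
                   seed: int | None = 0) -> pd.DataFrame:
    """Fill imputable intervals; zero out sub-threshold missing runs.

    Non-missing minutes are never altered.  ``method`` is
    ``minute_profile`` (deterministic) or ``zip_model`` (seeded draws).
    """
    if method not in ("minute_profile", "zip_model"):
        raise ValueError(f"unknown imputation method {method!r}")
    series = _sorted(series)
    valid = flag_valid_days(series, wear_min)
    intervals = missing_intervals(series, min_interval)
    out = []
    for sid, sub in series.groupby("subject_id", sort=False):
        sub = sub.reset_index(drop=True)
        rng = np.random.default_rng(
            None if seed is None
            else (int(seed) + zlib.crc32(str(sid).encode()) % 100000))
        vd = valid.loc[(valid["subject_id"] == sid) & valid["valid_day"],
                       "day_index"]
        valid_day_set = set(vd)
        imputable = np.zeros(len(sub), dtype=bool)
        for iv in intervals.loc[intervals["subject_id"] == sid].itertuples():
            imputable[iv.start_pos: iv.start_pos + iv.length] = True
        if not sub["missing"].any():
            sub["imputable"] = imputable
            out.append(sub)
            continue
        if method == "minute_profile" or not valid_day_set:
            vals = _minute_profile_impute(sub, imputable, valid_day_set)
        else:
            vals = _zip_impute(sub, imputable, valid_day_set, rng)
        # missing minutes below the interval threshold carry a value of 0
        short_missing = sub["missing"].to_numpy() & ~imputable
        vals[short_missing] = 0.0
        sub["value"] = vals
        sub["imputable"] = imputable
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def preprocess(records: pd.DataFrame,
               method: str = "minute_profile",
               min_interval: int = DEFAULT_MIN_INTERVAL,
               wear_min: int = DEFAULT_WEAR_MINUTES,
               min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
               seed: int | None = 0):
    """Full cleaning chain.

    Returns ``(clean, day_qc, subject_qc)``: the imputed minute series
    restricted to imputation-eligible subjects, the per-day QC table, and
    the per-subject eligibility table (all subjects, for attrition counts).
    """
    masked = mask_invalid_minutes(records)
    day_qc = flag_valid_days(masked, wear_min)
    subject_qc = imputation_eligibility(day_qc, min_valid_days)
    keep = subject_qc.loc[subject_qc["eligible"], "subject_id"]
    masked = masked[masked["subject_id"].isin(set(keep))]
    clean = impute_missing(masked, method, min_interval, wear_min, seed)
    return clean, day_qc, subject_qc


class ActivityPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer wrapper around the cleaning chain.

    ``transform`` maps a raw minute table to the imputed clean series; the
    QC tables from the last transform are kept on ``day_qc_`` and
    ``subject_qc_``.
    """

    def __init__(self, method: str = "minute_profile",
                 min_interval: int = DEFAULT_MIN_INTERVAL,
                 wear_min: int = DEFAULT_WEAR_MINUTES,
                 min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                 seed: int | None = 0):
        self.method = method
        self.min_interval = min_interval
        self.wear_min = wear_min
        self.min_valid_days = min_valid_days
        self.seed = seed

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        clean, self.day_qc_, self.subject_qc_ = preprocess(
            X, self.method, self.min_interval, self.wear_min,
            self.min_valid_days, self.seed)
        return clean
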