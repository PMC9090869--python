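"""Tabular I/O for minute-level activity and demographic/design tables.

Canonical in-memory containers are pandas DataFrames.  Column names mirror
the NHANES minute-summary (PAXMIN) and demographics (DEMO) variable names
through a documented alias map, so real NHANES exports load without renaming
while the synthetic cohort uses the same schemas.

Minute table canonical columns
------------------------------
subject_id        opaque identifier (NHANES SEQN)
day_index         recording day 1..7 (PAXDAYM)
minute_of_day     0..1439, minutes since midnight (0 = 00:00)
calendar_dow      day of week 1..7, 1 = Sunday (PAXDAYWM)
mims_triaxial     MIMS units/minute, >= 0, or the sentinel -0.01 (PAXMTSM)
wear_pred         one of {wake-wear, sleep-wear, non-wear, unknown} (PAXPREDM)
quality_flag_count  number of data-quality flags in the minute (PAXQFM)

Demographics canonical columns
------------------------------
subject_id, age_years (RIDAGEYR), sex (RIAGENDR), race (RIDRETH3 collapsed
to 4 groups), weight_2yr (WTMEC2YR), stratum (SDMVSTRA), psu (SDMVPSU),
cycle ({A, B} for the two 2-year exam cycles).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

MIMS_SENTINEL = -0.01

WEAR_CATEGORIES = ("wake-wear", "sleep-wear", "non-wear", "unknown")
#: NHANES PAXPREDM numeric coding.
WEAR_CODE_MAP = {1: "wake-wear", 2: "sleep-wear", 3: "non-wear", 4: "unknown"}

SEX_CODE_MAP = {1: "male", 2: "female", "male": "male", "female": "female",
                "M": "male", "F": "female"}

RACE_CATEGORIES = ("NH White", "NH Black", "Mexican American", "Other")
#: NHANES RIDRETH3 coding collapsed to the 4 analysis groups
#: (other Hispanic, Asian and other ethnicity fold into "Other").
RACE_CODE_MAP = {
    1: "Mexican American",
    2: "Other",            # other Hispanic
    3: "NH White",
    4: "NH Black",
    6: "Other",            # NH Asian
    7: "Other",            # other race / multiracial
    "NH White": "NH White",
    "NH Black": "NH Black",
    "Mexican American": "Mexican American",
    "Other": "Other",
    "other Hispanic": "Other",
    "Asian": "Other",
    "other": "Other",
}

MINUTE_ALIASES = {
    "SEQN": "subject_id",
    "PAXDAYM": "day_index",
    "PAXDAYWM": "calendar_dow",
    "PAXMTSM": "mims_triaxial",
    "PAXPREDM": "wear_pred",
    "PAXQFM": "quality_flag_count",
}

DEMO_ALIASES = {
    "SEQN": "subject_id",
    "RIDAGEYR": "age_years",
    "RIAGENDR": "sex",
    "RIDRETH3": "race",
    "WTMEC2YR": "weight_2yr",
    "SDMVSTRA": "stratum",
    "SDMVPSU": "psu",
    "SDDSRVYR": "cycle",
}

MINUTE_COLUMNS = ["subject_id", "day_index", "minute_of_day", "calendar_dow",
                  "mims_triaxial", "wear_pred", "quality_flag_count"]
DEMO_COLUMNS = ["subject_id", "age_years", "sex", "race", "weight_2yr",
                "stratum", "psu", "cycle"]

MIN_ELIGIBLE_AGE = 6


class SchemaError(ValueError):
    """A required column is absent or mis-typed."""


class IntegrityError(ValueError):
    """Row-level constraint violated (duplicates, invalid codes/values)."""


def _read_table(path, format=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "parquet" if path.suffix == ".parquet" else "csv"
    if format == "parquet":
        return pd.read_parquet(path)
    if format == "csv":
        return pd.read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _write_table(df: pd.DataFrame, path, format=None) -> None:
    path = Path(path)
    if format is None:
        format = "parquet" if path.suffix == ".parquet" else "csv"
    if format == "parquet":
        df.to_parquet(path, index=False)
    elif format == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def _apply_aliases(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    renames = {c: aliases[c] for c in df.columns if c in aliases}
    return df.rename(columns=renames)


def read_minute_table(path, format=None) -> pd.DataFrame:
    """Read a minute-level activity table (CSV or parquet).

    The -0.01 sentinel is preserved verbatim; masking happens in
    :mod:`somnoscope.preprocess`, not here.

    Raises
    ------
    SchemaError
        if a required column is missing (the error names it).
    IntegrityError
        on duplicate (subject_id, day_index, minute_of_day) rows or
        out-of-range values.
    """
    df = _apply_aliases(_read_table(path, format), MINUTE_ALIASES)
    for col in MINUTE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"minute table missing required column {col!r}")
    df = df[MINUTE_COLUMNS].copy()

    if df.empty:
        df["wear_pred"] = df["wear_pred"].astype(object)
        return df

    dup = df.duplicated(["subject_id", "day_index", "minute_of_day"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["subject_id", "day_index", "minute_of_day"]]
        raise IntegrityError(
            "duplicate subject-minute: subject %r day %r minute %r"
            % tuple(first))

    if pd.api.types.is_numeric_dtype(df["wear_pred"]):
        bad = ~df["wear_pred"].isin(WEAR_CODE_MAP)
        if bad.any():
            raise IntegrityError(
                f"unknown wear_pred code(s): {sorted(df.loc[bad, 'wear_pred'].unique())}")
        df["wear_pred"] = df["wear_pred"].map(WEAR_CODE_MAP)
    else:
        bad = ~df["wear_pred"].isin(WEAR_CATEGORIES)
        if bad.any():
            raise IntegrityError(
                f"unknown wear_pred value(s): {sorted(df.loc[bad, 'wear_pred'].unique())}")

    mims = df["mims_triaxial"].astype(float)
    ok = (mims >= 0) | (mims == MIMS_SENTINEL)
    if not ok.all():
        raise IntegrityError(
            f"mims_triaxial must be >= 0 or exactly {MIMS_SENTINEL}; "
            f"first offender {mims[~ok].iloc[0]!r}")
    df["mims_triaxial"] = mims

    if (df["quality_flag_count"] < 0).any():
        raise IntegrityError("quality_flag_count must be non-negative")
    if not df["minute_of_day"].between(0, 1439).all():
        raise IntegrityError("minute_of_day must be in 0..1439")
    if not df["calendar_dow"].between(1, 7).all():
        raise IntegrityError("calendar_dow must be in 1..7 (1 = Sunday)")
    return df


def read_demographics(path, format=None) -> pd.DataFrame:
    """Read a demographics/design table; map race to the 4-group coding.

    Rows with age below 6 are retained but flagged ``eligible = False``
    (the age filter is an analytic inclusion rule, applied downstream).
    """
    df = _apply_aliases(_read_table(path, format), DEMO_ALIASES)
    for col in DEMO_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"demographics missing required column {col!r}")
    df = df[DEMO_COLUMNS].copy()

    for i, v in enumerate(df["sex"]):
        if v not in SEX_CODE_MAP:
            raise IntegrityError(f"row {i}: unknown sex code {v!r}")
    df["sex"] = df["sex"].map(SEX_CODE_MAP)

    for i, v in enumerate(df["race"]):
        if v not in RACE_CODE_MAP:
            raise IntegrityError(f"row {i}: unknown race code {v!r}")
    df["race"] = df["race"].map(RACE_CODE_MAP)

    # NHANES SDDSRVYR: 7 = 2011-2012, 8 = 2013-2014
    df["cycle"] = df["cycle"].replace({7: "A", 8: "B", 7.0: "A", 8.0: "B"})
    if not df["cycle"].isin(["A", "B"]).all():
        raise IntegrityError("cycle must be 'A' or 'B'")

    if (df["weight_2yr"] <= 0).any():
        bad = df.index[df["weight_2yr"] <= 0][0]
        raise IntegrityError(f"row {bad}: weight_2yr must be positive")

    df["eligible"] = df["age_years"] >= MIN_ELIGIBLE_AGE
    return df


def write_outputs(tables: dict[str, pd.DataFrame], out_dir, format="csv") -> dict:
    """Write named result tables plus a JSON schema manifest.

    Column order is preserved deterministically; a per-night/per-subject
    ``sleep_efficiency`` column, if present, is validated into [0, 1].
    Returns the manifest dict (also written as ``manifest.json``).
    """
    if not tables:
        raise ValueError("no tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "parquet" if format == "parquet" else "csv"
    manifest = {"format": format, "files": {}}
    for name, df in tables.items():
        if "sleep_efficiency" in df.columns:
            eff = df["sleep_efficiency"].dropna()
            if ((eff < 0) | (eff > 1)).any():
                raise IntegrityError(
                    f"table {name!r}: sleep_efficiency outside [0, 1]")
        fname = f"{name}.{ext}"
        _write_table(df, out_dir / fname, format)
        manifest["files"][name] = {
            "path": fname,
            "n_rows": int(len(df)),
            "columns": list(df.columns),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
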