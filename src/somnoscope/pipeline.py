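"""End-to-end orchestration: simulate -> preprocess -> score -> sleep
parameters -> survey analysis, with provenance.

Every stage's row counts feed an attrition manifest (subjects lost to the
4-valid-day rule, nights lost to SPT bounds, subjects lost to the
3-valid-night rule), mirroring a study-flowchart accounting.  All
randomness is threaded from one root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hmm, io, preprocess, simulate, sleep, survey

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults reproduce the canonical thresholds of the analysis:
    60-min missing intervals, > 16 h wear days, >= 4 valid days,
    3-15 h SPT bounds, >= 3 valid nights."""

    out_dir: str = "somnoscope_out"
    format: str = "csv"
    seed: int = 0
    # input: either paths to minute/demographic tables, or simulate
    minute_path: str | None = None
    demo_path: str | None = None
    simulate: dict = field(default_factory=dict)    # GeneratorConfig overrides
    # preprocessing
    impute_method: str = "minute_profile"
    min_interval: int = preprocess.DEFAULT_MIN_INTERVAL
    wear_min: int = preprocess.DEFAULT_WEAR_MINUTES
    min_valid_days: int = preprocess.DEFAULT_MIN_VALID_DAYS
    # HMM
    hmm_init: str = "quantile_split"
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 200
    decode_rule: str = "posterior"
    # sleep parameters
    merge_gap_max: int = sleep.DEFAULT_MERGE_GAP
    min_valid_nights: int = sleep.MIN_VALID_NIGHTS
    # analysis
    outcomes: tuple = ("mean_onset_clock", "mean_duration_h",
                       "mean_efficiency")
    interactions: tuple = ("sex", "race")
    allow_single_cycle: bool = True   # synthetic cohorts may draw one cycle

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("outcomes", "interactions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run all stages; write outputs and a provenance manifest.

    Returns the manifest dict, which includes the attrition counts and
    the config hash.  Result tables land in ``config.out_dir``.
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
    }

    def stage(name, t):
        manifest["stages"][name] = {"seconds": round(time.time() - t, 2)}
        return manifest["stages"][name]

    # --- input -----------------------------------------------------------
    t = time.time()
    truth = None
    if cfg.minute_path:
        minutes = io.read_minute_table(cfg.minute_path)
        demo = io.read_demographics(cfg.demo_path)
    else:
        gen = simulate.GeneratorConfig(
            **{"seed": cfg.seed, **cfg.simulate})
        minutes, demo, truth = simulate.generate_cohort(gen)
    info = stage("input", t)
    info["n_subjects"] = int(demo["subject_id"].nunique())
    info["n_minutes"] = int(len(minutes))

    # --- preprocess ------------------------------------------------------
    t = time.time()
    clean, day_qc, subject_qc = preprocess.preprocess(
        minutes, cfg.impute_method, cfg.min_interval, cfg.wear_min,
        cfg.min_valid_days, cfg.seed)
    info = stage("preprocess", t)
    info["n_eligible_subjects"] = int(subject_qc["eligible"].sum())
    info["n_dropped_4day_rule"] = int((~subject_qc["eligible"]).sum())

    # --- HMM scoring -----------------------------------------------------
    t = time.time()
    labels, models = hmm.score_cohort(
        clean, cfg.hmm_init, cfg.hmm_tol, cfg.hmm_max_iter,
        cfg.decode_rule, cfg.seed)
    info = stage("score", t)
    info["n_scored_subjects"] = int(models.loc[~models.get(
        "degenerate", pd.Series(dtype=bool)), :].shape[0]) if len(models) else 0
    info["n_degenerate"] = int(models["degenerate"].sum()) if len(models) else 0

    # --- sleep parameters ------------------------------------------------
    t = time.time()
    nights = sleep.score_nights(labels, cfg.merge_gap_max)
    subjects = sleep.aggregate_subject(nights, demo, cfg.min_valid_nights)
    info = stage("sleep_parameters", t)
    info["n_nights"] = int(len(nights))
    info["n_valid_nights"] = int(nights["valid"].sum())
    info["n_included_subjects"] = int(subjects["included"].sum())
    info["n_dropped_3night_rule"] = int((~subjects["included"]).sum())

    # --- survey analysis -------------------------------------------------
    t = time.time()
    weighted = survey.four_year_weights(
        subjects[subjects["included"] & subjects["eligible"]],
        allow_single_cycle=cfg.allow_single_cycle)
    tables = {
        "nights": nights,
        "subjects": subjects,
        "population_summary": survey.population_summary(
            weighted, cfg.outcomes),
        "quantiles_by_age": survey.age_group_quantile_table(
            weighted, cfg.outcomes),
    }
    coef_rows, curve_frames, wald_rows = [], [], []
    for oc in cfg.outcomes:
        try:
            model = survey.SurveyPolynomialTrend(
                oc, cfg.interactions).fit(weighted)
        except ValueError as err:
            # small cohorts can leave interaction blocks rank-deficient
            logger.warning("outcome %s: %s; refitting main effects only",
                           oc, err)
            model = survey.SurveyPolynomialTrend(oc, ()).fit(weighted)
        for name, b, se in zip(model.names_, model.params_, model.se_):
            coef_rows.append({"outcome": oc, "term": name,
                              "coef": b, "se": se})
        for term, w in model.wald_.items():
            wald_rows.append({"outcome": oc, "term": term, **w})
        curve_frames.append(model.curve_grid())
    ordinal = survey.efficiency_quartile_ordinal(weighted)
    for name, b, se in zip(ordinal.names_, ordinal.params_, ordinal.se_):
        coef_rows.append({"outcome": "efficiency_quartile_ordinal",
                          "term": name, "coef": b, "se": se})
    tables["coefficients"] = pd.DataFrame(coef_rows)
    tables["wald_tests"] = pd.DataFrame(wald_rows)
    tables["fitted_curves"] = pd.concat(curve_frames, ignore_index=True)
    if truth is not None:
        tables["truth_nights"] = truth
        tables["truth_subjects"] = simulate.truth_summary(truth)
    info = stage("analyze", t)
    info["n_analyzed_subjects"] = int(len(weighted))

    out = Path(cfg.out_dir)
    written = io.write_outputs(tables, out, cfg.format)
    manifest["outputs"] = written["files"]
    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
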