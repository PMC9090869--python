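# somnoscope

Sleep epidemiology from minute-level wrist accelerometry, in the shape of
the NHANES 2011–2014 24-hour accelerometer release: preprocessing of
per-minute MIMS activity summaries, unsupervised sleep/wake scoring with a
two-state hidden Markov model, sleep-period-time (SPT) window parameter
derivation, and design-based (complex survey) estimation of how clock time
of sleep onset (CTSO), sleep duration and sleep efficiency are distributed
by age, sex and race.

It is written for epidemiologists and sleep researchers who want a tested,
reproducible Python pipeline for actigraphy cohorts with a survey design —
and for method validation, since it ships a synthetic-cohort generator with
known ground truth that exercises every stage.

## The method

**Input.** Per subject-minute: a MIMS (Monitor-Independent Movement
Summary) triaxial activity value, a wear prediction
(wake-wear/sleep-wear/non-wear/unknown), and a data-quality flag count —
the layout of the NHANES PAXMIN files (`PAXMTSM`, `PAXPREDM`, `PAXQFM`,
loaded via a built-in alias map) — plus a demographics table with age, sex,
race, 2-year exam weight, stratum and PSU.

**Preprocessing.** A minute is missing iff its value is the −0.01 sentinel,
its wear prediction is non-wear, or it carries any quality flag.  Missing
runs of ≥ 60 min are imputable intervals (filled from the subject's own
minute-of-day profile, or a seeded zero-inflated draw); shorter runs count
as zero activity.  A day is valid with > 16 h of wear; subjects need ≥ 4
valid days.

**Sleep/wake scoring.** Per subject, a two-state Gaussian HMM on
y = log(1 + MIMS) over the whole concatenated series, fitted by Baum–Welch
EM (scaled forward–backward recursions; the lower-mean state is sleep).
Minutes are labelled by posterior decoding: sleep iff P(sleep | y) > 0.5.

**Sleep parameters.** In each noon-to-noon window, sleep runs separated by
wake gaps < 60 min are merged; the longest merged block is the SPT window.
With wake bouts W inside the SPT,

    CTSO       = 12 + (SPT start − noon)/60   (continuous 12–36 h clock; 1 am → 25)
    duration   = |SPT| − Σ|W|
    efficiency = duration / |SPT|

Nights with |SPT| < 3 h or > 15 h are excluded; subjects need ≥ 3 valid
nights.  A night is a weekend night when its noon anchor is Friday or
Saturday.

**Survey estimation.** 4-year weights (2-year/2 over two combined cycles),
Horvitz–Thompson means, weighted quantiles by the nine standard age groups,
and survey-weighted regression of each parameter on a quartic age trend
(age, age², age³, age⁴ on centred/scaled age), sex and race, with optional
sex×age and race×age interaction blocks; efficiency additionally gets a
survey-weighted proportional-odds model on its weighted quartiles.
Variances are Taylor-linearized (stratified, with-replacement PSUs); Wald
tests use the adjusted F with design df = n_PSU − n_strata.

## Worked example

```python
from somnoscope import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(
    out_dir="demo_out", seed=3, simulate={"n_subjects": 40}))
print({k: v for k, v in manifest["stages"]["sleep_parameters"].items()})
```

prints (seed 3, 40 subjects):

```
{'seconds': 0.55, 'n_nights': 320, 'n_valid_nights': 240,
 'n_included_subjects': 40, 'n_dropped_3night_rule': 0}
```

320 night rows are 40 subjects × 8 noon windows; the 240 valid ones are
the 6 complete windows per subject (the partial first/last windows hold
truncated sleep periods and are excluded), and every subject clears the
3-valid-night bar.  `demo_out/` then contains the per-night and
per-subject tables, a Table-1-style weighted summary, the age-group
quantile grid, coefficient/Wald tables and fitted age curves per sex and
race, plus `provenance.json` with the attrition accounting.

The same stages are available from a shell:

```bash
somnoscope simulate --seed 1 --n-subjects 50 --out cohort/
somnoscope run --seed 1 --out results/
```

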