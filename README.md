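# fingertap

Quantitative analysis of repetitive finger-opposition movements recorded
with a sensor-engineered glove: from raw touch-event streams to kinematic
parameters, test–retest reliability, patient/control discrimination and
clinical-scale correlations — plus a synthetic cohort simulator so the whole
pipeline is testable without access to raw recordings.

## What it computes

Each 60-s trial is a stream of thumb-to-finger contacts (fingers 2–5, one or
both hands, 1 kHz timestamps) in one of four conditions: spontaneous
velocity (`SV`), maximal velocity (`MV`), metronome-paced at 2 Hz (`2HZ`)
and bimanual metronome-paced (`2HZ_BIM`). From these the package extracts:

* **TD** — touch duration, the contact time per touch (ms)
* **ITI** — inter-tap interval, the gap between consecutive contacts (ms)
* **RATE** — movement rate, `1000 / (mean TD + mean ITI)` (Hz)
* **IHI** — inter-hand interval, the mean absolute onset difference between
  corresponding left/right touches in bimanual trials (ms); larger = worse
  bimanual coordination

Downstream analyses:

* `reliability` — two-way random-effects absolute-agreement ICC (single and
  average of two sessions), SEM, smallest real difference
  (`SRD = 1.96·√2·SEM`) and SRD% per parameter; IHI analysed on the natural
  log scale.
* `cohort_stats` — Mann–Whitney group comparisons, age-adjusted partial
  Spearman correlations with clinical scores (EDSS, MSFC, 9-HPT, T25W,
  PASAT, MFIS), linear-trend ANOVA across ordered EDSS strata.
* `discrimination` — forward stepwise logistic regression (likelihood-ratio
  entry at α = 0.05, age forced) building a composite impairment score;
  ROC with DeLong confidence intervals; leave-one-out cross-validation with
  the final feature set fixed (per-fold re-selection available).
* `simulate` — Gaussian-copula cohort generator: latent motor traits and
  clinical covariates with configurable rank-correlation targets, per-trial
  event streams with tone-locking error, cycle jitter, half-normal
  inter-hand asynchrony and a between-session random effect. The packaged
  `reference` profile is calibrated to published group statistics.

## CLI

```sh
# full pipeline on a simulated cohort (80 controls + 40 patients)
fingertap run --seed 7 --out runs/demo

# individual stages
fingertap simulate --profile reference --seed 7 --out runs/demo \
    --n-hc 27 --sessions 2
fingertap extract --events runs/demo/events.csv --tones runs/demo/tones.csv \
    --out runs/demo/params.csv
fingertap reliability --params runs/demo/params.csv --out runs/demo/reliability.csv
fingertap compare   --params ... --cohort ... --out comparison.csv
fingertap correlate --params ... --cohort ... --out correlations.csv
fingertap score     --params ... --cohort ... --out runs/demo
fingertap run --seed 7 --out runs/demo --skip reliability
```

All CSV outputs start with `#`-prefixed provenance lines (tool version,
seed, config hash); re-running with the same seed and config reproduces
every output byte.

File formats (plain CSV):

* events — `trial_id,subject_id,session,condition,hand,finger,t_on_ms,t_off_ms`
* tones — `trial_id,t_tone_ms`
* cohort — `subject_id,group,age,sex,edss,...` (clinical columns optional
  for controls)

## Layout

```
src/fingertap/
  glove_io.py        data model + CSV I/O, validation
  kinematics.py      TD / ITI / RATE / IHI extraction
  reliability.py     ICC, SEM, SRD
  cohort_stats.py    Mann-Whitney, partial Spearman, strata trend
  discrimination.py  stepwise logistic, ROC/DeLong, LOO-CV
  simulate.py        copula cohort + trial simulator
  cli.py             pipeline orchestration
tests/               unit, property and acceptance tests
scripts/acceptance.py
```
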