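# speechgaze

Eye-tracking analysis of **visual speech perception in children**: where
do 5–8-year-old deaf and hearing children look while watching a silently
speaking face, and does their gaze strategy predict how much of the
message they catch?

The package turns raw remote-eye-tracker logs (250 Hz, one gaze sample
per row) of children watching short silent talking-head videos into
per-participant attention metrics and group-level inference:

* **Moving AOIs** — two equal semicircular areas of interest (Eyes /
  Mouth) whose shared flat edge crosses the nose, anchored to facial
  landmarks and moving with the video.
* **%NDT** — percentage Net Dwell Time per AOI in each of the three
  trial segments (pre-speech, speech, post-speech), sample-based, with
  drift correction and strict quality control (a trial needs > 50%
  on-screen tracking during speech; a child needs ≥ 8 of 12 trials).
* **Social-tuning ratio (STR)** — a single score for the
  eyes-before-speech → mouth-during-speech → eyes-after-speech pattern:

  ```
  STR = (E_pre + M_speech + E_post)
        / (E_pre + M_pre + E_speech + M_speech + E_post + M_post)
  ```

  the pattern-concordant share of total eyes+mouth dwell mass, in
  [0, 1] with 0.5 as the indifference point (see `docs/methods.md` for
  why this operationalisation and how it is version-tagged).
* **Inference** — pooled/Welch t tests with Cohen's d (pooled SD in both
  variants), Pearson correlations with seeded percentile-bootstrap CIs,
  dummy-coded moderated regressions `y ~ x + g + x:g` with the
  drop-the-interaction reduction rule, and a composite reading score
  from summed z-scores.
* **Synthetic cohorts** — a gaze-stream generator with full ground truth
  (latent strategy per child, per-trial behaviour, outcome
  coefficients), used to validate the entire pipeline by parameter
  recovery. No real data ship with the package.

## Worked example

Simulate a study-sized cohort (29 deaf children split across a
speechreading-training and a maths-training arm, 29 hearing children)
and run the full analysis:

```bash
speechgaze all --seed 7 --out-dir demo/out   # dataset lands in ./data
```

or, controlling the data directory too, from Python:

```python
from speechgaze import pipeline
cfg = pipeline.PipelineConfig(data_dir="demo/data", out_dir="demo/out", seed=7)
pipeline.run_simulate(cfg)   # writes gaze.tsv, events.csv, landmarks.csv, ...
pipeline.run_analyze(cfg)    # QC -> metrics -> contrasts/correlations/regressions
```

The run logs every exclusion with the rule that fired
(`dropped trial p0002/2: on-screen fraction 0.429 <= 0.5` …) and prints
`demo/out/summary.txt`, which for this seed begins:

```
speechgaze analysis summary (n = 58, social-tuning formula pattern-mass-v1)

Group contrasts
  deaf vs hearing, mouth %NDT during speech: deaf M=62.43 SD=13.99 vs hearing M=69.32 SD=19.82; t(56.0) = -1.53, p = 0.132, d = -0.40 [pooled]
  deaf vs hearing, social-tuning ratio: deaf M=0.38 SD=0.05 vs hearing M=0.50 SD=0.09; t(44.8) = -6.86, p = 0.000, d = -1.80 [welch]
  ...

Metric-outcome correlations (percentile bootstrap 95% CI)
  deaf: mouth_ndt_speech ~ tocs_questions_score: r(27) = 0.491, p = 0.007, CI [0.215, 0.703]
  ...
```

Reading this: the simulated deaf group spends slightly less time on the
mouth during speech than the hearing group (62% vs 69% of the speech
window, a non-significant d of 0.40 at this sample size) but uses the
social-tuning pattern less consistently (STR 0.38 vs 0.50, a large and
significant difference); within groups, mouth dwell correlates with the
number of lexical items the simulated children "identify" (r ≈ .4–.5),
exactly the structure the generator planted. Alongside the summary the
run writes `metrics.csv` (per-child %NDT cells, mouth %NDT, STR, all
tagged with the formula version), QC reports, and machine-readable
`contrasts.csv` / `correlations.csv` / `regressions.csv` /
`report.json`, plus `resolved_config.yaml` so the run can be reproduced
from its outputs alone.

## Layout

```
src/speechgaze/
  geometry.py    semicircular AOI pair, point classification, landmark tracks
  gaze_io.py     gaze/event/correction I/O, drift correction, segmentation
  qc.py          trial and participant exclusion rules
  metrics.py     %NDT extraction, trial averaging, social-tuning ratio
  inference.py   t tests, bootstrap correlations, moderated regression
  simulate.py    synthetic cohorts with ground truth (sample & metric level)
  pipeline.py    simulate -> qc -> metrics -> analyze orchestration
  cli.py         click subcommand CLI
  plotting.py    one-trial diagnostic plot
```

`docs/methods.md` documents the model, every default and tolerance, what
the generator does and does not emulate, and known limitations.
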