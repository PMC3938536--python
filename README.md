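# ppa-speech

Acoustic speech biomarkers for differentiating logopenic (lvPPA) and
nonfluent (nfvPPA) variants of primary progressive aphasia:

* **Silence analysis** of a reading recording — range-relative intensity
  thresholding with three post-processing criteria, summarised as
  proportion of silence time (PST, arcsin-transformed), median silence
  duration, and the median absolute deviation (MAD) of silence duration.
* **Lexical-stress analysis** of repeated polysyllabic words — Pairwise
  Variability Indices (PVI) of vowel duration (ms) and peak vowel
  intensity for the first two vowels, reduced to per-subject medians over
  strong-weak (e.g. *dinosaur*) and weak-strong (e.g. *potato*) word sets.
* **Statistics & classification** — normality screening, one-way ANOVA
  with Tukey-HSD/Kramer post-hocs, an independent-samples median test,
  collinearity (|r| > 0.80) and Mahalanobis-distance screening, a
  two-group discriminant fit realised as OLS of a 0/1 group code, and the
  two published diagnostic index models with their printed coefficients
  (rounding the continuous index gives 0 = lvPPA, 1 = nfvPPA).
* **Synthetic data** — pseudo-speech audio with planted silence/vowel
  ground truth and cohort simulation from the published per-group feature
  means/SDs, so every stage is testable without patient recordings.

## CLI

```bash
ppa-speech silences reading.wav --out metrics.json              # silence metrics
ppa-speech pvi words.wav vowels.TextGrid --tier vowels --out pvi.csv
ppa-speech classify features.csv --model duration --out results.csv
ppa-speech fit features.csv --screen --out fit.json             # refit DFA
ppa-speech simulate-audio spec.json --seed 7 --out sim.wav --truth truth.json
ppa-speech simulate-cohort --seed 42 --out cohort.csv
ppa-speech run-subject reading.wav words.wav vowels.csv --out report.json
ppa-speech run-cohort cohort.csv --fit --screen --out report.json
```

Exit codes: 0 success, 2 validation error, 3 computation error.
Feature CSVs use the columns `subject_id, group, arcsin_pst,
mad_silence_s, median_silence_s, pvi_dur_ws, pvi_dur_sw, pvi_int_ws,
pvi_int_sw` (silence durations in **seconds**, PVI columns absolute).
Vowel annotations are either a CSV (`word, pattern, v1_on_s, v1_off_s,
v2_on_s, v2_off_s`) or a Praat TextGrid interval tier with labels
`word_V1` / `word_V2` (pattern suffix `_SW`/`_WS` for words outside the
built-in stimulus lists).

## Conventions

* Audio: mono, samples in [-1, 1]; intensity in dB relative to full
  scale (recordings are uncalibrated; silence thresholds are
  range-relative so the reference cancels). Default contour: 32 ms Hann
  window, 8 ms hop, -96 dB floor.
* Detected silence boundaries are frame-quantised and carry up to one
  analysis window (32 ms) of blur.
* Model 1's PVI coefficient sign is taken from its standardized
  coefficient/t statistic (the printed unstandardized value carries the
  opposite sign); both models accept coefficient overrides.
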