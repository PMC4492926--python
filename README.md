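# dxtrial

Toolkit for Bayesian diagnostic-test interpretation and for reproducing a
randomised trial of how test-accuracy information is presented to doctors.
It implements:

- **`dxtrial.bayes_core`** — sensitivity/specificity, likelihood ratios,
  odds-form pre-test → post-test updating, predictive values.
- **`dxtrial.presentations`** — the four presentation formats as data
  structures and deterministic SVGs: text summary, Fagan-style nomogram
  (base-10 log-odds axes), probability-modifying plot, natural frequency
  tree (largest-remainder integer counts).
- **`dxtrial.scoring`** — answer keys and correct/incorrect/blank rules for
  the vignette question (±1% margin, ±3% sensitivity analysis) and the
  five-item baseline-knowledge quiz.
- **`dxtrial.trial_analysis`** — arm tabulation, 2×2 odds ratios with Wald
  95% CIs (Haldane correction on zero cells), Pearson chi-squared
  heterogeneity, proportions, IRLS logistic regression, and the
  two-proportion minimal-detectable-difference power calculation.
- **`dxtrial.synthetic_cohort`** — a respondent-cohort generator
  parameterised by the published margins, including a deterministic
  exact-table fixture that reproduces the published outcome counts.
- **`dxtrial.study_cli`** — a `click` CLI tying the stages together.

## CLI

```sh
dxtrial interpret --pretest 50 --sens 60 --spec 90        # -> 86
dxtrial render --format tree --sens 60 --spec 90 --n 1000 --out tree.svg
dxtrial simulate --seed 7 --n 874 --out cohort.csv        # add --exact for the fixture
dxtrial score   --input cohort.csv --margin 1
dxtrial analyze --input cohort.csv --margin 1 --report report.json
dxtrial power   --n 200 --alpha 0.05 --power 0.8 --p 0.5  # -> 0.1401
dxtrial reproduce --outdir out   # full pipeline; exit 1 on any regression
```

`reproduce` writes `report.json`, a derived `report.md`, and the four SVG
figures, and checks all six published odds-ratio/CI pairs at two decimals.

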