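# tolrad

Predict whether a bacterium tolerates ionizing radiation from nothing but
its genome annotations.

Experimentally measuring a species' radiation tolerance — its D10, the
acute dose in gray at which only 10% of cells still form colonies —
requires an irradiation source and an isolated culture, which is why so
few radiosensitive bacteria are known. `tolrad` implements a
genotype-to-phenotype shortcut: a random-forest binary classifier that
labels a genome **radiosensitive** (D10 < 200 Gy) or **tolerant**
(D10 > 200 Gy) from the *relative frequencies* of Pfam protein-domain
annotations in its proteome,

```
freq_g(d) = (instances of domain d in genome g) / (all domain instances in g),
```

together with the full predictor-selection funnel used to build such a
classifier, an incomplete-genome robustness simulator for
metagenome-assembled genomes (MAGs), and a CFU-survival D10 estimator.
It is aimed at microbiologists and metagenomics practitioners who want
to screen genome collections (UniProt proteomes, EggNOG-Mapper-annotated
MAGs) for putative radiosensitive species.

## What is implemented

- **annotations_io** — parsers for two Pfam annotation dialects
  (per-protein TSV and EggNOG-Mapper `.emapper.annotations`), and
  genomes × domains frequency tables with raw counts.
- **labels** — D10 records, the 200 Gy binary labeling rule (mean of
  replicate D10 values, strict `<`), a quantile-cutoff diagnostic, and
  stratified train/test splits.
- **feature_selection** — the predictor funnel: domains universal to the
  training genomes → mean occurrence per genome > 2 → Boruta
  shadow-feature selection (maxRuns = 500) → stepwise pruning by
  permutation mean decrease in accuracy (MDA).
- **classifier** — random-forest training with mtry tuned by stratified
  10-fold CV, vote-fraction predictions, out-of-bag permutation MDA, and
  model persistence. Genomes missing ≥ 2 predictor domains are excluded
  from classification rather than guessed at.
- **mag_tools** — exact-fraction subsampling of annotation instances to
  emulate partial MAGs, degradation-robustness curves, cohort screening.
- **survival** — sham-baselined surviving fractions from CFU counts and
  D10 estimation under the log-linear (single-hit) survival model
  `log10 S(d) = -d / D10`.
- **synthetic** — cohort and assay generators with planted,
  ledger-documented ground truth, so the whole pipeline is testable
  without downloads.

## Worked example

Simulate a 16-genome cohort with four planted informative domains, train
on it, and classify it:

```sh
tolrad simulate --out-dir cohort --seed 7 --n-per-class 8 --n-noise-domains 30
tolrad build-features --annotations-dir cohort --dialect pfam --out feats.tsv
tolrad train --features feats.tsv --labels cohort/labels.tsv \
  --predictors PF77001,PF77002,PF77003,PF77004 \
  --seed 7 --cv-folds 5 --n-trees 200 --out-dir model
tolrad classify --model model --annotations-dir cohort --dialect eggnog --out report.tsv
```

prints (among log lines):

```
cv_accuracy=1.0000 mtry=1 -> model
classified 16, excluded 0 -> report.tsv
```

`cv_accuracy` is the stratified cross-validated accuracy at the selected
mtry — 1.0 here because the planted class signal is strong. The report
has one row per genome:

```
genome_id  predicted_class  vote_fraction_radiosensitive  n_zero_predictors  excluded
rad_000    radiosensitive   1.000000                      0                  False
```

`vote_fraction_radiosensitive` is the fraction of forest trees voting
radiosensitive; `n_zero_predictors` counts predictor domains absent from
the genome (at ≥ 2 the row is excluded and carries no class).

Fitting a D10 from a CFU assay (dose-0 rows are the sham baseline):

```sh
tolrad fit-d10 --assay assay.csv --out fit.json
# D10 = 110.3 Gy (loglinear) -> fit.json
```

A D10 of 110 Gy means ~10% survival at 110 Gy and a predicted
`10^(-200/110)` ≈ 1.5% survival at 200 Gy.

The same operations are available as library functions
(`tolrad.boruta_select`, `tolrad.train`, `tolrad.degradation_curve`,
`tolrad.fit_d10`, ...); see the module docstrings and
[docs/methods.md](docs/methods.md) for the underlying models and design
choices.

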