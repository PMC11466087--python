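# Example configuration

`tolrad.config.json` holds the default run parameters (200 Gy labeling
cutoff, 10-fold CV, 500-tree forests, Boruta maxRuns 500, exclusion at
2 missing predictors); pass it to any subcommand with `--config` —
explicit flags win over config values.

For classifying real genome collections the most widely quoted
four-domain predictor set for this kind of radiation-tolerance
classifier is

    PF03466,PF07992,PF00300,PF00849

(pass via `tolrad train --predictors ...`). Published sources disagree
internally about the fourth domain and about two name/ID pairings (see
docs/methods.md), so treat the list as illustrative; the selection
funnel (`tolrad select-features`) derives a predictor set from your own
training cohort.
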