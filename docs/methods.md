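# Methods

This note documents the models and procedures `tolrad` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Labels and the 200 Gy cutoff

A species' ionizing-radiation tolerance is summarised by its D10: the
acute dose (Gy) at which 10% of exposed cells form viable colonies.
Species with several published D10 values are summarised by the
arithmetic mean. The binary label is *radiosensitive* when the mean D10
is strictly below the cutoff (default 200 Gy) and *tolerant* otherwise;
a mean exactly at the cutoff is tolerant. The 200 Gy default
corresponds to the lower tail of the strongly right-skewed distribution
of published bacterial D10 values (roughly its lower quarter/quintile —
the two descriptions coincide at 200 Gy on that distribution but differ
in general, which is why `quantile_cutoff` is provided only as a
diagnostic and never relabels by default). Everything above the cutoff
is collapsed into one tolerant class: the classifier does not grade
tolerance.

`stratified_split` draws per-class `round(fraction × class size)`
training members. Published cohorts of this kind were often split plain
randomly; stratification is the safer default on ~60-genome cohorts
with a ~1:3 class imbalance, where an unlucky random split can starve a
fold of the minority class.

## Pfam frequency features

A genome's feature vector is the relative frequency of each Pfam domain:
instance count divided by the total number of domain instances in the
proteome. Counting is by *instance* with multiplicity — a domain
occurring three times in one protein contributes three — because the
annotation dialects list repeats and because per-proteome mean
occurrences of useful predictors are far above one. Version suffixes
(`PF00300.23`) are stripped; clan structure is ignored. When a table is
restricted to a predictor subset, the denominator stays the
full-proteome total, so subset rows sum to less than 1 and an absent
domain is exactly 0 (never missing). A zero-instance annotation set has
no defined frequencies and is an explicit error.

## Predictor-selection funnel

1. **Universality**: keep domains with ≥ 1 instance in every training
   genome. Rationale: a predictor that can be absent for ordinary
   lineage reasons would confound absence-by-incompleteness in MAGs and
   overfit rare domains.
2. **Abundance**: keep domains with mean occurrence per genome strictly
   greater than 2 (boundary excluded).
3. **Boruta**: each iteration appends one independently permuted
   "shadow" copy of every undecided feature, fits a random forest
   (default 100 trees, √p features per split) on real + shadow columns,
   and scores importance as out-of-bag mean decrease in accuracy (MDA).
   A real feature scores a hit when it beats the best shadow. Hits are
   tested against Binomial(n_iterations, ½) two-sidedly at α = 0.05
   with Bonferroni correction across the currently undecided features;
   significantly-many hits confirm, significantly-few reject. After
   `max_runs` (default 500) undecided features are *tentative* and are
   treated as not selected downstream, favouring parsimony. Zero-variance
   features are auto-rejected up front with a warning. The α level and
   correction are exposed as configuration since the canonical
   description leaves them open.
4. **Stepwise pruning**: repeatedly consider removing the
   lowest-MDA predictor (lexicographic tie-break for determinism). A
   removal is accepted when (a) the stratified CV accuracy of the
   reduced set is at least that of the current set *and* (b) the
   candidate's MDA is at most `mda_threshold` (default 2.5 percentage
   points). Condition (b) is this package's design choice for an
   otherwise underdetermined stopping rule: on cleanly separable
   cohorts every subset of mutually redundant informative predictors
   ties at CV accuracy 1.0, so an accuracy comparison alone would prune
   the set to a single predictor even though each member demonstrably
   carries signal. The threshold sits in the measured gap between the
   spurious importance of uninformative predictors on desk-scale
   cohorts (up to ~1.5 points, because small-sample forests partially
   memorise noise columns) and the importance of redundant informative
   predictors (~10 points and above). The audit trail records every
   candidate, both accuracies, the candidate's importance, and the
   decision; the result is never empty.

## Classifier

A scikit-learn random forest (default 500 trees) on the predictor
frequencies. The per-split feature count mtry is tuned over
{1..n_predictors} by stratified k-fold CV accuracy (default 10 folds;
ties to the smallest mtry), then the forest is refit on all data.
Stratified folds are essential at these cohort sizes (10 folds on 40
genomes with 10 minority members would otherwise risk minority-free
folds). Prediction reports the fraction of trees voting radiosensitive;
an exactly tied vote goes to tolerant, the majority class —
conservative for a screen whose purpose is flagging sensitives.

**Missing predictors.** A genome's predictor with frequency exactly 0 is
counted missing. At ≥ 2 missing (configurable) the genome is excluded
from classification and carries no class; with exactly 1 missing it is
still classified. Excluded genomes are never counted in accuracy
denominators.

**Permutation importance** is out-of-bag MDA on the percent scale:
per-tree OOB accuracy minus OOB accuracy after permuting one column,
averaged over trees and `n_repeats` independent permutations, × 100.
scikit-learn does not expose per-tree bootstrap masks publicly; they
are reconstructed from each tree's stored seed (the documented draw
`RandomState(seed).randint(0, n, n)` as int32), and the test-suite
cross-checks the reconstruction against the forest's own
`oob_decision_function_`. Permuting a constant column is exactly a
no-op, so constant features score identically 0.

**Persistence** is a directory bundle: a JSON sidecar (format version,
predictors, tuning metadata) plus the joblib-serialised ensemble.
Prediction column order comes from the fitted forest itself, so the
sidecar's predictor list is metadata and reordering it cannot change
predictions.

## MAG degradation model

Partial MAGs are emulated by drawing exactly `round(f × N)` of a
genome's N domain instances uniformly without replacement (fixed
completeness levels, not Bernoulli thinning), preserving protein
grouping. The degradation unit is the annotation *instance*, not the
unique domain or the contig; instance-level sampling produces the
gradual predictor loss seen in real incomplete assemblies, and a
unique-domain alternative would discard the abundance information the
classifier uses. Composing degradations multiplies fractions up to
rounding: `round(g·round(f·N))` retained. After degradation,
frequencies are recomputed against the *degraded* total before
reclassification. Percent correct at each completeness level is scored
among non-excluded genomes only, and the distribution of
missing-predictor counts is tallied per level.

## Survival model and D10 fitting

Within each biological replicate the baseline is the mean sham (0 Gy)
plate count; every dosed technical replicate yields surviving fraction
count/baseline (fractions can exceed 1; all counts are assumed
dilution-adjusted to a common scale). The default dose-response is the
classical single-hit exponential, linear in log survival and
constrained through the origin (zero-dose survival ≡ 1):

    log10 S(d) = -d / D10,  fitted by least squares on (d, log10 S),
    slope = Σ d·log10 S / Σ d²,  D10 = -1/slope.

This is the model under which D10 is well defined and a single point
(200 Gy, 0.1) identifies D10 = 200 Gy exactly. Points with fraction ≤ 0
cannot be log-transformed; they are dropped with a warning and counted
(a pseudo-count alternative was considered and rejected as the default
because it biases the slope at the doses that matter most). A fitted
slope ≥ 0 raises "no dose-dependent killing detected". A two-parameter
logistic in log dose is available behind `model="logistic"` for
shouldered curves; its D10 is read off where the fitted curve crosses
S = 0.1. Neither form claims to reproduce any particular published
fitting choice, which is typically unstated.

## Synthetic data: what it emulates, what it does not

`generate_cohort` plants class-conditional frequency shifts — the
statistical structure the classifier assumes — on a background of
uninformative domains. Per genome: the total instance count N is
uniform on `total_instances_range`; each informative domain's expected
frequency is drawn from a truncated normal (support (0,1)) around its
class mean; the remaining budget is split across noise domains by a
symmetric Dirichlet; realised counts are one multinomial draw of size
N; instances are shuffled into fixed-size records of 5 per synthetic
protein (protein grouping matters only to parser round-trips, not to
any downstream arithmetic). An infeasible budget (informative means
plus 6 sd reaching 1) errors before any draw. The ledger stores every
drawn expectation and realised count, making the cohort independently
recomputable; regeneration from (spec, seed) is bit-identical.

Defaults (the study conditions used throughout the test-suite): 20
genomes per class; four informative domains with class means between
0.02 and 0.08 and sd 0.005 — class-mean gaps of 6–12 sd, comfortably
above the 4-sd floor that makes a domain individually informative; 200
noise domains at Dirichlet concentration 1; 3,000–6,000 instances per
genome, a small-bacterial-proteome scale. Because Dirichlet(1)
backgrounds make some noise domains rare, a realistic fraction of them
fails the universality filter, as rare domains do in real cohorts.

What the generator does **not** emulate: phylogenetic correlation
between genomes (real cohorts are not i.i.d. within class),
annotation-pipeline error, domain co-occurrence structure within
proteins, and presence/absence signals (the planted signal is purely
frequency-shift, mirroring what the classifier consumes). Passing tests
therefore demonstrate the pipeline's statistical machinery, not its
accuracy on real proteomes.

`generate_survival` draws counts Poisson(baseline × 10^(−d/D10) ×
lognormal(1, cv)) with sham counts Poisson(baseline × lognormal(1, cv));
the lognormal is mean-1 (μ = −σ²/2). Defaults: 3 doses × 3 technical ×
3 biological replicates, cv = 5%, baseline 10⁵ dilution-adjusted
counts, which keeps Poisson noise small relative to plating noise; a
baseline below 10 warns of unstable fits.

## Numerical and interface choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; seeded reruns are byte-identical.
- Quantiles use linear interpolation; per-class train sizes round half
  up; Boruta/stepwise ties break lexicographically on domain id.
- EggNOG parsing takes only `#query` and `PFAMs` columns, ignores other
  columns silently (versions of that tool vary), treats `-` as "no
  domains", stops at a terminal `##` footer, and tolerates CRLF and
  trailing blank lines. Malformed accession tokens are skipped with a
  warning and tallied per file.
- The example predictor set used in documentation (PF03466, PF07992,
  PF00300, PF00849) follows the most widely quoted four-domain list for
  this classifier; published sources disagree internally (one table
  lists PF13411 in place of PF00849 and swaps two name/ID pairings), so
  the list should be treated as illustrative, not canonical.
- Known limitations: forests give no coefficients to interpret;
  desk-scale cohorts make importance estimates noisy (hence the
  stepwise importance floor); exclusion by missing predictors is a
  proxy, not a completeness estimate; the log-linear survival model has
  no shoulder term (use the logistic flag for shouldered data).
- Problem sizes in the test-suite and acceptance script (20-seed
  simulation loops, 20+20-genome cohorts, 100-tree Boruta forests,
  500-tree classifiers) were chosen as the smallest sizes at which the
  measured properties are stable.
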