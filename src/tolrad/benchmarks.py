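"""Property-style benchmark runs over synthetic cohorts.

These routines regenerate the study conditions from scratch and measure
the package's behaviour on them: frequency-tally agreement against an
independent oracle, predictor-funnel recovery of planted domains,
classifier accuracy on separated and label-permuted cohorts,
degradation monotonicity, the missing-predictor exclusion rule, D10
recovery, and determinism of seeded pipelines.  They back both the
acceptance test-suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tolrad.annotations_io import (
    PfamAnnotationSet,
    build_frequency_table,
    compute_frequencies,
)
from tolrad.classifier import permutation_importance, predict, train
from tolrad.feature_selection import (
    boruta_select,
    filter_abundant,
    filter_universal,
    stepwise_prune,
)
from tolrad.mag_tools import degradation_curve
from tolrad.survival import fit_d10, surviving_fraction
from tolrad.synthetic import PlantedCohortSpec, generate_cohort, generate_survival

PLANTED_DOMAINS = ["PF77001", "PF77002", "PF77003", "PF77004"]


def frequency_oracle_errors(n_sets: int = 1000, seed: int = 0) -> tuple[float, float]:
    """(max |freq - oracle|, max |row sum - 1|) over random annotation sets.

    The oracle is an independent flat tally over the instance stream.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    max_rowsum_dev = 0.0
    for _ in range(n_sets):
        n_dom = int(rng.integers(1, 12))
        domains = [f"PF{20000 + i:05d}" for i in range(n_dom)]
        records = []
        for p in range(int(rng.integers(1, 8))):
            picks = rng.integers(0, n_dom, size=int(rng.integers(0, 6)))
            records.append((f"p{p}", [domains[int(j)] for j in picks]))
        aset = PfamAnnotationSet("g", records)
        if aset.total_instances == 0:
            continue
        flat = [d for _, doms in aset.records for d in doms]
        oracle = Counter(flat)
        freqs = compute_frequencies(aset)
        for d, f in freqs.items():
            max_err = max(max_err, abs(f - oracle[d] / len(flat)))
        max_rowsum_dev = max(max_rowsum_dev, abs(sum(freqs.values()) - 1.0))
    return max_err, max_rowsum_dev


def run_funnel(seed: int, spec: PlantedCohortSpec | None = None) -> tuple[int, int]:
    """Full predictor funnel on a planted cohort → (n planted kept, n noise kept)."""
    spec = spec or PlantedCohortSpec(seed=seed)
    sets, labels, ledger = generate_cohort(spec)
    y = np.array([labels[s.genome_id] for s in sets])
    universal = filter_universal(sets)
    abundant = filter_abundant(sets, universal)
    table = build_frequency_table(sets, domains=abundant)
    result = boruta_select(table, y, max_runs=500, seed=seed)
    final = result.confirmed
    if len(final) >= 2:
        final, _ = stepwise_prune(table.restrict(final), y, final, cv_folds=10, seed=seed)
    planted = set(ledger["informative_domains"])
    return len(set(final) & planted), len(set(final) - planted)


def funnel_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Seeds on which the funnel keeps ≥3 of 4 planted and ≤1 noise domain."""
    kept_planted, kept_noise, successes = [], [], 0
    for i in range(n_seeds):
        n_p, n_n = run_funnel(seed=base_seed + i)
        kept_planted.append(n_p)
        kept_noise.append(n_n)
        successes += (n_p >= 3) and (n_n <= 1)
    return {
        "successes": successes,
        "n_seeds": n_seeds,
        "mean_planted": float(np.mean(kept_planted)),
        "mean_noise": float(np.mean(kept_noise)),
    }


@dataclass
class SeparatedCohort:
    sets: list
    labels: dict
    y: np.ndarray
    table: object  # FrequencyTable restricted to planted predictors


def make_separated_cohort(seed: int = 0) -> SeparatedCohort:
    sets, labels, _ = generate_cohort(PlantedCohortSpec(seed=seed))
    y = np.array([labels[s.genome_id] for s in sets])
    table = build_frequency_table(sets, domains=PLANTED_DOMAINS)
    return SeparatedCohort(sets=sets, labels=labels, y=y, table=table)


def null_cv_accuracies(cohort: SeparatedCohort, n_seeds: int = 20, base_seed: int = 0) -> list[float]:
    """CV accuracies after label permutation (class structure destroyed)."""
    accs = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + 1000 + i)
        y_perm = rng.permutation(cohort.y)
        model = train(cohort.table, y_perm, cv_folds=10, n_trees=500, seed=base_seed + i)
        accs.append(model.cv_accuracy)
    return accs


def constant_feature_mdas(cohort: SeparatedCohort, n_seeds: int = 20, base_seed: int = 0) -> list[float]:
    """Permutation MDA of an appended constant column under n_seeds permutation seeds."""
    df = cohort.table.frequencies.copy()
    df["PF00042"] = 0.01
    model = train(df, cohort.y, cv_folds=10, n_trees=500, seed=base_seed)
    return [
        permutation_importance(model, df, cohort.y, n_repeats=5, seed=base_seed + i)[
            "PF00042"
        ]
        for i in range(n_seeds)
    ]


def degradation_summary(cohort: SeparatedCohort, model, replicates: int = 20, seed: int = 0):
    """Mean percent-correct and missing-predictor curves over f = 1.0 … 0.5."""
    report = degradation_curve(
        cohort.sets,
        cohort.labels,
        model,
        fractions=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5),
        replicates=replicates,
        seed=seed,
    )
    return report.mean_percent_correct(), report.mean_missing_predictors()


def exclusion_rule_outcomes(model) -> dict:
    """Behaviour of the ≥2-missing-predictor exclusion rule on crafted rows."""
    base = pd.DataFrame(
        [[0.05, 0.04, 0.05, 0.04]], columns=PLANTED_DOMAINS, index=["full"]
    )
    one = base.rename(index={"full": "one_missing"}).copy()
    one.iloc[0, 0] = 0.0
    two = base.rename(index={"full": "two_missing"}).copy()
    two.iloc[0, :2] = 0.0
    allz = pd.DataFrame([[0.0] * 4], columns=PLANTED_DOMAINS, index=["all_missing"])
    frame = predict(model, pd.concat([base, one, two, allz])).frame.set_index("genome_id")
    return {
        "two_missing_excluded": bool(frame.loc["two_missing", "excluded"]),
        "all_missing_excluded": bool(frame.loc["all_missing", "excluded"]),
        "one_missing_classified": bool(not frame.loc["one_missing", "excluded"]),
        "excluded_have_no_class": frame[frame["excluded"]]["predicted_class"].isna().all(),
    }


def d10_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Within-10% D10 recovery under 5% CV noise for 70/110/400 Gy truths."""
    truths = (70.0, 110.0, 400.0)
    per_truth: dict[float, int] = {}
    rel_errors = []
    for true_d10 in truths:
        ok = 0
        for i in range(n_seeds):
            assay = generate_survival(
                true_d10,
                doses=[0.5 * true_d10, true_d10, 1.5 * true_d10],
                cv=0.05,
                n_technical=3,
                n_biological=3,
                seed=base_seed + i,
            )
            pts = [(d, f) for d, f, _ in surviving_fraction(assay)]
            fit = fit_d10(pts)
            rel = abs(fit.d10_gy - true_d10) / true_d10
            rel_errors.append(rel)
            ok += rel <= 0.10
        per_truth[true_d10] = ok
    return {
        "within_10pct_per_truth": per_truth,
        "within_10pct_total": sum(per_truth.values()),
        "n_fits": len(truths) * n_seeds,
        "max_rel_error": float(max(rel_errors)),
        "per_truth_seeds": n_seeds,
    }
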