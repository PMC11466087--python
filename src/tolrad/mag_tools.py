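"""Incomplete-MAG simulation, degradation-robustness curves, and cohort screening.

Metagenome-assembled genomes are usually partial.  ``degrade`` emulates
that by subsampling a genome's flattened multiset of Pfam domain
instances down to an exact retained fraction; ``degradation_curve``
re-annotates, re-normalises (the frequency denominator is the degraded
total) and re-classifies degraded cohorts to chart how accuracy and
missing-predictor counts respond to incompleteness; ``screen_collection``
applies a trained model to a genome collection with completeness-aware
exclusion accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tolrad.annotations_io import PfamAnnotationSet, build_frequency_table
from tolrad.classifier import ClassificationReport, TrainedModel, predict
from tolrad.labels import RADIOSENSITIVE, TOLERANT

__all__ = ["DegradationReport", "degrade", "degradation_curve", "screen_collection", "ScreenSummary"]


def degrade(aset: PfamAnnotationSet, fraction: float, seed: int) -> PfamAnnotationSet:
    """Subsample a genome to an exact retained fraction of domain instances.

    Retains exactly ``round(fraction * total_instances)`` instances,
    drawn uniformly without replacement from the flattened instance
    multiset; protein grouping is preserved for retained instances.
    Deterministic for a fixed seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    total = aset.total_instances
    if total < 1:
        raise ValueError(f"genome {aset.genome_id!r} has no domain instances")
    k = int(np.floor(fraction * total + 0.5))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {total} instances rounds to 0 retained "
            f"for genome {aset.genome_id!r}"
        )
    rng = np.random.default_rng(seed)
    keep_flags = np.zeros(total, dtype=bool)
    keep_flags[rng.choice(total, size=k, replace=False)] = True
    records: list[tuple[str, list[str]]] = []
    pos = 0
    for pid, doms in aset.records:
        kept = [d for j, d in enumerate(doms) if keep_flags[pos + j]]
        pos += len(doms)
        records.append((pid, kept))
    return PfamAnnotationSet(genome_id=aset.genome_id, records=records)


@dataclass
class DegradationReport:
    """Accuracy and missing-predictor tallies across completeness levels.

    ``curve``: one row per (fraction, replicate) with percent_correct
    among non-excluded genomes plus classified/excluded counts.
    ``missing``: per-fraction distribution of n_zero_predictors.
    """

    curve: pd.DataFrame
    missing: pd.DataFrame
    fractions: list[float]

    def mean_percent_correct(self) -> pd.Series:
        return self.curve.groupby("fraction")["percent_correct"].mean()

    def mean_missing_predictors(self) -> pd.Series:
        grp = self.missing.groupby("fraction")
        return grp.apply(
            lambda d: float(np.average(d["n_zero_predictors"], weights=d["count"])),
            include_groups=False,
        )


def degradation_curve(
    sets: list[PfamAnnotationSet],
    classes: dict[str, str],
    model: TrainedModel,
    fractions: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5),
    replicates: int = 10,
    seed: int = 0,
    exclusion_threshold: int = 2,
) -> DegradationReport:
    """Degrade, re-normalise, re-classify, and score each completeness level.

    For every fraction × replicate each genome is independently degraded,
    frequencies are recomputed against the degraded total, the model
    predicts, and percent correct is scored among non-excluded genomes
    only (excluded genomes are never counted as wrong).
    """
    if not sets:
        raise ValueError("need at least one annotation set")
    seedseq = np.random.SeedSequence(seed)
    curve_rows = []
    missing_rows: dict[tuple[float, int], int] = {}
    for fraction in fractions:
        for rep in range(replicates):
            child = np.random.default_rng(seedseq.spawn(1)[0])
            degraded = [
                degrade(s, fraction, seed=int(child.integers(2**31 - 1))) for s in sets
            ]
            table = build_frequency_table(degraded, domains=model.predictor_domains)
            report = predict(model, table, exclusion_threshold=exclusion_threshold)
            df = report.frame
            for nz in df["n_zero_predictors"]:
                key = (fraction, int(nz))
                missing_rows[key] = missing_rows.get(key, 0) + 1
            scored = df[~df["excluded"]]
            truth = scored["genome_id"].map(classes)
            n_classified = len(scored)
            pct = (
                float((scored["predicted_class"] == truth).mean())
                if n_classified
                else np.nan
            )
            curve_rows.append(
                {
                    "fraction": fraction,
                    "replicate": rep,
                    "percent_correct": pct,
                    "n_classified": n_classified,
                    "n_excluded": int(df["excluded"].sum()),
                }
            )
    curve = pd.DataFrame(curve_rows)
    missing = pd.DataFrame(
        [
            {"fraction": f, "n_zero_predictors": nz, "count": c}
            for (f, nz), c in sorted(missing_rows.items())
        ]
    )
    return DegradationReport(curve=curve, missing=missing, fractions=list(fractions))


@dataclass
class ScreenSummary:
    """Cohort screening result: per-genome report plus aggregates."""

    report: ClassificationReport
    n_total: int
    n_classified: int
    n_excluded: int
    n_radiosensitive: int
    n_tolerant: int
    fraction_radiosensitive: float
    by_phylum: pd.DataFrame | None = None


def screen_collection(
    sets: list[PfamAnnotationSet],
    model: TrainedModel,
    taxonomy: dict[str, str] | None = None,
    exclusion_threshold: int = 2,
) -> ScreenSummary:
    """Classify a genome collection and aggregate class/exclusion counts.

    ``fraction_radiosensitive`` is computed among classified (non-excluded)
    genomes.  When a genome→phylum taxonomy is supplied, a per-phylum
    breakdown of classified counts is included.
    """
    table = build_frequency_table(sets, domains=model.predictor_domains)
    report = predict(model, table, exclusion_threshold=exclusion_threshold)
    df = report.frame
    classified = df[~df["excluded"]]
    n_rs = int((classified["predicted_class"] == RADIOSENSITIVE).sum())
    n_tol = int((classified["predicted_class"] == TOLERANT).sum())
    by_phylum = None
    if taxonomy is not None:
        tmp = classified.assign(phylum=classified["genome_id"].map(taxonomy))
        by_phylum = (
            tmp.groupby(["phylum", "predicted_class"], dropna=False)
            .size()
            .rename("count")
            .reset_index()
        )
    return ScreenSummary(
        report=report,
        n_total=len(df),
        n_classified=len(classified),
        n_excluded=int(df["excluded"].sum()),
        n_radiosensitive=n_rs,
        n_tolerant=n_tol,
        fraction_radiosensitive=(n_rs / len(classified)) if len(classified) else float("nan"),
        by_phylum=by_phylum,
    )
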