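"""Synthetic annotation cohorts and survival assays with known ground truth.

The cohort generator plants class-informative Pfam-domain frequency
shifts — the statistical structure the classifier assumes — against a
background of uninformative domains: per genome, informative-domain
frequencies are drawn from truncated normals around class-specific
means, the remaining frequency budget is spread over noise domains by a
symmetric Dirichlet draw, and integer instance counts are realised by a
single multinomial of the genome's total instance count.  A ledger
records every drawn frequency and realised count, so any downstream
quantity can be recomputed independently.

The survival generator produces Poisson CFU counts around a log-linear
dose-response with multiplicative lognormal noise.

Defaults describe the study conditions used throughout the test-suite:
20 genomes per class, four planted domains with class-mean gaps of at
least 4 standard deviations, 200 noise domains, and 3,000–6,000 domain
instances per genome (a small-bacterial-proteome scale).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from tolrad.annotations_io import (
    PfamAnnotationSet,
    write_eggnog_annotations,
    write_pfam_table,
)
from tolrad.labels import RADIOSENSITIVE, TOLERANT
from tolrad.survival import BiologicalReplicate, SurvivalAssay

__all__ = [
    "InformativeDomain",
    "PlantedCohortSpec",
    "generate_cohort",
    "generate_survival",
    "write_cohort",
]

_PROTEIN_SIZE = 5  # domain instances per synthetic protein record


@dataclass(frozen=True)
class InformativeDomain:
    """A planted domain with class-conditional mean frequencies."""

    domain_id: str
    mean_radiosensitive: float
    mean_tolerant: float
    sd: float


DEFAULT_INFORMATIVE = (
    InformativeDomain("PF77001", 0.080, 0.020, 0.005),
    InformativeDomain("PF77002", 0.020, 0.080, 0.005),
    InformativeDomain("PF77003", 0.060, 0.030, 0.005),
    InformativeDomain("PF77004", 0.030, 0.060, 0.005),
)


@dataclass
class PlantedCohortSpec:
    """Study conditions for a planted-signal cohort."""

    n_per_class: int = 20
    informative_domains: tuple[InformativeDomain, ...] = DEFAULT_INFORMATIVE
    n_noise_domains: int = 200
    noise_frequency_concentration: float = 1.0
    total_instances_range: tuple[int, int] = (3000, 6000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_frequency_concentration <= 0:
            raise ValueError("noise_frequency_concentration must be > 0")
        lo, hi = self.total_instances_range
        if not (1 <= lo <= hi):
            raise ValueError("total_instances_range must satisfy 1 <= lo <= hi")
        for dom in self.informative_domains:
            for m in (dom.mean_radiosensitive, dom.mean_tolerant):
                if not 0 < m < 1:
                    raise ValueError(f"{dom.domain_id}: mean frequencies must be in (0,1)")
            if dom.sd < 0:
                raise ValueError(f"{dom.domain_id}: sd must be >= 0")
        for cls_means in (
            [d.mean_radiosensitive for d in self.informative_domains],
            [d.mean_tolerant for d in self.informative_domains],
        ):
            budget = sum(cls_means) + 6 * sum(d.sd for d in self.informative_domains)
            if budget >= 1 and self.n_noise_domains > 0:
                raise ValueError(
                    "infeasible frequency budget: informative means (+6 sd) "
                    f"sum to {budget:.3f} >= 1"
                )


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(
    spec: PlantedCohortSpec,
) -> tuple[list[PfamAnnotationSet], dict[str, str], dict]:
    """Generate (annotation sets, class labels, ground-truth ledger).

    Deterministic per ``spec.seed``; the ledger holds, per genome, the
    class, total instance count, every drawn expected frequency, and the
    realised multinomial counts.
    """
    rng = np.random.default_rng(spec.seed)
    noise_ids = [f"PF{10001 + i:05d}" for i in range(spec.n_noise_domains)]
    info_ids = [d.domain_id for d in spec.informative_domains]
    all_ids = info_ids + noise_ids
    lo, hi = spec.total_instances_range
    sets: list[PfamAnnotationSet] = []
    labels: dict[str, str] = {}
    ledger_genomes: dict[str, dict] = {}
    for cls in (RADIOSENSITIVE, TOLERANT):
        for i in range(spec.n_per_class):
            gid = f"{cls[:3]}_{i:03d}"
            n_total = int(rng.integers(lo, hi + 1))
            probs = np.empty(len(all_ids))
            for j, dom in enumerate(spec.informative_domains):
                mean = dom.mean_radiosensitive if cls == RADIOSENSITIVE else dom.mean_tolerant
                probs[j] = _draw_truncnorm(rng, mean, dom.sd)
            remainder = 1.0 - probs[: len(info_ids)].sum()
            if remainder <= 0:
                raise ValueError(f"{gid}: informative frequency draws exhausted the budget")
            if noise_ids:
                conc = np.full(len(noise_ids), spec.noise_frequency_concentration)
                probs[len(info_ids):] = remainder * rng.dirichlet(conc)
            counts = rng.multinomial(n_total, probs / probs.sum())
            instances = np.repeat(np.arange(len(all_ids)), counts)
            rng.shuffle(instances)
            records: list[tuple[str, list[str]]] = []
            for p, start in enumerate(range(0, len(instances), _PROTEIN_SIZE)):
                chunk = instances[start : start + _PROTEIN_SIZE]
                records.append((f"{gid}_p{p:05d}", [all_ids[j] for j in chunk]))
            sets.append(PfamAnnotationSet(genome_id=gid, records=records))
            labels[gid] = cls
            ledger_genomes[gid] = {
                "class": cls,
                "total_instances": n_total,
                "expected_frequencies": {
                    d: float(p) for d, p in zip(all_ids, probs / probs.sum())
                },
                "realized_counts": {
                    d: int(c) for d, c in zip(all_ids, counts) if c > 0
                },
            }
    ledger = {
        "spec": asdict(spec),
        "informative_domains": info_ids,
        "noise_domains": noise_ids,
        "genomes": ledger_genomes,
    }
    return sets, labels, ledger


def write_cohort(
    sets: list[PfamAnnotationSet],
    labels: dict[str, str],
    ledger: dict,
    outdir: str | Path,
    dialects: tuple[str, ...] = ("pfam", "eggnog"),
) -> None:
    """Serialise a cohort in the supported annotation dialects plus ledger/labels.

    Writes ``<genome>.pfam.tsv`` and/or ``<genome>.emapper.annotations``
    per genome, ``labels.tsv`` (genome_id<TAB>label), and ``ledger.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for aset in sets:
        if "pfam" in dialects:
            write_pfam_table(aset, outdir / f"{aset.genome_id}.pfam.tsv")
        if "eggnog" in dialects:
            write_eggnog_annotations(aset, outdir / f"{aset.genome_id}.emapper.annotations")
    with (outdir / "labels.tsv").open("w", newline="") as fh:
        fh.write("genome_id\tlabel\n")
        for aset in sets:
            fh.write(f"{aset.genome_id}\t{labels[aset.genome_id]}\n")
    (outdir / "ledger.json").write_text(json.dumps(ledger, indent=2) + "\n")


def generate_survival(
    true_d10: float,
    doses: list[float],
    cv: float = 0.05,
    n_technical: int = 3,
    n_biological: int = 3,
    baseline_count: int = 100_000,
    seed: int = 0,
) -> SurvivalAssay:
    """Synthetic CFU assay around a log-linear dose-response.

    Counts are Poisson(baseline × 10^(−dose/true_d10) × lognormal(1, cv));
    sham counts are Poisson(baseline × lognormal(1, cv)).  Counts are on
    the dilution-adjusted scale, so the default baseline of 1e5 keeps
    Poisson noise small relative to the multiplicative plating noise.
    """
    if true_d10 <= 0:
        raise ValueError("true_d10 must be > 0 Gy")
    if not doses:
        raise ValueError("doses must be non-empty")
    if baseline_count < 10:
        warnings.warn("baseline_count < 10: D10 fits will be unstable")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    mu = -(sigma**2) / 2

    def noise() -> float:
        return float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0

    reps = []
    for _ in range(n_biological):
        sham = [int(rng.poisson(baseline_count * noise())) for _ in range(n_technical)]
        dosed: dict[float, list[int]] = {}
        for dose in doses:
            expect = baseline_count * 10.0 ** (-dose / true_d10)
            dosed[float(dose)] = [
                int(rng.poisson(expect * noise())) for _ in range(n_technical)
            ]
        reps.append(BiologicalReplicate(sham_counts=sham, dosed_counts=dosed))
    return SurvivalAssay(biological_replicates=reps)
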