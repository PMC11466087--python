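"""D10 records, tolerance labels, and reproducible train/test splits.

D10 is the acute ionizing-radiation dose at which 10% of exposed cells
still form viable colonies.  A species with several published D10 values
is summarised by their arithmetic mean; the binary label is
*radiosensitive* if the mean D10 falls strictly below the cutoff
(200 Gy by default) and *tolerant* otherwise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RADIOSENSITIVE",
    "TOLERANT",
    "D10Record",
    "LabelingConfig",
    "mean_d10",
    "assign_class",
    "quantile_cutoff",
    "stratified_split",
    "read_label_table",
]

RADIOSENSITIVE = "radiosensitive"
TOLERANT = "tolerant"


@dataclass
class D10Record:
    """One species' experimentally determined D10 values in gray (Gy)."""

    species_id: str
    d10_values: list[float]
    phylum: str | None = None
    source_note: str | None = None

    def __post_init__(self) -> None:
        if not self.d10_values:
            raise ValueError(f"{self.species_id}: d10_values must be non-empty")
        if any(v <= 0 for v in self.d10_values):
            raise ValueError(f"{self.species_id}: all D10 values must be > 0 Gy")


@dataclass
class LabelingConfig:
    """Labeling cutoff; mean D10 < cutoff_gy → radiosensitive."""

    cutoff_gy: float = 200.0

    def __post_init__(self) -> None:
        if self.cutoff_gy <= 0:
            raise ValueError("cutoff_gy must be > 0")


def mean_d10(rec: D10Record) -> float:
    """Arithmetic mean of a species' D10 values (Gy)."""
    return float(np.mean(rec.d10_values))


def assign_class(rec: D10Record, cfg: LabelingConfig | None = None) -> str:
    """Binary tolerance label: radiosensitive iff mean D10 < cutoff.

    A mean exactly at the cutoff is labelled tolerant (strict ``<``).
    """
    cfg = cfg or LabelingConfig()
    return RADIOSENSITIVE if mean_d10(rec) < cfg.cutoff_gy else TOLERANT


def quantile_cutoff(recs: list[D10Record], q: float) -> float:
    """Empirical q-quantile (linear interpolation) of per-species mean D10.

    Diagnostic only: the default labeling uses the fixed 200 Gy cutoff.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if len(recs) < 2:
        raise ValueError("need at least 2 records for a quantile cutoff")
    means = [mean_d10(r) for r in recs]
    return float(np.quantile(means, q, method="linear"))


def stratified_split(
    labeled: list[tuple[str, str]], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Per-class stratified split into (train_ids, test_ids).

    Each class contributes ``round(train_fraction * class_size)`` members
    to the train set.  Disjoint, exhaustive, and reproducible for a fixed
    seed (the split does not depend on input order).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    by_class: dict[str, list[str]] = defaultdict(list)
    for gid, cls in labeled:
        by_class[cls].append(gid)
    if len(by_class) < 2:
        raise ValueError("both classes must be present for a stratified split")
    for cls, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both sides non-empty per class
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def read_label_table(path: str | Path) -> list[D10Record]:
    """Read a label TSV: species_id<TAB>d10_gy[<TAB>phylum], one row per measurement.

    Repeated species rows aggregate into a single record.
    """
    path = Path(path)
    values: dict[str, list[float]] = {}
    phyla: dict[str, str | None] = {}
    order: list[str] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:2] != ["species_id", "d10_gy"]:
            raise ValueError(
                f"{path}: expected header 'species_id<TAB>d10_gy[<TAB>phylum]', got {header}"
            )
        for line in fh:
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            sid = cells[0]
            if sid not in values:
                values[sid] = []
                phyla[sid] = None
                order.append(sid)
            values[sid].append(float(cells[1]))
            if len(cells) > 2 and cells[2].strip():
                phyla[sid] = cells[2].strip()
    return [D10Record(species_id=s, d10_values=values[s], phylum=phyla[s]) for s in order]
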