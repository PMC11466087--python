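"""Read and write Pfam annotation files and build domain-frequency tables.

Two input dialects are supported: a canonical per-protein TSV
(``protein_id<TAB>pfam_ids`` with ``;``-separated accessions) and the
tabular output of EggNOG-Mapper (``.emapper.annotations``), of which only
the ``PFAMs`` column is consumed.  Domain *instances* form a multiset: the
same accession may occur several times within one protein, and each
occurrence counts.  Relative frequency of a domain in a genome is its
instance count divided by the total number of domain instances in that
genome.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationFormatError",
    "EmptyAnnotationSetError",
    "PfamAnnotationSet",
    "FrequencyTable",
    "read_eggnog_annotations",
    "read_pfam_table",
    "write_pfam_table",
    "write_eggnog_annotations",
    "compute_frequencies",
    "build_frequency_table",
]

_PFAM_TOKEN = re.compile(r"^(PF\d{5})(?:\.\d+)?$")


class AnnotationFormatError(ValueError):
    """An annotation file does not conform to its declared dialect."""


class EmptyAnnotationSetError(ValueError):
    """Raised when an operation needs at least one domain instance."""


@dataclass
class PfamAnnotationSet:
    """A genome's multiset of Pfam domain instances, grouped by protein.

    Parameters
    ----------
    genome_id:
        Identifier of the genome/proteome the annotations belong to.
    records:
        Ordered ``(protein_id, [accessions])`` pairs.  A protein may carry
        zero domains; a domain may occur more than once per protein.
    skipped_tokens:
        Count of unparseable accession tokens dropped (with a warning)
        during parsing.
    """

    genome_id: str
    records: list[tuple[str, list[str]]] = field(default_factory=list)
    skipped_tokens: int = 0

    @property
    def total_instances(self) -> int:
        """Total number of domain instances (with multiplicity)."""
        return sum(len(doms) for _, doms in self.records)

    def domain_counts(self) -> Counter:
        """Instance count per domain accession."""
        counts: Counter = Counter()
        for _, doms in self.records:
            counts.update(doms)
        return counts


def _parse_token(token: str, tally: list[int]) -> str | None:
    token = token.strip()
    if not token:
        return None
    m = _PFAM_TOKEN.match(token)
    if m is None:
        warnings.warn(f"skipping unparseable Pfam accession token {token!r}")
        tally[0] += 1
        return None
    return m.group(1)


def read_eggnog_annotations(path: str | Path, genome_id: str) -> PfamAnnotationSet:
    """Parse an EggNOG-Mapper ``.emapper.annotations`` file.

    Metadata lines start with ``##``; the header line starts with
    ``#query`` and must contain a ``PFAMs`` column.  A ``PFAMs`` cell of
    ``-`` means the protein carries no Pfam domains; otherwise the cell is
    a comma-separated list of accessions, one instance each.  A terminal
    ``##`` footer block (and anything after it) is ignored.
    """
    path = Path(path)
    header_cols: list[str] | None = None
    pfams_idx = -1
    records: list[tuple[str, list[str]]] = []
    tally = [0]
    with path.open("r", newline="") as fh:
        in_data = False
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                if in_data:
                    break  # terminal footer: ignore the rest
                continue
            if line.startswith("#query"):
                header_cols = line.lstrip("#").split("\t")
                header_cols[0] = "query"
                if "PFAMs" not in header_cols:
                    raise AnnotationFormatError(
                        f"{path}: no PFAMs column; columns found: {header_cols}"
                    )
                pfams_idx = header_cols.index("PFAMs")
                continue
            if header_cols is None:
                raise AnnotationFormatError(f"{path}: data row before '#query' header")
            in_data = True
            cells = line.split("\t")
            if pfams_idx >= len(cells):
                raise AnnotationFormatError(
                    f"{path}: row with {len(cells)} columns, PFAMs expected at "
                    f"column {pfams_idx + 1}"
                )
            query = cells[0]
            cell = cells[pfams_idx].strip()
            if cell in ("-", ""):
                records.append((query, []))
                continue
            doms = [d for t in cell.split(",") if (d := _parse_token(t, tally))]
            records.append((query, doms))
    if header_cols is None:
        raise AnnotationFormatError(f"{path}: no '#query' header line found")
    return PfamAnnotationSet(genome_id=genome_id, records=records, skipped_tokens=tally[0])


def read_pfam_table(path: str | Path, genome_id: str) -> PfamAnnotationSet:
    """Parse the canonical per-protein TSV dialect.

    Header is ``protein_id<TAB>pfam_ids``; ``pfam_ids`` is ``;``-separated
    and may be empty.  Version suffixes (``PF00300.23``) are stripped to
    the bare accession.  Duplicate protein rows make the proteome
    ambiguous and are an error.
    """
    path = Path(path)
    lines = [ln.rstrip("\r\n") for ln in path.open("r", newline="")]
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise AnnotationFormatError(f"{path}: empty annotation file")
    header = lines[0].split("\t")
    if header[:2] != ["protein_id", "pfam_ids"]:
        raise AnnotationFormatError(
            f"{path}: expected header 'protein_id<TAB>pfam_ids', got {lines[0]!r}"
        )
    records: list[tuple[str, list[str]]] = []
    seen: set[str] = set()
    tally = [0]
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        pid = cells[0]
        if pid in seen:
            raise AnnotationFormatError(f"{path}: duplicate protein_id {pid!r}")
        seen.add(pid)
        cell = cells[1] if len(cells) > 1 else ""
        doms = [d for t in cell.split(";") if (d := _parse_token(t, tally))]
        records.append((pid, doms))
    return PfamAnnotationSet(genome_id=genome_id, records=records, skipped_tokens=tally[0])


def write_pfam_table(aset: PfamAnnotationSet, path: str | Path) -> None:
    """Write the canonical per-protein TSV form of an annotation set."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("protein_id\tpfam_ids\n")
        for pid, doms in aset.records:
            fh.write(f"{pid}\t{';'.join(doms)}\n")


def write_eggnog_annotations(aset: PfamAnnotationSet, path: str | Path) -> None:
    """Write an annotation set as a minimal ``.emapper.annotations`` file."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"## emapper-style annotations for {aset.genome_id}\n")
        fh.write("#query\tseed_ortholog\tDescription\tPFAMs\n")
        for pid, doms in aset.records:
            cell = ",".join(doms) if doms else "-"
            fh.write(f"{pid}\t-\t-\t{cell}\n")
        fh.write("## end\n")


def compute_frequencies(aset: PfamAnnotationSet) -> dict[str, float]:
    """Relative frequency of each observed domain in a genome.

    frequency(d) = instance count of d / total instance count; the values
    over all observed domains sum to 1.
    """
    total = aset.total_instances
    if total == 0:
        raise EmptyAnnotationSetError(
            f"empty annotation set for genome {aset.genome_id!r}: no domain instances"
        )
    return {d: c / total for d, c in sorted(aset.domain_counts().items())}


@dataclass
class FrequencyTable:
    """Genomes × domains matrix of relative frequencies with raw counts.

    ``frequencies`` and ``counts`` are parallel DataFrames indexed by
    genome id with Pfam accessions as columns; ``totals`` holds each
    genome's full-universe instance count, so that restricting the table
    to a domain subset keeps frequencies on the full-proteome denominator
    (row sums over a subset may be < 1).
    """

    frequencies: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series

    @property
    def genome_ids(self) -> list[str]:
        return list(self.frequencies.index)

    @property
    def domain_ids(self) -> list[str]:
        return list(self.frequencies.columns)

    def restrict(self, domains: list[str]) -> "FrequencyTable":
        """Restrict columns to ``domains``; absent domains become 0."""
        freq = self.frequencies.reindex(columns=list(domains), fill_value=0.0)
        cnt = self.counts.reindex(columns=list(domains), fill_value=0)
        return FrequencyTable(frequencies=freq, counts=cnt, totals=self.totals.copy())

    def to_tsv(self, path: str | Path) -> None:
        """Write frequencies (genomes as rows, domains as columns) at full precision."""
        df = self.frequencies.copy()
        df.index.name = "genome_id"
        df.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        """Read a frequency TSV written by :meth:`to_tsv`.

        Raw counts and totals are unknown for an external frequency file;
        counts are left as NaN-free zeros and totals as 0 (frequency-only
        table, sufficient for classification).
        """
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        zeros = pd.DataFrame(0, index=df.index, columns=df.columns)
        totals = pd.Series(0, index=df.index)
        return cls(frequencies=df, counts=zeros, totals=totals)


def build_frequency_table(
    sets: list[PfamAnnotationSet], domains: list[str] | None = None
) -> FrequencyTable:
    """Stack per-genome frequencies into a FrequencyTable.

    If ``domains`` is given, columns are restricted to it (domains absent
    from a genome get frequency exactly 0); otherwise the union of all
    observed domains, sorted, forms the column universe.
    """
    if not sets:
        raise ValueError("need at least one annotation set")
    gids = [s.genome_id for s in sets]
    if len(set(gids)) != len(gids):
        dupes = sorted({g for g in gids if gids.count(g) > 1})
        raise ValueError(f"duplicate genome_id(s): {dupes}")
    all_counts = [s.domain_counts() for s in sets]
    totals = pd.Series([s.total_instances for s in sets], index=gids, dtype=int)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise EmptyAnnotationSetError(f"empty annotation set(s): {bad}")
    if domains is None:
        universe: set[str] = set()
        for c in all_counts:
            universe.update(c)
        cols = sorted(universe)
    else:
        cols = list(domains)
    mat = np.zeros((len(sets), len(cols)), dtype=int)
    col_idx = {d: j for j, d in enumerate(cols)}
    for i, c in enumerate(all_counts):
        for d, n in c.items():
            j = col_idx.get(d)
            if j is not None:
                mat[i, j] = n
    counts = pd.DataFrame(mat, index=gids, columns=cols)
    freqs = counts.div(totals, axis=0)
    return FrequencyTable(frequencies=freqs, counts=counts, totals=totals)
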