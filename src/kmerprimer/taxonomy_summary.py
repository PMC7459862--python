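"""Covered-taxonomy and phenotype-group summaries.

Given the set of sequences a primer (or primer set) covers, tabulate per
taxon at a chosen rank — or per phenotype class (oxygen requirement, gram
type) from a user-supplied taxon->phenotype table — how many database
sequences exist and how many are covered. Records without an annotation at
the rank fall under "unclassified"; taxa absent from the phenotype table
fall under "unknown".

The phenotype table is a three-column TSV (taxon, oxygen class, gram
class) in the style of species-phenotype lookups such as BugBase; lineage
resolution is most-specific-wins (species before genus and so on).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .primer_properties import round2
from .seq_processing import SequenceRecord

RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]

OXYGEN_CLASSES = {"aerobic", "anaerobic", "facultative_anaerobic", "unknown"}
GRAM_CLASSES = {"positive", "negative", "unknown"}

UNCLASSIFIED = "unclassified"
UNKNOWN = "unknown"


@dataclass
class TaxonBreakdown:
    rank: str
    rows: list[tuple[str, int, int, float]]  # taxon, n_total, n_covered, % covered


class PhenotypeMap:
    """taxon name -> (oxygen_class, gram_class)."""

    def __init__(self, mapping: dict[str, tuple[str, str]]):
        for taxon, (oxy, gram) in mapping.items():
            if oxy not in OXYGEN_CLASSES:
                raise ValueError(f"bad oxygen class for {taxon!r}: {oxy!r}")
            if gram not in GRAM_CLASSES:
                raise ValueError(f"bad gram class for {taxon!r}: {gram!r}")
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._map

    def lookup(self, lineage: Sequence[str] | None, axis: str) -> str:
        """Resolve a lineage to a class, most specific taxon first."""
        idx = {"oxygen": 0, "gram": 1}[axis]
        if lineage:
            for taxon in reversed(lineage):
                if taxon in self._map:
                    return self._map[taxon][idx]
        return UNKNOWN

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeMap":
        mapping: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"phenotype TSV needs 3 columns, got: {line!r}")
                mapping[parts[0]] = (parts[1], parts[2])
        if not mapping:
            raise ValueError(f"empty phenotype table: {path}")
        return cls(mapping)


def _tabulate(rank: str, labels: Iterable[tuple[str, bool]],
              last: str) -> TaxonBreakdown:
    totals: dict[str, int] = {}
    covered: dict[str, int] = {}
    for label, is_covered in labels:
        totals[label] = totals.get(label, 0) + 1
        if is_covered:
            covered[label] = covered.get(label, 0) + 1
    rows = [
        (t, n, covered.get(t, 0), round2(covered.get(t, 0) * 100.0 / n))
        for t, n in totals.items()
    ]
    rows.sort(key=lambda r: (r[0] == last, -r[1], r[0]))
    return TaxonBreakdown(rank=rank, rows=rows)


def breakdown_by_rank(
    db: Sequence[SequenceRecord],
    covered: set[str] | Iterable[str],
    rank: str | int,
) -> TaxonBreakdown:
    """Per-taxon totals and covered counts at one taxonomic rank."""
    covered = set(covered)
    if isinstance(rank, str):
        try:
            idx = RANKS.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
        rank_name = rank
    else:
        idx, rank_name = rank, f"rank{rank}"
    if not any(rec.lineage for rec in db):
        raise ValueError("no record carries a lineage annotation")
    labels = []
    for rec in db:
        if rec.lineage and idx < len(rec.lineage):
            label = rec.lineage[idx]
        else:
            label = UNCLASSIFIED
        labels.append((label, rec.id in covered))
    return _tabulate(rank_name, labels, UNCLASSIFIED)


def breakdown_by_phenotype(
    db: Sequence[SequenceRecord],
    covered: set[str] | Iterable[str],
    phenomap: PhenotypeMap,
    axis: str,
) -> TaxonBreakdown:
    """Totals and covered counts per oxygen-requirement or gram class."""
    if axis not in ("oxygen", "gram"):
        raise ValueError("axis must be 'oxygen' or 'gram'")
    if len(phenomap) == 0:
        raise ValueError("phenotype map is empty")
    covered = set(covered)
    labels = [
        (phenomap.lookup(rec.lineage, axis), rec.id in covered) for rec in db
    ]
    return _tabulate(axis, labels, UNKNOWN)


def breakdown_to_tsv(bd: TaxonBreakdown, path: str | Path,
                     header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment)
        fh.write(f"{bd.rank}\tn_total\tn_covered\tpct_covered\n")
        for taxon, n, c, pct in bd.rows:
            fh.write(f"{taxon}\t{n}\t{c}\t{pct:.2f}\n")
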