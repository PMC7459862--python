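"""Sliding-window k-mer tabulation over a sequence database.

A length-m sequence yields m − k + 1 windows at step 1; windows containing
N are dropped (an ambiguous window is not evidence for any concrete k-mer).
Counting is strand-specific: a k-mer and its reverse complement are
distinct entries, because primers are strand-specific and reverse primers
are derived later by explicit reverse complementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .seq_processing import SequenceRecord


@dataclass
class KmerStat:
    """One k-mer with its total multiplicity and per-sequence reach."""

    kmer: str
    occurrences: int
    seq_hits: int
    seq_fraction: float


@dataclass
class KmerTable:
    k: int
    n_sequences: int
    stats: dict[str, KmerStat] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stats)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.stats

    def __getitem__(self, kmer: str) -> KmerStat:
        return self.stats[kmer]

    def __iter__(self) -> Iterator[KmerStat]:
        return iter(self.stats.values())

    def get(self, kmer: str) -> KmerStat | None:
        return self.stats.get(kmer)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.stats.values(), key=lambda s: (-s.occurrences, s.kmer))
        return pd.DataFrame(
            {
                "kmer": [s.kmer for s in rows],
                "occurrences": [s.occurrences for s in rows],
                "seq_hits": [s.seq_hits for s in rows],
                "seq_fraction": [f"{s.seq_fraction:.6f}" for s in rows],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def kmerize(seq: str, k: int) -> list[str]:
    """All step-1 windows of length k, in order; N-containing windows dropped.

    ``kmerize("AACTGACTGA", 4)`` is the canonical worked example: seven
    windows AACT, ACTG, CTGA, TGAC, GACT, ACTG, CTGA.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if "N" not in seq:
        return [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return [
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    ]


def count_kmers(db: Sequence[SequenceRecord], k: int) -> KmerTable:
    """Tabulate every N-free window of length k across the database.

    ``occurrences`` is total multiplicity; ``seq_hits`` counts each sequence
    once regardless of multiplicity.
    """
    if not db:
        raise ValueError("count_kmers requires a non-empty database")
    if k < 1:
        raise ValueError("k must be >= 1")
    occ: dict[str, int] = {}
    hits: dict[str, int] = {}
    for rec in db:
        windows = kmerize(rec.seq, k)
        for w in windows:
            occ[w] = occ.get(w, 0) + 1
        for w in set(windows):
            hits[w] = hits.get(w, 0) + 1
    n = len(db)
    table = KmerTable(k=k, n_sequences=n)
    for kmer, c in occ.items():
        h = hits[kmer]
        table.stats[kmer] = KmerStat(kmer, c, h, h / n)
    return table


def count_kmer_range(
    db: Sequence[SequenceRecord], k_min: int, k_max: int
) -> list[KmerTable]:
    """One independent table per k in [k_min, k_max]."""
    if k_min > k_max:
        raise ValueError(f"k_min ({k_min}) exceeds k_max ({k_max})")
    return [count_kmers(db, k) for k in range(k_min, k_max + 1)]
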