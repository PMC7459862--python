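"""FASTA ingest and the three database-preprocessing tools.

A primer-design database is a list of :class:`SequenceRecord`. On ingest
sequences are uppercased, RNA U is converted to T, ambiguity codes other
than N are collapsed to N, and records containing non-IUPAC characters are
rejected with a logged warning. Taxonomic lineages may ride along in the
FASTA description (semicolon-separated, optional ``k__``-style rank
prefixes) or be attached from a two-column TSV.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .iupac import IUPAC_SETS

logger = logging.getLogger(__name__)

_AMBIGUOUS = set(IUPAC_SETS) - set("ACGTN")
_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


@dataclass
class SequenceRecord:
    """One database entry: id, free-text description, DNA over {A,C,G,T,N}."""

    id: str
    description: str = ""
    seq: str = ""
    lineage: Optional[list[str]] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LengthStats:
    n_sequences: int
    min_len: int
    max_len: int
    mean_len: float
    median_len: float
    histogram: dict[int, int] = field(default_factory=dict)


def normalize_sequence(raw: str) -> Optional[str]:
    """Uppercase, U->T, ambiguity codes (other than N) -> N.

    Returns None (record should be rejected) when a character outside the
    IUPAC nucleotide alphabet is present, or the sequence is empty.
    """
    seq = raw.upper().replace("U", "T")
    if not seq:
        return None
    out = []
    for ch in seq:
        if ch in "ACGTN":
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("N")
        else:
            return None
    if any(c in _AMBIGUOUS for c in seq):
        logger.warning("ambiguity codes collapsed to N in a database sequence")
    return "".join(out)


def parse_lineage(description: str, delimiter: str = ";") -> Optional[list[str]]:
    """Extract an ordered lineage from a FASTA description.

    The text after the first whitespace is split on ``delimiter``; optional
    one-letter rank prefixes (``k__Bacteria``) are stripped. Returns None
    when no delimiter is present.
    """
    text = description.strip()
    if not text or delimiter not in text:
        return None
    taxa = [_RANK_PREFIX.sub("", t.strip()) for t in text.split(delimiter)]
    taxa = [t for t in taxa if t]
    return taxa or None


def load_fasta(
    path: str | Path,
    lineage_delimiter: str = ";",
) -> list[SequenceRecord]:
    """Read a FASTA database into normalized records, preserving file order.

    Records with non-nucleotide characters are dropped with a warning; an
    empty or record-free file raises ValueError.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq))
        if seq is None:
            logger.warning("rejecting record %s: non-nucleotide characters", entry.id)
            continue
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {entry.id}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id) :].strip()
        records.append(
            SequenceRecord(
                id=entry.id,
                description=desc,
                seq=seq,
                lineage=parse_lineage(desc, lineage_delimiter),
            )
        )
    if not records:
        raise ValueError(f"no usable FASTA records in {path}")
    return records


def write_fasta(db: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as multi-line FASTA (default 80-column wrap)."""
    with open(path, "w") as fh:
        for rec in db:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def attach_lineages(db: Sequence[SequenceRecord], path: str | Path,
                    delimiter: str = ";") -> None:
    """Attach lineages from a TSV mapping (sequence id -> lineage string)."""
    table: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, _, lin = line.partition("\t")
            parsed = parse_lineage(lin, delimiter)
            if parsed:
                table[sid] = parsed
    for rec in db:
        if rec.id in table:
            rec.lineage = table[rec.id]


def length_stats(db: Sequence[SequenceRecord], bin_width: int = 100) -> LengthStats:
    """Summary statistics of sequence lengths; histogram keyed by bin start."""
    if not db:
        raise ValueError("length_stats requires a non-empty database")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = [len(r) for r in db]
    hist: dict[int, int] = {}
    for L in lengths:
        b = (L // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return LengthStats(
        n_sequences=len(lengths),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=statistics.fmean(lengths),
        median_len=statistics.median(lengths),
        histogram=dict(sorted(hist.items())),
    )


def trim_by_length(
    db: Sequence[SequenceRecord],
    min_len: int,
    max_len: int,
    mode: str = "delete",
) -> list[SequenceRecord]:
    """Length filter: drop sequences shorter than ``min_len``; sequences longer
    than ``max_len`` are dropped (``mode='delete'``) or cut to their first
    ``max_len`` bases (``mode='truncate'``). Order is preserved."""
    if not (0 < min_len <= max_len):
        raise ValueError(f"need 0 < min_len <= max_len, got {min_len}..{max_len}")
    if mode not in ("delete", "truncate"):
        raise ValueError(f"mode must be 'delete' or 'truncate', got {mode!r}")
    out: list[SequenceRecord] = []
    for rec in db:
        L = len(rec)
        if L < min_len:
            continue
        if L > max_len:
            if mode == "delete":
                continue
            rec = SequenceRecord(rec.id, rec.description, rec.seq[:max_len], rec.lineage)
        out.append(rec)
    return out


def dedupe_exact(db: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Remove exact duplicate sequences, keeping the first in file order."""
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for rec in db:
        if rec.seq not in seen:
            seen.add(rec.seq)
            out.append(rec)
    return out
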