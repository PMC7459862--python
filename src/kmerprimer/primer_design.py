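"""Degenerate-primer construction from high-frequency k-mers.

The design route avoids multiple alignment entirely: conserved regions are
located as k-mers that recur across many database sequences. High-frequency
k-mers are selected, near-duplicates occupying the same locus are merged by
mutual overlap, and single-base variants above a frequency floor are folded
into the survivor as IUPAC ambiguity codes, yielding one degenerate primer
per conserved locus. All tie-breaks are total orders (count, then length,
then lexicographic) so output is byte-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, TYPE_CHECKING

from . import iupac
from .kmer_engine import KmerStat, KmerTable, count_kmers

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig
    from .seq_processing import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class DegeneratePrimer:
    """An IUPAC-alphabet oligo with provenance and (optionally) coverage.

    ``iupac_seq`` always has the same length as the seed k-mer it grew from,
    and the seed is always one of its expansions.
    """

    iupac_seq: str
    seed_kmer: str
    absorbed_variants: list[str] = field(default_factory=list)
    name: Optional[str] = None
    coverage: Optional[float] = None
    seed_occurrences: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.iupac_seq) != len(self.seed_kmer):
            raise ValueError("iupac_seq and seed_kmer lengths differ")

    def __len__(self) -> int:
        return len(self.iupac_seq)

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.iupac_seq)

    def reverse_complement(self) -> "DegeneratePrimer":
        """The primer as it would be synthesized to bind the other strand."""
        return DegeneratePrimer(
            iupac_seq=iupac.reverse_complement(self.iupac_seq),
            seed_kmer=iupac.reverse_complement(self.seed_kmer),
            absorbed_variants=[
                iupac.reverse_complement(v) for v in self.absorbed_variants
            ],
            name=self.name,
            coverage=self.coverage,
            seed_occurrences=self.seed_occurrences,
        )


def select_high_frequency(
    table: KmerTable, top_n: int = 30, min_fraction: float = 0.0
) -> list[KmerStat]:
    """The top_n k-mers by occurrence count whose sequence fraction clears
    ``min_fraction``. Ties in count break lexicographically."""
    if len(table) == 0:
        raise ValueError("k-mer table is empty")
    ranked = sorted(table, key=lambda s: (-s.occurrences, s.kmer))
    return [s for s in ranked[:top_n] if s.seq_fraction >= min_fraction]


def overlap_length(a: str, b: str) -> int:
    """Locus-sharing overlap of two k-mer strings.

    The maximum of: longest suffix of ``a`` equal to a prefix of ``b``, the
    symmetric quantity, and — when one contains the other — the length of
    the shorter.
    """
    if a in b or b in a:
        return min(len(a), len(b))
    best = 0
    for l in range(min(len(a), len(b)) - 1, 0, -1):
        if a[-l:] == b[:l] or b[-l:] == a[:l]:
            best = l
            break
    return best


def merge_overlapping(candidates: Sequence[KmerStat], x: int) -> list[KmerStat]:
    """Collapse k-mers occupying the same locus (pairwise overlap > x).

    Candidates are grouped transitively; within each group the survivor is
    the highest-count k-mer, ties broken by greater length, then
    lexicographically. Survivors are returned sorted by count descending.
    """
    if x < 1:
        raise ValueError("overlap threshold x must be >= 1")
    cands = list(candidates)
    n = len(cands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_length(cands[i].kmer, cands[j].kmer) > x:
                parent[find(i)] = find(j)

    groups: dict[int, list[KmerStat]] = {}
    for i, s in enumerate(cands):
        groups.setdefault(find(i), []).append(s)

    survivors = [
        min(g, key=lambda s: (-s.occurrences, -len(s.kmer), s.kmer))
        for g in groups.values()
    ]
    return sorted(survivors, key=lambda s: (-s.occurrences, s.kmer))


def combine_variants(
    seed: str,
    table: KmerTable,
    variant_min_fraction: float = 0.01,
    max_degeneracy: int = 64,
) -> DegeneratePrimer:
    """Fold Hamming-distance-1 variants of ``seed`` into a degenerate primer.

    Every table k-mer one substitution away from the seed whose sequence
    fraction clears ``variant_min_fraction`` is absorbed, most frequent
    first: at its differing position the IUPAC set becomes the union of the
    existing set and the variant base. Absorption stops before the first
    fold that would push degeneracy above ``max_degeneracy``.
    """
    if seed not in table:
        raise KeyError(f"seed k-mer not present in table: {seed}")
    eligible = [
        table[v]
        for v in iupac.hamming1_neighbors(seed)
        if v in table and table[v].seq_fraction >= variant_min_fraction
    ]
    eligible.sort(key=lambda s: (-s.seq_fraction, s.kmer))

    sets = [set(iupac.base_set(c)) for c in seed]
    absorbed: list[str] = []
    deg = 1
    for stat in eligible:
        v = stat.kmer
        pos = next(i for i in range(len(seed)) if v[i] != seed[i])
        new_size = len(sets[pos] | {v[pos]})
        new_deg = deg // len(sets[pos]) * new_size
        if new_deg > max_degeneracy:
            break
        sets[pos].add(v[pos])
        deg = new_deg
        absorbed.append(v)

    iupac_seq = "".join(iupac.code_for(s) for s in sets)
    return DegeneratePrimer(
        iupac_seq=iupac_seq,
        seed_kmer=seed,
        absorbed_variants=absorbed,
        seed_occurrences=table[seed].occurrences,
    )


def design_primers(
    db: Sequence["SequenceRecord"],
    config: Optional["PipelineConfig"] = None,
    name_prefix: str = "primer",
    **overrides,
) -> list[DegeneratePrimer]:
    """Full single-primer design: count, select, merge, fold, filter.

    For each k in the configured primer-length range the database is
    tabulated, high-frequency k-mers are selected against the coverage
    floor, same-locus k-mers merged, variants folded, and candidates whose
    verified coverage falls below ``min_coverage`` dropped. The union over
    k is returned sorted by coverage descending and named sequentially.
    """
    from .config import PipelineConfig
    from .coverage_assessment import primer_coverage

    if not db:
        raise ValueError("design_primers requires a non-empty database")
    if config is None:
        config = PipelineConfig()
    if overrides:
        config = config.replace(**overrides)

    primers: list[DegeneratePrimer] = []
    seen: set[str] = set()
    for k in range(config.primer_len_min, config.primer_len_max + 1):
        table = count_kmers(db, k)
        if len(table) == 0:
            continue
        selected = select_high_frequency(table, config.top_n, config.min_coverage)
        merged = merge_overlapping(selected, config.overlap)
        for stat in merged:
            primer = combine_variants(
                stat.kmer,
                table,
                config.variant_min_fraction,
                config.max_degeneracy,
            )
            cov = primer_coverage(primer, db, config.max_mismatches)
            if cov < config.min_coverage:
                continue
            if primer.iupac_seq in seen:
                continue
            seen.add(primer.iupac_seq)
            primers.append(primer)

    primers.sort(key=lambda p: (-(p.coverage or 0.0), p.iupac_seq))
    for i, p in enumerate(primers, start=1):
        p.name = f"{name_prefix}_kmer{i}"
    if not primers:
        logger.warning("no primer reached the coverage floor %.2f", config.min_coverage)
    return primers
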