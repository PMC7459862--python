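"""IUPAC-aware in-silico PCR: binding sites, coverage, pairing, specificity.

Matching is a deterministic window scan: a primer position matches a
template base when the base belongs to the position's IUPAC set; a template
N matches only a primer N. A mismatch budget (default 0) relaxes this per
window. Reverse-strand binding of a primer (stored 5'->3' as synthesized)
is evaluated by matching its reverse complement against the sense strand.
Coordinates are 0-based half-open internally; user-facing reports convert
to 1-based inclusive.

Specificity is simply the same coverage computation run against an
off-target database: the lower the better.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from . import iupac
from .primer_design import DegeneratePrimer
from .seq_processing import SequenceRecord


@dataclass
class BindingSite:
    """One primer-template match: [start, end) on the sense strand."""

    seq_id: str
    start: int
    end: int
    strand: str  # "forward" | "reverse"
    mismatches: int = 0


@dataclass
class PrimerPairReport:
    """In-silico amplification summary for one (forward, reverse) pair."""

    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    pair_coverage: float
    product_lengths: Counter = field(default_factory=Counter)
    product_length_mode: Optional[int] = None
    specificity: dict[str, float] = field(default_factory=dict)
    covered_ids: set[str] = field(default_factory=set)


def _iupac_seq(p: DegeneratePrimer | str) -> str:
    return p if isinstance(p, str) else p.iupac_seq


def _char_class(code: str) -> str:
    # template N matches only primer N; N's class therefore includes N
    bases = sorted(iupac.base_set(code))
    if code == "N":
        bases.append("N")
    return "[" + "".join(bases) + "]"


def _pattern(iupac_seq: str) -> re.Pattern:
    # lookahead so overlapping sites are all reported
    return re.compile("(?=(" + "".join(_char_class(c) for c in iupac_seq) + "))")


def _matches(code: str, base: str) -> bool:
    if base == "N":
        return code == "N"
    return base in iupac.base_set(code)


def _scan(iupac_seq: str, seq: str, max_mismatches: int) -> list[int]:
    """Start positions where the pattern matches within the mismatch budget."""
    if max_mismatches == 0:
        return [m.start() for m in _pattern(iupac_seq).finditer(seq)]
    L = len(iupac_seq)
    out = []
    for i in range(len(seq) - L + 1):
        mm = 0
        for j in range(L):
            if not _matches(iupac_seq[j], seq[i + j]):
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            out.append(i)
    return out


def _mismatch_count(iupac_seq: str, window: str) -> int:
    return sum(0 if _matches(c, b) else 1 for c, b in zip(iupac_seq, window))


def match_sites(
    primer: DegeneratePrimer | str,
    rec: SequenceRecord,
    max_mismatches: int = 0,
) -> list[BindingSite]:
    """All forward- and reverse-strand binding sites of a primer on one record.

    Forward sites match the primer as written; reverse sites are positions
    where the primer's reverse complement matches the sense strand (i.e.,
    where the primer itself would anneal to the antisense strand).
    """
    pat = _iupac_seq(primer)
    seq = rec.seq
    L = len(pat)
    if L > len(seq):
        return []
    sites = [
        BindingSite(rec.id, i, i + L, "forward",
                    _mismatch_count(pat, seq[i : i + L]))
        for i in _scan(pat, seq, max_mismatches)
    ]
    rc = iupac.reverse_complement(pat)
    sites += [
        BindingSite(rec.id, i, i + L, "reverse",
                    _mismatch_count(rc, seq[i : i + L]))
        for i in _scan(rc, seq, max_mismatches)
    ]
    return sites


def covered_ids(
    primer: DegeneratePrimer | str,
    db: Sequence[SequenceRecord],
    max_mismatches: int = 0,
) -> set[str]:
    """Ids of database sequences with at least one site on either strand."""
    pat = _iupac_seq(primer)
    rc = iupac.reverse_complement(pat)
    out: set[str] = set()
    for rec in db:
        if len(pat) > len(rec.seq):
            continue
        if _scan(pat, rec.seq, max_mismatches) or _scan(rc, rec.seq, max_mismatches):
            out.add(rec.id)
    return out


def primer_coverage(
    primer: DegeneratePrimer | str,
    db: Sequence[SequenceRecord],
    max_mismatches: int = 0,
) -> float:
    """Fraction of database sequences the primer binds (either strand)."""
    if not db:
        raise ValueError("primer_coverage requires a non-empty database")
    frac = len(covered_ids(primer, db, max_mismatches)) / len(db)
    if isinstance(primer, DegeneratePrimer):
        primer.coverage = frac
    return frac


def evaluate_pair(
    fwd: DegeneratePrimer | str,
    rev: DegeneratePrimer | str,
    db: Sequence[SequenceRecord],
    product_min: int,
    product_max: int,
    max_mismatches: int = 0,
) -> PrimerPairReport:
    """Amplicon prediction for one forward/reverse primer pair.

    Per sequence, forward sites of ``fwd`` are combined with reverse-strand
    sites of ``rev`` lying strictly downstream (no overlap); the amplicon
    length is reverse-site end minus forward-site start, primers inclusive.
    A sequence counts as covered when at least one length falls in
    [product_min, product_max]; its shortest in-range amplicon (ties:
    leftmost forward site) is recorded. The product-length mode is the most
    frequent recorded length, ties resolved to the smallest.
    """
    if not db:
        raise ValueError("evaluate_pair requires a non-empty database")
    fpat = _iupac_seq(fwd)
    rpat_rc = iupac.reverse_complement(_iupac_seq(rev))
    rlen = len(rpat_rc)
    lengths: Counter = Counter()
    amplified: set[str] = set()
    for rec in db:
        fstarts = _scan(fpat, rec.seq, max_mismatches) if len(fpat) <= len(rec.seq) else []
        if not fstarts:
            continue
        rstarts = _scan(rpat_rc, rec.seq, max_mismatches) if rlen <= len(rec.seq) else []
        if not rstarts:
            continue
        best: Optional[tuple[int, int]] = None  # (length, fwd start)
        for fs in fstarts:
            fe = fs + len(fpat)
            for rs in rstarts:
                if rs < fe:
                    continue
                length = rs + rlen - fs
                if product_min <= length <= product_max:
                    cand = (length, fs)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            amplified.add(rec.id)
            lengths[best[0]] += 1
    mode = None
    if lengths:
        mode = min(lengths, key=lambda L: (-lengths[L], L))
    report = PrimerPairReport(
        fwd=fwd if isinstance(fwd, DegeneratePrimer) else DegeneratePrimer(fpat, fpat),
        rev=rev if isinstance(rev, DegeneratePrimer) else DegeneratePrimer(_iupac_seq(rev), _iupac_seq(rev)),
        pair_coverage=len(amplified) / len(db),
        product_lengths=lengths,
        product_length_mode=mode,
        covered_ids=amplified,
    )
    return report


def pair_and_report(
    primers: Sequence[DegeneratePrimer],
    db: Sequence[SequenceRecord],
    product_min: int = 200,
    product_max: int = 500,
    max_mismatches: int = 0,
) -> list[PrimerPairReport]:
    """Evaluate every ordered pair of as-synthesized primers.

    The first primer of a pair is matched forward, the second via its
    reverse complement on the sense strand. Reports are sorted by pair
    coverage descending (ties: forward then reverse name/sequence).
    """
    if len(primers) < 2:
        raise ValueError("pair_and_report requires at least two primers")
    reports = [
        evaluate_pair(f, r, db, product_min, product_max, max_mismatches)
        for f in primers
        for r in primers
        if f is not r
    ]
    reports.sort(
        key=lambda rep: (
            -rep.pair_coverage,
            rep.fwd.name or rep.fwd.iupac_seq,
            rep.rev.name or rep.rev.iupac_seq,
        )
    )
    return reports


PairLike = Union[DegeneratePrimer, str, tuple]


def specificity(
    primer_or_pair: PairLike,
    offtarget_db: Sequence[SequenceRecord],
    max_mismatches: int = 0,
    product_min: int = 200,
    product_max: int = 500,
) -> float:
    """Coverage of an off-target database (lower = more specific)."""
    if not offtarget_db:
        raise ValueError("specificity requires a non-empty off-target database")
    if isinstance(primer_or_pair, tuple):
        f, r = primer_or_pair
        return evaluate_pair(
            f, r, offtarget_db, product_min, product_max, max_mismatches
        ).pair_coverage
    return primer_coverage(primer_or_pair, offtarget_db, max_mismatches)
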