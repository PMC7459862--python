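"""IUPAC nucleotide ambiguity-code algebra.

The 15 IUPAC letters map bijectively onto the 15 non-empty subsets of
{A, C, G, T}. A degenerate oligo is a string over this alphabet; its
*expansions* are all concrete ACGT sequences obtained by picking one base
per position, and its *degeneracy* is the number of such expansions.
"""

from __future__ import annotations

import itertools
from functools import reduce
from typing import Iterable, Iterator

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: inverse map: non-empty base subset -> the unique IUPAC letter
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: complement of each ambiguity letter (complement the base set)
CODE_COMPLEMENT: dict[str, str] = {
    c: SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in s)]
    for c, s in IUPAC_SETS.items()
}


def base_set(code: str) -> frozenset[str]:
    """Base subset denoted by a single IUPAC letter."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(bases: Iterable[str]) -> str:
    """The IUPAC letter for a non-empty subset of {A, C, G, T}."""
    s = frozenset(bases)
    try:
        return SET_TO_CODE[s]
    except KeyError:
        raise ValueError(f"not a subset of ACGT: {sorted(s)}") from None


def merge_codes(code: str, other: str) -> str:
    """Letter denoting the union of two letters' base sets (degenerate fold)."""
    return code_for(base_set(code) | base_set(other))


def degeneracy(seq: str) -> int:
    """Number of distinct expansions: product of per-position set sizes."""
    return reduce(lambda n, c: n * len(base_set(c)), seq, 1)


def expand(seq: str) -> list[str]:
    """All expansions of ``seq``, in lexicographic order."""
    pools = [sorted(base_set(c)) for c in seq]
    return ["".join(p) for p in itertools.product(*pools)]


def iter_expand(seq: str) -> Iterator[str]:
    """Lazy variant of :func:`expand` (same lexicographic order)."""
    pools = [sorted(base_set(c)) for c in seq]
    for p in itertools.product(*pools):
        yield "".join(p)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full ambiguity alphabet.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return "".join(CODE_COMPLEMENT[c] for c in reversed(seq))


def is_strict_dna(seq: str) -> bool:
    """True when ``seq`` uses only concrete bases A/C/G/T."""
    return all(c in "ACGT" for c in seq)


def hamming1_neighbors(kmer: str) -> Iterator[str]:
    """All 3·k concrete sequences at Hamming distance exactly 1 from a k-mer."""
    for i, c in enumerate(kmer):
        for b in "ACGT":
            if b != c:
                yield kmer[:i] + b + kmer[i + 1 :]
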