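"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by direct enumeration (expansion lists,
substring scans, exhaustive stem/loop search) rather than by the package's
production route, so agreement is informative.
"""

from __future__ import annotations

import itertools

from kmerprimer import iupac
from kmerprimer.primer_properties import LOOP_DG, NN_PARAMS, loop_penalty

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def expand_brute(seq: str) -> list[str]:
    """All expansions by per-position cartesian product (sorted)."""
    pools = [sorted(iupac.IUPAC_SETS[c]) for c in seq]
    return sorted("".join(p) for p in itertools.product(*pools))


def gc_pct(seq: str) -> float:
    return sum(1 for c in seq if c in "GC") * 100.0 / len(seq)


def wallace_tm(seq: str) -> float:
    gc = sum(1 for c in seq if c in "GC")
    return 4.0 * gc + 2.0 * (len(seq) - gc)


def long_tm(seq: str) -> float:
    return 62.3 + 0.41 * gc_pct(seq) - 500.0 / len(seq)


def match_starts_brute(primer: str, seq: str, max_mismatches: int = 0) -> list[int]:
    """Forward-strand start positions by scanning every expansion.

    A window matches when some expansion is within the Hamming budget.
    Valid for N-free template sequences.
    """
    L = len(primer)
    exps = expand_brute(primer)
    out = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        best = min(
            sum(1 for a, b in zip(e, window) if a != b) for e in exps
        )
        if best <= max_mismatches:
            out.append(i)
    return out


def fold_dg_brute(seq: str, temp_c: float, ds_corr: float = 0.0) -> float:
    """Exhaustive hairpin search: every (open, close, stem-length) triple.

    Shares the nearest-neighbor table and loop lookup with the package but
    enumerates decompositions independently of the production scan.
    """
    n = len(seq)
    T = temp_c + 273.15
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            for s in range(3, (j - i) // 2 + 2):
                # pairs (i+t, j-t) for t in 0..s-1
                loop = (j - s) - (i + s) + 1
                if loop < 3:
                    break
                if not all(
                    _COMP[seq[i + t]] == seq[j - t] for t in range(s)
                ):
                    continue
                dg = 0.0
                for t in range(1, s):
                    dh, ds = NN_PARAMS[seq[i + t - 1 : i + t + 1]]
                    dg += dh - T * (ds + ds_corr) / 1000.0
                dg += loop_penalty(loop)
                if best is None or dg < best:
                    best = dg
    return best if best is not None else 0.0


def count_kmers_brute(seqs: list[str], k: int) -> dict[str, tuple[int, int]]:
    """kmer -> (occurrences, seq_hits) by direct substring scanning."""
    occ: dict[str, int] = {}
    hits: dict[str, int] = {}
    for s in seqs:
        seen = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            occ[w] = occ.get(w, 0) + 1
            seen.add(w)
        for w in seen:
            hits[w] = hits.get(w, 0) + 1
    return {w: (occ[w], hits[w]) for w in occ}
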