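"""Physicochemical properties of degenerate primers.

GC content and annealing temperature are reported as (min, max) ranges over
all non-degenerate expansions; both follow directly from the minimum and
maximum possible number of G/C positions, so no explicit expansion is
needed. Annealing temperature uses the Wallace rule Tm = 4(G+C) + 2(A+T)
for primers up to 20 bp and Tm = 62.3 + 0.41·GC% − 500/L above that, the
two regimes conventional for short oligos.

Self-folding stability is a transparent nearest-neighbor hairpin model:
minimum free energy over all hairpins with stem >= 3 bp and loop >= 3 nt,
Watson-Crick stacks scored as dG = dH − T·dS from the unified DNA
parameter set at 1 M Na+, plus a fixed loop-length penalty, with a
monovalent-equivalent salt correction for the configured Mg++/Na+ (mM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from . import iupac
from .primer_design import DegeneratePrimer

logger = logging.getLogger(__name__)

GC = frozenset("GC")


@dataclass
class PropertyRange:
    """Closed numeric interval [min_val, max_val] for one primer property."""

    min_val: float
    max_val: float

    def __post_init__(self) -> None:
        if self.min_val > self.max_val:
            raise ValueError("min_val exceeds max_val")

    def __iter__(self):
        return iter((self.min_val, self.max_val))


@dataclass
class FoldingConditions:
    """PCR folding temperature (°C) and ionic conditions (mM)."""

    fold_temp: float = 57.0
    mg: float = 20.0
    na: float = 0.0

    def __post_init__(self) -> None:
        if self.fold_temp <= 0:
            raise ValueError("fold_temp must be positive (°C)")


def round2(x: float | Decimal) -> float:
    """Round half-up to 2 decimals (fixed-point report style)."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _iupac_seq(p: DegeneratePrimer | str) -> str:
    return p if isinstance(p, str) else p.iupac_seq


def expansions(p: DegeneratePrimer | str, max_degeneracy: int = 1024) -> list[str]:
    """All distinct non-degenerate expansions, lexicographic order."""
    seq = _iupac_seq(p)
    deg = iupac.degeneracy(seq)
    if deg > max_degeneracy:
        raise ValueError(
            f"degeneracy {deg} exceeds cap {max_degeneracy}; "
            "use the range-by-bounds property functions instead"
        )
    return iupac.expand(seq)


def gc_bounds(p: DegeneratePrimer | str) -> tuple[int, int]:
    """Minimum and maximum possible count of G/C positions.

    A position contributes 1 to the minimum when its base set is entirely
    G/C, and 1 to the maximum when it intersects G/C.
    """
    seq = _iupac_seq(p)
    lo = sum(1 for c in seq if iupac.base_set(c) <= GC)
    hi = sum(1 for c in seq if iupac.base_set(c) & GC)
    return lo, hi


def gc_range(p: DegeneratePrimer | str) -> PropertyRange:
    """GC percentage range over expansions, percent to 2 decimals."""
    seq = _iupac_seq(p)
    lo, hi = gc_bounds(seq)
    L = len(seq)
    return PropertyRange(
        round2(Decimal(lo * 100) / Decimal(L)),
        round2(Decimal(hi * 100) / Decimal(L)),
    )


def _tm(L: int, gc: int) -> float:
    if L <= 20:
        return 4.0 * gc + 2.0 * (L - gc)
    return 62.3 + 0.41 * (gc * 100.0 / L) - 500.0 / L


def tm_range(p: DegeneratePrimer | str) -> PropertyRange:
    """Annealing-temperature range (°C) over expansions.

    Tm is monotone in the G+C count in both length regimes, so the range
    follows from the GC-count bounds.
    """
    seq = _iupac_seq(p)
    L = len(seq)
    lo, hi = gc_bounds(seq)
    return PropertyRange(round2(_tm(L, lo)), round2(_tm(L, hi)))


# Unified DNA nearest-neighbor stack parameters at 1 M NaCl:
# 5'->3' top-strand dinucleotide -> (dH kcal/mol, dS cal/(mol·K)).
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Hairpin loop penalties dG37 (kcal/mol) by loop length; intermediate sizes
# interpolated, larger loops extrapolated by the Jacobson-Stockmayer term.
LOOP_DG: dict[int, float] = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.6,
    12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7, 25: 6.1, 30: 6.3,
}

_R = 1.987e-3  # kcal/(mol·K)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MIN_STEM = 3
MIN_LOOP = 3


def loop_penalty(n: int) -> float:
    """Free-energy cost of closing a hairpin loop of n unpaired bases."""
    if n < MIN_LOOP:
        raise ValueError("loop below geometric minimum")
    if n in LOOP_DG:
        return LOOP_DG[n]
    if n < 30:
        ks = sorted(LOOP_DG)
        lo = max(k for k in ks if k < n)
        hi = min(k for k in ks if k > n)
        f = (n - lo) / (hi - lo)
        return LOOP_DG[lo] + f * (LOOP_DG[hi] - LOOP_DG[lo])
    return LOOP_DG[30] + 1.75 * _R * 310.15 * math.log(n / 30)


def _salt_ds_correction(cond: FoldingConditions) -> float:
    """Per-stack dS adjustment for non-1M monovalent-equivalent salt."""
    na_eq_mM = cond.na + (120.0 * math.sqrt(cond.mg) if cond.mg > 0 else 0.0)
    if na_eq_mM <= 0:
        return 0.0
    return 0.368 * math.log(na_eq_mM / 1000.0)


def fold_dG(seq: str, cond: FoldingConditions | None = None) -> float:
    """Minimum self-folding free energy (kcal/mol) of a concrete sequence.

    Enumerates every hairpin (stem >= 3 WC pairs, loop >= 3 nt); each is
    scored as the sum of its stacked-pair dG = dH − T·dS terms plus the
    loop penalty. Returns 0.0 when no qualifying hairpin exists. Positive
    minima are reported as-is (an unstable fold, not an error).
    """
    if cond is None:
        cond = FoldingConditions()
    if not iupac.is_strict_dna(seq):
        raise ValueError("fold_dG requires a non-degenerate ACGT sequence")
    n = len(seq)
    if n < 8:
        logger.info("sequence of %d bp cannot form a stem-3/loop-3 hairpin", n)
        return 0.0

    T = cond.fold_temp + 273.15
    ds_corr = _salt_ds_correction(cond)
    stack_dg = {
        d: dh - T * (ds + ds_corr) / 1000.0 for d, (dh, ds) in NN_PARAMS.items()
    }

    best: float | None = None
    # hairpin closed by pair (i, j); stem extends inward while WC-paired
    for i in range(n):
        for j in range(i + 2 * MIN_STEM + MIN_LOOP - 1, n):
            dg = 0.0
            s = 0
            while (
                i + s < j - s
                and (j - s) - (i + s) - 1 >= MIN_LOOP
                and _COMPLEMENT[seq[i + s]] == seq[j - s]
            ):
                if s > 0:
                    dg += stack_dg[seq[i + s - 1 : i + s + 1]]
                s += 1
                if s >= MIN_STEM:
                    loop = (j - s) - (i + s) + 1
                    total = dg + loop_penalty(loop)
                    if best is None or total < best:
                        best = total
    return best if best is not None else 0.0


def dG_range(
    p: DegeneratePrimer | str,
    cond: FoldingConditions | None = None,
    max_degeneracy: int = 1024,
) -> PropertyRange:
    """Self-folding dG range (kcal/mol) over all expansions."""
    vals = [fold_dG(e, cond) for e in expansions(p, max_degeneracy)]
    return PropertyRange(round2(min(vals)), round2(max(vals)))
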