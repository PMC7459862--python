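"""GC%, annealing temperature, degeneracy and self-folding dG of primers.

Property ranges span all non-degenerate expansions of a degenerate primer:
each ambiguous position contributes its minimum/maximum possible G+C
status, and Tm follows the Wallace rule (4(G+C) + 2(A+T)) for primers up
to 20 bp. Self-folding dG comes from a nearest-neighbor hairpin model at
the configured folding temperature and ionic conditions.
"""

from kmerprimer import FoldingConditions, dG_range, gc_range, tm_range
from kmerprimer.iupac import degeneracy

PRIMERS = {
    "napA_kmer5": "TTYTAYGACTGGTAYKSYGA",
    "amoA_kmer15": "AADTTCTAYAAYAGYCCHG",
    "amoA_kmer2": "GGTTTCTACTGGTGGTCVCA",
}

cond = FoldingConditions(fold_temp=57.0, mg=20.0, na=0.0)

print("name\tdegeneracy\tGC% range\tTm range (C)\tdG range (kcal/mol)")
for name, seq in PRIMERS.items():
    gc = gc_range(seq)
    tm = tm_range(seq)
    dg = dG_range(seq, cond)
    print(
        f"{name}\t{degeneracy(seq)}\t"
        f"{gc.min_val:.2f}-{gc.max_val:.2f}\t"
        f"{tm.min_val:.2f}-{tm.max_val:.2f}\t"
        f"({dg.min_val:.2f})-({dg.max_val:.2f})"
    )

# napA_kmer5 prints 64 expansions, GC 30.00-55.00%, Tm 52.00-62.00 C: six
# twofold codes give 2^6 expansions whose G+C count spans 6 to 11 of 20.
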