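# kmerprimer

Alignment-free design and assessment of degenerate PCR primers for
amplicon microbiome studies.

Surveys of microbial functional genes (nitrogen-cycle genes such as
*napA* and *amoA*, and many others) depend on PCR primers that amplify a
conserved locus across thousands of divergent database sequences.
Classical degenerate-primer design first builds a multiple sequence
alignment, which for 10⁴–10⁵ sequences can take days. `kmerprimer`
instead locates conserved loci directly as **high-frequency k-mers**:
a sequence of length *m* yields *m − k + 1* sliding windows, and a region
conserved across the database surfaces as a k-mer whose per-sequence hit
fraction approaches the fraction of sequences carrying the region — no
alignment required.

The design route is:

1. **k-mer tabulation** for each candidate primer length *k* (default
   18–20 bp): occurrence counts and per-sequence fractions.
2. **Selection** of the top-*n* k-mers by count, subject to a coverage
   floor (default 20%).
3. **Overlap merging**: k-mers sharing the same locus (mutual overlap
   > *x*, default 10) are collapsed to the most frequent one (ties:
   longer, then lexicographic).
4. **Degenerate folding**: every k-mer at Hamming distance 1 from a
   surviving seed with sequence fraction ≥ 1% is absorbed as an IUPAC
   ambiguity code (e.g. C/T → Y), up to a degeneracy cap (default 64).
5. **Assessment**: IUPAC-aware in-silico matching on both strands gives
   primer coverage; ordered forward/reverse combinations are screened by
   amplicon length (default 200–500 bp) to recommend primer pairs with
   their product-length mode; running the same matcher against an
   off-target database gives specificity (lower is better).

For each primer the package reports degeneracy (the number of concrete
expansions, ∏ per-position set sizes), the GC% range over expansions,
the annealing-temperature range — Wallace rule Tm = 4(G+C) + 2(A+T) for
L ≤ 20 bp, Tm = 62.3 + 0.41·GC% − 500/L above — and a self-folding ΔG
estimate from a nearest-neighbor hairpin model. Covered sequences can be
summarized per taxon and per phenotype class (oxygen requirement, gram
type) from a user-supplied taxon→phenotype TSV.

## Worked example

A synthetic database of 100 sequences (600–800 bp) where 85% carry the
20-bp locus `TTCTACGACTGGTACGCCGA` exactly and a further 10% carry it
with a single C→T substitution at position 3:

```python
from kmerprimer import (PipelineConfig, PlantedMotifSpec,
                        design_primers, generate_database)

spec = PlantedMotifSpec("TTCTACGACTGGTACGCCGA", carrier_fraction=0.85,
                        variant_defs=((2, "T", 0.10),))
db, manifest = generate_database(100, (600, 800), [spec], seed=7)
primers = design_primers(db, PipelineConfig(primer_len_min=20,
                                            primer_len_max=20),
                         name_prefix="demo")
for p in primers:
    print(p.name, p.iupac_seq, p.degeneracy, f"{p.coverage:.2f}")
```

prints

```
demo_kmer1 TTYTACGACTGGTACGCCGA 2 0.95
```

The designer recovered the planted locus, folded the 10% variant into a
`Y` (C or T) at the substituted position — degeneracy 2 — and verified
coverage 0.95, exactly the summed carrier fraction. Property calculation
on a published-style primer:

```python
from kmerprimer import gc_range, tm_range
print(tuple(gc_range("TTYTAYGACTGGTAYKSYGA")))   # (30.0, 55.0)  percent
print(tuple(tm_range("TTYTAYGACTGGTAYKSYGA")))   # (52.0, 62.0)  °C
```

The six twofold codes give 2⁶ = 64 expansions whose G+C count spans 6–11
of 20 positions, hence GC 30–55% and Wallace Tm 52–62 °C.

The `examples/` directory holds one short narrative script per
capability (k-mer statistics, design, properties, pair evaluation,
taxonomy summaries); each prints its results with a comment on what the
numbers mean. A thin CLI mirrors the library:
`kmerprimer stats|trim|dedupe|kmers|design|props|evaluate|taxsummary|simulate|run`.

## Notes on fidelity

Self-folding ΔG uses a transparent nearest-neighbor hairpin model
(unified DNA stack parameters, fixed loop-penalty lookup, monovalent-
equivalent salt correction), not the folding software used for the
original reports, so ΔG values are indicative rather than comparable
digit-for-digit. Likewise coverage uses a deterministic IUPAC window
scan with an optional mismatch budget rather than a BLASTn backend.
Both choices are documented in `docs/methods.md`.
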