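# Methods

## Model of a conserved locus

The package assumes that a primer-worthy region of a functional-gene
database is (i) near-identical across a large fraction of sequences and
(ii) long enough that an exact window of primer length recurs verbatim.
Under that assumption the per-sequence hit fraction of a k-mer is an
alignment-free estimator of the conservation of its locus, and
single-base polymorphisms of the locus appear as k-mers at Hamming
distance 1 from the consensus with proportional frequencies. The design
algorithm is a direct operationalization: tabulate, select, merge
same-locus duplicates, fold variants into IUPAC codes, verify coverage.

This breaks down for loci with indel variation (variants shift the whole
window rather than changing one base) and for conserved regions shorter
than the primer length; both show up as reduced coverage rather than as
wrong primers, since every candidate's coverage is re-verified by
explicit matching before output.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `primer_len_min/max` | 18–20 | bp | k-mer lengths tried; each k is designed independently |
| `top_n` | 30 | — | high-frequency k-mers carried per k |
| `min_coverage` | 0.2 | fraction | floor on seed selection and on emitted primer coverage |
| `overlap` | 10 | bases | same-locus merge threshold (pairs with overlap > x collapse) |
| `variant_min_fraction` | 0.01 | fraction | floor for folding a Hamming-1 variant |
| `max_degeneracy` | 64 | — | cap on expansions; folding stops before exceeding it |
| `product_min/max` | 200–500 | bp | accepted amplicon lengths (primers inclusive) |
| `max_mismatches` | 0 | — | per-window mismatch budget of the matcher |
| `fold_temp` | 57 | °C | temperature for the hairpin ΔG evaluation |
| `mg`, `na` | 20, 0 | mM | ionic conditions; salt correction of stack entropies |

The defaults are the platform parameter sheet of the original tool. The
degeneracy cap is a package design choice: unbounded folding makes GC/Tm
ranges vacuous and expansions intractable, so absorption proceeds
highest-fraction-first and stops before the first fold that would exceed
the cap. Variant folding considers Hamming-1 neighbors of the *seed*
only (no iterated re-absorption against the growing degenerate string).

## Matching semantics

A primer position matches a template base when the base is a member of
the position's IUPAC set; a template `N` matches only a primer `N` (an
ambiguous database base is not evidence of a binding site). Reverse
primers are stored 5'→3' as synthesized and their binding is evaluated
by matching the reverse complement against the sense strand. For a pair,
a sequence counts as amplified when some forward site and some
non-overlapping downstream reverse site give a product length
(reverse-site end − forward-site start) within bounds; per sequence the
shortest in-range product is recorded (ties: leftmost forward site), and
the pair's product-length mode is the most frequent recorded length
(ties: smallest). Requiring non-overlap makes every recorded length at
least the sum of the primer lengths. This deterministic scan replaces a
BLASTn backend deliberately: BLAST's word-size/E-value behaviour is not
bit-reproducible across versions, whereas the scan is exact and is
cross-checked against per-expansion brute-force matching in the tests.

Overlap between two k-mers is the maximum of the longest suffix–prefix
match in either order and, when one contains the other, the length of
the shorter — i.e. the number of shared bases when the two windows are
laid on a common locus. Merge tie-breaks (count → length → lexicographic)
and all other orderings are total, so the whole analysis path is
RNG-free and byte-deterministic.

## Property calculations

GC% and Tm ranges are computed from per-position set membership: a
position contributes its minimum (set ⊆ {G,C}) and maximum (set ∩ {G,C}
≠ ∅) possible G+C status, which yields exactly the min/max over all
expansions because both properties are monotone in the G+C count. The
Wallace rule Tm = 4(G+C) + 2(A+T) is applied for lengths ≤ 20 (every
published 20-bp cell is consistent with it) and
Tm = 62.3 + 0.41·GC% − 500/L above. Reported values are rounded half-up
to two decimals, matching fixed-point report style.

Self-folding ΔG is the minimum over all hairpins with stem ≥ 3
Watson–Crick pairs and loop ≥ 3 nt. Stacks are scored ΔG = ΔH − T·ΔS
with the unified DNA nearest-neighbor parameters (1 M Na⁺); loop closure
adds a fixed ΔG₃₇ lookup (anchors at 3–30 nt, linear interpolation
between anchors, Jacobson–Stockmayer extrapolation beyond 30), treated
as temperature-independent since loop penalties are dominantly entropic
and the evaluation temperature is near 37 °C. Ionic conditions enter as
a per-stack entropy correction 0.368·ln[Na⁺eq] with
[Na⁺eq] = [Na⁺] + 120·√[Mg²⁺] (mM); the Mg/Na defaults are interpreted
as mM. Sequences shorter than 8 nt, or without any qualifying hairpin,
return 0.0. A positive minimum is reported as-is (an unstable fold).
This model is intentionally simpler than full secondary-structure
folding: no bulges, internal loops, dangling ends or coaxial stacking,
and no partition function. ΔG ranges over expansions are therefore
indicative screening values, not replacements for a dedicated folding
package.

## Synthetic databases and what the tests show

`generate_database` plants a consensus motif (optionally with defined
single-base variants at defined carrier fractions, and optionally a
paired downstream motif at fixed spacing) into i.i.d. uniform-ACGT
backgrounds, with a manifest of every carrier, coordinate and variant.
Carrier counts are deterministic (half-up rounding of n·fraction) and
all randomness flows from one integer seed.

The generator emulates exactly the structure the method exploits —
conserved exact windows plus point variants — and none of the
confounders of real databases: indels, correlated background
composition, GC skew, partial gene fragments, sequencing error, or
homologous off-target genes with graded similarity. Passing the
recovery tests therefore shows the algorithm implements its definition
correctly (selection, merging, folding, coverage arithmetic), not that
designed primers will perform at any particular level on a real
functional-gene database, where coverage depends on the database's
actual conservation structure.

Test problem sizes were chosen as the smallest at which each property is
informative: recovery uses 20 databases of 100 sequences × 600–800 bp
(recovery demanded in ≥ 19/20, coverage within 0.02 of truth);
brute-force equivalence suites use 50–200 randomized cases with
degeneracy ≤ 64–1024 and sequences ≤ 30 bp for the folding oracle.

## Degenerate inputs and edge behaviour

Ambiguity codes other than N in database sequences collapse to N on
ingest (with a warning) so matcher semantics stay well defined; records
with non-IUPAC characters are dropped with a warning. Duplicate removal
is exact string equality after normalization — no reverse-complement
collapsing. A k larger than a sequence yields no windows (not an error);
an empty design below the coverage floor is a warning with empty
reports, not a failure. Primer naming is sequential in coverage order
(`<prefix>_kmer1`, ...), as the original tool's naming scheme is not
specified.

## Known limitations

- Coverage is exact-window (plus optional mismatch budget) matching;
  thermodynamic binding strength and 3'-end stability are not modelled.
- Primer-dimer interactions between the two primers of a pair are not
  evaluated (only self-folding of each expansion).
- Counting is strand-specific by design; palindromic loci appear twice
  (once per strand) and are merged only if their overlap exceeds x.
- In-memory counting targets desk-scale databases (≤ ~10⁵ sequences ×
  1 kb); no disk-backed or parallel counting.
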