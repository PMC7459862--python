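"""Count k-mers across a small database and find the conserved locus.

A conserved region shared by many sequences shows up, without any
alignment, as a k-mer whose sequence fraction approaches the fraction of
sequences carrying the region.
"""

from kmerprimer import PlantedMotifSpec, count_kmers, generate_database

MOTIF = "TTCTACGACTGGTACGCCGA"

db, _ = generate_database(
    n_seqs=50,
    seq_len_range=(300, 400),
    motifs=[PlantedMotifSpec(MOTIF, carrier_fraction=0.8)],
    seed=1,
)

table = count_kmers(db, k=20)
top = sorted(table, key=lambda s: -s.occurrences)[:3]

print(f"{len(table)} distinct 20-mers across {table.n_sequences} sequences")
print("kmer\toccurrences\tseq_hits\tseq_fraction")
for s in top:
    print(f"{s.kmer}\t{s.occurrences}\t{s.seq_hits}\t{s.seq_fraction:.2f}")

# The planted motif is carried by 80% of sequences, so its window tops the
# table with seq_fraction 0.80; background 20-mers are essentially unique.
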