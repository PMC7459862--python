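"""Design a degenerate primer from a database with a known variant.

85% of sequences carry a conserved 20-bp locus exactly and another 10%
carry it with a single C->T substitution at position 3. The designer
recovers the locus as its top primer with a Y (C/T) at that position, and
the verified coverage equals the summed carrier fraction.
"""

from kmerprimer import PipelineConfig, PlantedMotifSpec, design_primers, generate_database

MOTIF = "TTCTACGACTGGTACGCCGA"
spec = PlantedMotifSpec(MOTIF, carrier_fraction=0.85, variant_defs=((2, "T", 0.10),))

db, manifest = generate_database(100, (600, 800), [spec], seed=7)
print("planted consensus:  ", MOTIF)
print("expected degenerate:", spec.expected_iupac)

config = PipelineConfig(primer_len_min=20, primer_len_max=20)
primers = design_primers(db, config, name_prefix="demo")

print("\nname\tiupac_seq\tdegeneracy\tcoverage")
for p in primers:
    print(f"{p.name}\t{p.iupac_seq}\t{p.degeneracy}\t{p.coverage:.2f}")

# demo_kmer1 prints TTYTACGACTGGTACGCCGA with coverage 0.95: the folded Y
# recovers both planted alleles, and 0.95 = 0.85 + 0.10 carriers.
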